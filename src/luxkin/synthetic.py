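"""Synthetic data with known ground truth for every pipeline stage.

Each generator returns a ``(data, truth)`` pair: downstream recovery tests
consume only ``data`` and compare estimates against ``truth``. All randomness
flows through a single integer seed, so every generated object is bitwise
reproducible.

The defaults emulate the study conditions of the single-turnover stopped-flow
experiment: five bioluminescence curves at decanal 10-50 uM (L0 = 1 uM,
F0 = 15 uM), 15 s traces, with 2% multiplicative noise plus a small additive
floor standing in for averaged instrument noise. The default ground-truth
rate constants are chosen so that the implied Michaelis constants fall in the
1-2 uM (flavin) and 25-50 uM (decanal) windows typical for the buffer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reaction_model import InitialConditions, KineticCurve, RateConstants, simulate_curve
from .fitting import SingleTurnoverDataset
from .spectra import EmissionSpectrum
from .viscosity import ViscosityPoint

__all__ = [
    "NoiseModel",
    "DEFAULT_TRUE_RATES",
    "DEFAULT_ALDEHYDE_UM",
    "default_time_grid",
    "generate_bioluminescence_dataset",
    "generate_absorbance_trace",
    "generate_viscosity_series",
    "generate_spectrum",
]

#: Ground-truth rate constants used by the fixtures. K_M^F = k2/k1 = 1.5 uM,
#: K_M^a = (k_minus3 + k4)/k3 = 30 uM; flash-like curves peaking near 1 s.
DEFAULT_TRUE_RATES = RateConstants(
    k1=1e7, k2=15.0, k3=1e5, k_minus3=2.0, k4=1.0, kd=0.5, kdd=0.1, scale=1e12
)

#: Decanal concentrations of the five-curve design, uM.
DEFAULT_ALDEHYDE_UM = (10.0, 20.0, 30.0, 40.0, 50.0)


def default_time_grid(duration_s: float = 15.0, n_points: int = 1000) -> np.ndarray:
    """Uniform acquisition grid: 15 s traces sampled at 1000 points."""
    return np.linspace(0.0, duration_s, n_points)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-noise description applied to noise-free signals.

    multiplicative_sigma is the relative std of per-point Gaussian noise;
    additive_sigma (in signal units) stands in for detector/baseline noise;
    baseline is a constant offset. Defaults: 2% multiplicative plus an
    additive floor of 0.1% of the signal peak (resolved per curve).
    """

    multiplicative_sigma: float = 0.02
    additive_sigma: float | None = None  # None -> 0.1% of the curve's peak
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sigma < 0:
            raise ValueError("multiplicative_sigma must be nonnegative")
        if self.additive_sigma is not None and self.additive_sigma < 0:
            raise ValueError("additive_sigma must be nonnegative")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        add = self.additive_sigma
        if add is None:
            add = 1e-3 * float(np.max(np.abs(y))) if y.size else 0.0
        out = y * (1.0 + self.multiplicative_sigma * rng.standard_normal(y.shape))
        out = out + add * rng.standard_normal(y.shape) + self.baseline
        return out


def generate_bioluminescence_dataset(
    rates: RateConstants = DEFAULT_TRUE_RATES,
    *,
    L0_uM: float = 1.0,
    F0_uM: float = 15.0,
    aldehyde_uM=DEFAULT_ALDEHYDE_UM,
    t_grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
):
    """Five-curve single-turnover dataset with known generating parameters.

    Returns
    -------
    (dataset, truth) : (SingleTurnoverDataset, dict)
        ``truth`` records the generating rates, concentrations and noise model.
    """
    if t_grid is None:
        t_grid = default_time_grid()
    if noise is None:
        noise = NoiseModel(seed=seed)
    rng = np.random.default_rng(seed)
    curves = []
    for a_uM in aldehyde_uM:
        ic = InitialConditions(L0=L0_uM * 1e-6, F0=F0_uM * 1e-6, A0=a_uM * 1e-6)
        clean = simulate_curve(rates, ic, t_grid)
        y = noise.apply(clean.y, rng)
        meta = dict(clean.meta)
        meta["decanal_uM"] = a_uM
        curves.append(KineticCurve(t=t_grid, y=y, meta=meta))
    dataset = SingleTurnoverDataset(
        curves=curves,
        L0=L0_uM * 1e-6,
        F0=F0_uM * 1e-6,
        A0_list=[a * 1e-6 for a in aldehyde_uM],
    )
    truth = {
        "rates": rates.as_dict(),
        "L0_uM": L0_uM,
        "F0_uM": F0_uM,
        "aldehyde_uM": list(aldehyde_uM),
        "noise": {
            "multiplicative_sigma": noise.multiplicative_sigma,
            "additive_sigma": noise.additive_sigma,
            "baseline": noise.baseline,
        },
        "seed": seed,
    }
    return dataset, truth


def generate_absorbance_trace(
    kind: str = "mono",
    *,
    k: float = 0.5,
    k_slow: float = 0.05,
    amplitude: float = 0.15,
    amplitude_slow: float = 0.05,
    offset: float = 0.02,
    decaying: bool = True,
    t_grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    signal_kind: str = "absorbance_445",
):
    """Mono- or bi-exponential absorbance trace with known components.

    ``kind='mono'``: A(t) = offset + amplitude * exp(-k t) (decaying) or the
    complementary rise. ``kind='bi'``: sum of a fast (k, amplitude) and a slow
    (k_slow, amplitude_slow) exponential plus offset, emulating the biphasic
    445-nm flavin-autoxidation signal.

    Returns ``(KineticCurve, truth_dict)``.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 60.0, 600)
    if noise is None:
        noise = NoiseModel(multiplicative_sigma=0.0, additive_sigma=0.0, seed=seed)
    t = np.asarray(t_grid, dtype=float)
    if kind == "mono":
        y = offset + amplitude * np.exp(-k * t)
        if not decaying:
            y = offset + amplitude * (1.0 - np.exp(-k * t))
        truth = {"kind": kind, "k": k, "amplitude": amplitude, "offset": offset}
    elif kind == "bi":
        y = offset + amplitude * np.exp(-k * t) + amplitude_slow * np.exp(-k_slow * t)
        truth = {
            "kind": kind,
            "k_fast": k,
            "k_slow": k_slow,
            "amplitude_fast": amplitude,
            "amplitude_slow": amplitude_slow,
            "offset": offset,
        }
    else:
        raise ValueError(f"unknown trace kind {kind!r} (expected 'mono' or 'bi')")
    rng = np.random.default_rng(seed)
    curve = KineticCurve(t=t, y=noise.apply(y, rng), signal_kind=signal_kind)
    truth["seed"] = seed
    return curve, truth


def generate_viscosity_series(
    A: float,
    delta: float,
    eta_list=None,
    noise_fraction: float = 0.05,
    seed: int = 0,
    cosolvent: str = "synthetic",
):
    """Rate-vs-viscosity points from the power law k = A * eta**(-delta).

    Noise is multiplicative Gaussian: k_i = A * eta_i**(-delta) * (1 + eps_i).
    Defaults: 24 viscosities uniformly spaced over 1-6 cP, 5% noise.

    Returns ``(list of ViscosityPoint, truth_dict)``.
    """
    if A <= 0:
        raise ValueError("amplitude A must be positive")
    if eta_list is None:
        eta_list = np.linspace(1.0, 6.0, 24)
    eta = np.asarray(eta_list, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("viscosities must be positive")
    rng = np.random.default_rng(seed)
    eps = noise_fraction * rng.standard_normal(eta.shape)
    k = A * eta ** (-delta) * (1.0 + eps)
    points = [
        ViscosityPoint(eta=float(e), k=float(kk), cosolvent=cosolvent, wt_percent=None)
        for e, kk in zip(eta, k)
    ]
    truth = {"A": A, "delta": delta, "noise_fraction": noise_fraction, "seed": seed}
    return points, truth


def generate_spectrum(
    peak_nm: float = 340.0,
    width_nm: float = 25.0,
    grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    amplitude: float = 1.0,
    seed: int = 0,
    condition: str = "synthetic",
):
    """Gaussian emission band sampled on the 305-450 nm acquisition range.

    A stand-in for tryptophan emission spectra: a single Gaussian band of the
    given peak position and standard deviation. Returns
    ``(EmissionSpectrum, truth_dict)``.
    """
    if grid is None:
        grid = np.arange(305.0, 450.5, 0.5)
    lam = np.asarray(grid, dtype=float)
    y = amplitude * np.exp(-0.5 * ((lam - peak_nm) / width_nm) ** 2)
    if noise is not None:
        rng = np.random.default_rng(seed)
        y = np.clip(noise.apply(y, rng), 0.0, None)
    spec = EmissionSpectrum(lam=lam, intensity=y, condition=condition)
    truth = {"peak_nm": peak_nm, "width_nm": width_nm, "amplitude": amplitude, "seed": seed}
    return spec, truth
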
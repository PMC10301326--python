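"""Viscosity and water-activity analysis of rate constants.

Diffusion-limited elementary steps slow down with medium viscosity following
Kramers-type power laws, k = A * eta**(-delta): delta ~ 1 marks diffusion
control, delta >> 1 an "overdamped" dependence steeper than diffusion control
(typical of small polyols penetrating the active site), and delta ~ 0 a
viscosity-independent step. This module fits those power laws, classifies the
regime, evaluates water activity of cosolvent solutions by the Norrish
equation, and correlates rate constants with cosolvent-water interaction
parameters (Norrish constant, van der Waals interaction energies supplied as
tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ViscosityPoint",
    "PowerLawFit",
    "NorrishInput",
    "CorrelationResult",
    "WATER_MOLAR_MASS",
    "fit_power_law",
    "classify_diffusion_control",
    "mole_fractions",
    "norrish_water_activity",
    "correlate",
]

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.015


@dataclass(frozen=True)
class ViscosityPoint:
    """One (viscosity, rate) observation.

    eta in cP (aqueous reference ~ 1 cP); k is the rate constant or empirical
    parameter value, in the units of the quantity analysed.
    """

    eta: float
    k: float
    cosolvent: str | None = None
    wt_percent: float | None = None

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("viscosity must be positive")
        if self.k <= 0:
            raise ValueError("rate value must be positive")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting k = A * eta**(-delta).

    delta is reported positive for rates that fall with viscosity; A carries
    the units of k. Standard errors come from the nonlinear-fit covariance.
    """

    A: float
    delta: float
    A_stderr: float
    delta_stderr: float
    r_squared: float
    n: int

    def predict(self, eta) -> np.ndarray:
        return self.A * np.asarray(eta, dtype=float) ** (-self.delta)


@dataclass(frozen=True)
class NorrishInput:
    """Cosolvent description for the Norrish water-activity model.

    kN is the (dimensionless) Norrish constant: kN < 0 depresses water
    activity below the Raoult mole-fraction prediction, kN > 0 raises it.
    """

    kN: float
    molar_mass: float
    wt_percent: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        if not 0 <= self.wt_percent < 100:
            raise ValueError("wt_percent must be in [0, 100)")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation between two paired series."""

    r: float
    n: int
    p_value: float
    labels: tuple = ("x", "y")


def fit_power_law(points: Sequence[ViscosityPoint]) -> PowerLawFit:
    """Least-squares fit of k = A * eta**(-delta) to (eta, k) points.

    Residuals are weighted relative to the measured rate (sigma proportional
    to k), matching the multiplicative error typical of rate-constant
    measurements: without it, the steep-decay series would be fitted almost
    entirely by its low-viscosity points. Warm start from the log-log linear
    regression; on noise-free power-law data the warm start is already the
    exact solution and the refinement leaves it unchanged.

    Requires at least 3 points with positive eta and k.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points to fit a power law, got {len(pts)}")
    eta = np.array([p.eta for p in pts], dtype=float)
    k = np.array([p.k for p in pts], dtype=float)

    # warm start: ln k = ln A - delta * ln eta
    slope, intercept = np.polyfit(np.log(eta), np.log(k), 1)
    A0, d0 = float(np.exp(intercept)), float(-slope)

    def model(e, A, d):
        return A * e ** (-d)

    popt, pcov = optimize.curve_fit(
        model, eta, k, p0=[A0, d0], sigma=k, maxfev=10000
    )
    A_fit, d_fit = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = k - model(eta, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((k - k.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        A=A_fit,
        delta=d_fit,
        A_stderr=float(perr[0]),
        delta_stderr=float(perr[1]),
        r_squared=r2,
        n=len(pts),
    )


def classify_diffusion_control(fit: PowerLawFit, tol: float = 0.25) -> str:
    """Classify the viscosity regime from the power-law exponent.

    delta < tol           -> 'viscosity_independent'
    |delta - 1| <= tol    -> 'diffusion_limited'
    delta > 1 + tol       -> 'overdamped'

    Exponents between tol and 1 - tol are labelled 'intermediate' (apparent
    rate composed of viscosity-dependent and -independent stages).
    """
    d = fit.delta
    if d < tol:
        return "viscosity_independent"
    if abs(d - 1.0) <= tol:
        return "diffusion_limited"
    if d > 1.0 + tol:
        return "overdamped"
    return "intermediate"


def mole_fractions(wt_percent: float, molar_mass: float) -> tuple[float, float]:
    """Convert cosolvent weight percent to (x_water, x_cosolvent).

    Binary water + cosolvent mixture; water molar mass 18.015 g/mol.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if not 0 <= wt_percent < 100:
        raise ValueError("wt_percent must be in [0, 100)")
    w = wt_percent / 100.0
    n_s = w / molar_mass
    n_w = (1.0 - w) / WATER_MOLAR_MASS
    x_s = n_s / (n_s + n_w)
    return 1.0 - x_s, x_s


def norrish_water_activity(inp: NorrishInput) -> float:
    """Water activity a_w of a binary solution by the Norrish equation.

    a_w = x_w * exp(kN * x_s**2), with mole fractions computed from the
    cosolvent weight percent and molar mass. kN = 0 recovers the ideal
    (Raoult) limit a_w = x_w; pure water gives a_w = 1.
    """
    x_w, x_s = mole_fractions(inp.wt_percent, inp.molar_mass)
    return float(x_w * np.exp(inp.kN * x_s**2))


def correlate(xs, ys, labels: tuple = ("x", "y")) -> CorrelationResult:
    """Pearson correlation coefficient between paired series.

    Raises on mismatched lengths, n < 3, or zero variance in either series.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be equal-length one-dimensional series")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=len(x), p_value=float(res.pvalue), labels=labels
    )
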
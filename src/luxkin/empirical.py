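"""Empirical parameters of a flash-like bioluminescence curve.

A single-turnover light curve is summarised by four model-free quantities:

* ``Imax``    - peak intensity (maximum signal), a.u.;
* ``Qstar``   - total quantum yield, the area under the curve, a.u.*s;
* ``v0``      - initial velocity, the slope of the starting linear part of
  the curve, a.u./s;
* ``k_decay`` - exponential decay index of the final part of the curve, 1/s.

The windows for v0 and k_decay are configurable: by default v0 is the OLS
slope from t = 0 until the signal first reaches 20% of Imax (at least 5
points), and the decay fit spans from 2 s past the peak to the end of the
trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reaction_model import KineticCurve

__all__ = [
    "EmpiricalParams",
    "peak_intensity",
    "total_quantum_yield",
    "initial_velocity",
    "decay_constant",
    "empirical_params",
]


@dataclass(frozen=True)
class EmpiricalParams:
    """The four empirical parameters of one curve plus the windows used."""

    Imax: float
    k_decay: float
    v0: float
    Qstar: float
    v0_window: tuple
    decay_window: tuple

    def as_dict(self) -> dict:
        return {
            "Imax": self.Imax,
            "k_decay_1_per_s": self.k_decay,
            "v0_per_s": self.v0,
            "Qstar": self.Qstar,
            "v0_window_s": list(self.v0_window),
            "decay_window_s": list(self.decay_window),
        }


def peak_intensity(curve: KineticCurve) -> float:
    """Maximum of the signal, a.u."""
    return float(np.max(curve.y))


def total_quantum_yield(curve: KineticCurve, baseline: float = 0.0) -> float:
    """Area under the curve by the trapezoidal rule, a.u.*s.

    ``baseline`` is subtracted before integration when provided (default off).
    """
    return float(np.trapezoid(curve.y - baseline, curve.t))


def _window_mask(curve: KineticCurve, window) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    return (curve.t >= t0) & (curve.t <= t1)


def initial_velocity(curve: KineticCurve, window: tuple | None = None) -> tuple:
    """OLS slope of the starting linear part of the curve, a.u./s.

    Default window: from t = 0 until y first reaches 20% of the peak,
    extended to contain at least 5 points.

    Returns ``(v0, window_used)``.
    """
    if window is None:
        thresh = 0.2 * peak_intensity(curve)
        above = np.nonzero(curve.y >= thresh)[0]
        i_end = above[0] if len(above) else len(curve.t) - 1
        i_end = max(i_end, 4)  # need >= 5 points for a slope
        if i_end >= len(curve.t):
            raise ValueError("curve too short for the default initial-velocity window")
        window = (float(curve.t[0]), float(curve.t[i_end]))
    mask = _window_mask(curve, window)
    if mask.sum() < 5:
        raise ValueError(f"initial-velocity window {window} holds {mask.sum()} points (< 5)")
    slope = np.polyfit(curve.t[mask], curve.y[mask], 1)[0]
    return float(slope), window


def decay_constant(curve: KineticCurve, window: tuple | None = None) -> tuple:
    """Exponential decay index of the final part of the curve, 1/s.

    Fits y = B * exp(-k_decay * t) by linear regression on ln y inside the
    window. The default window runs from 2 s past the peak until the signal
    last exceeds 1% of the peak (or the end of the trace if it never falls
    that far): beyond that point a measured tail sits at the noise floor and
    carries no decay information. The signal must be strictly positive
    inside the window; choose the window accordingly for noisy data.

    Returns ``(k_decay, window_used)``.
    """
    if window is None:
        i_peak = int(np.argmax(curve.y))
        t_peak = float(curve.t[i_peak])
        above = np.nonzero(curve.y >= 0.01 * curve.y[i_peak])[0]
        t_cut = float(curve.t[above[-1]]) if len(above) else float(curve.t[-1])
        if t_cut <= t_peak + 2.0:
            t_cut = float(curve.t[-1])
        window = (t_peak + 2.0, t_cut)
    mask = _window_mask(curve, window)
    if mask.sum() < 2:
        raise ValueError(f"decay window {window} holds {mask.sum()} points (< 2)")
    y = curve.y[mask]
    if np.any(y <= 0):
        raise ValueError("nonpositive intensities inside the decay window: cannot take log")
    slope = np.polyfit(curve.t[mask], np.log(y), 1)[0]
    return float(-slope), window


def empirical_params(
    curve: KineticCurve,
    v0_window: tuple | None = None,
    decay_window: tuple | None = None,
    baseline: float = 0.0,
) -> EmpiricalParams:
    """All four empirical parameters of one flash-like curve."""
    v0, v0_win = initial_velocity(curve, v0_window)
    k_dec, dec_win = decay_constant(curve, decay_window)
    return EmpiricalParams(
        Imax=peak_intensity(curve),
        k_decay=k_dec,
        v0=v0,
        Qstar=total_quantum_yield(curve, baseline=baseline),
        v0_window=v0_win,
        decay_window=dec_win,
    )
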
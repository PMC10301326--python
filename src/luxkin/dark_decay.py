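"""Dark-decay constants from absorbance traces by windowed exponential fits.

Two dark processes compete with light emission in the single-turnover assay:
autoxidation of free FMNH2 by dissolved oxygen (apparent constant ``kd``,
followed at 445 nm where oxidized flavin absorbs) and spontaneous decay of
the enzyme-bound peroxyflavin intermediate (``kdd``, followed at 380 nm).
Both are estimated by approximating user-chosen time windows of the
absorbance trace with a three-parameter exponential

    A(t) = A_inf + dA * exp(-k * t)

fitted by nonlinear least squares with a log-linear warm start. The true
autoxidation kinetics is multi-stage and autocatalytic; this module
deliberately implements only the windowed-exponential *procedure* that
defines the apparent constants, not a mechanistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .reaction_model import KineticCurve

__all__ = ["AbsorbanceFit", "fit_exponential", "fit_kd", "fit_kdd"]


@dataclass(frozen=True)
class AbsorbanceFit:
    """Exponential approximation of one window of an absorbance trace.

    k in 1/s; amplitude (signed: negative for rising signals) and offset in
    absorbance units; residual_norm is the RMS residual of the fit.
    """

    k: float
    amplitude: float
    offset: float
    window: tuple
    residual_norm: float

    def predict(self, t) -> np.ndarray:
        return self.offset + self.amplitude * np.exp(-self.k * np.asarray(t, dtype=float))


def _warm_start(t: np.ndarray, y: np.ndarray) -> tuple:
    """Initial (k, amplitude, offset) from a log-linear regression.

    The offset is probed slightly beyond the extreme sample on the plateau
    side so the log argument stays positive.
    """
    y_inf = y[-1] + 0.05 * (y[-1] - y[0])  # plateau guess past the last point
    z = y - y_inf
    sign = 1.0 if z[0] >= 0 else -1.0
    z = sign * z
    pos = z > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(z[pos]), 1)
        k0 = max(-slope, 1e-12)
        amp0 = sign * float(np.exp(intercept))
    else:  # flat or degenerate window: fall back to a scale guess
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)
        amp0 = float(y[0] - y[-1])
    return k0, amp0, float(y_inf)


def fit_exponential(curve: KineticCurve, window: tuple) -> AbsorbanceFit:
    """Fit A(t) = A_inf + dA * exp(-k t) on one window of a trace.

    Nonlinear least squares (scipy curve_fit) warm-started by a log-linear
    regression; on noise-free exponential data the refinement converges to
    the generating parameters at machine precision. Warns when the windowed
    segment is not monotone (an exponential cannot represent it well).
    """
    t0, t1 = window
    mask = (curve.t >= t0) & (curve.t <= t1)
    if mask.sum() < 4:
        raise ValueError(f"window {window} holds {mask.sum()} points (< 4)")
    t = curve.t[mask]
    y = curve.y[mask]

    dy = np.diff(y)
    if np.any(dy > 0) and np.any(dy < 0):
        frac = min(np.sum(dy > 0), np.sum(dy < 0)) / len(dy)
        if frac > 0.25:  # tolerate noise wiggle, flag real non-monotonicity
            warnings.warn(
                f"segment in window {window} is not monotone "
                f"({frac:.0%} of steps run against the trend); "
                "a single exponential may be inadequate",
                stacklevel=2,
            )

    k0, amp0, off0 = _warm_start(t, y)

    def model(tt, k, amp, off):
        return off + amp * np.exp(-k * tt)

    popt, _ = optimize.curve_fit(
        model, t, y, p0=[k0, amp0, off0], bounds=([0.0, -np.inf, -np.inf], np.inf),
        maxfev=20000,
    )
    resid = y - model(t, *popt)
    return AbsorbanceFit(
        k=float(popt[0]),
        amplitude=float(popt[1]),
        offset=float(popt[2]),
        window=(float(t0), float(t1)),
        residual_norm=float(np.sqrt(np.mean(resid**2))),
    )


def fit_kd(trace_445: KineticCurve, window_fast: tuple, window_slow: tuple) -> tuple:
    """Estimate the apparent flavin-autoxidation constant from a 445-nm trace.

    The absorbance change after mixing reduced flavin with aerated buffer is
    biphasic; the procedure approximates two disjoint time ranges with
    independent exponentials. The slow-window rate is reported as the
    apparent ``kd``.

    Returns ``(fit_fast, fit_slow)``; ``fit_slow.k`` is kd in 1/s.
    """
    if window_fast[1] > window_slow[0]:
        raise ValueError(
            f"windows must be disjoint and ordered: {window_fast} vs {window_slow}"
        )
    fit_fast = fit_exponential(trace_445, window_fast)
    fit_slow = fit_exponential(trace_445, window_slow)
    return fit_fast, fit_slow


def fit_kdd(trace_380: KineticCurve, window: tuple) -> AbsorbanceFit:
    """Estimate the peroxyflavin dark-decay constant from a 380-nm trace.

    Single-exponential fit (free offset) on the chosen window; the fitted
    rate is ``kdd`` in 1/s.
    """
    return fit_exponential(trace_380, window)
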
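"""Global fitting of elementary rate constants to single-turnover progress curves.

The estimation problem
----------------------
Five bioluminescence curves recorded at different decanal concentrations
(sharing enzyme and flavin concentrations) are fitted *simultaneously* by the
mass-action model of :mod:`luxkin.reaction_model`. The free parameters are the
five elementary rate constants ``k1, k2, k3, k_minus3, k4`` plus one shared
intensity scale; the dark-decay constants ``kd`` and ``kdd`` are always fixed,
because they are measured in separate absorbance experiments. The objective is
the pooled least-squares error over all curves.

Numerical strategy: bound-constrained trust-region least squares in log10
parameter space, multi-start (log-uniform draws within the bounds) for
robustness to local minima, and the shared scale solved in closed form at each
objective evaluation (the model is linear in it).

Usage follows the Model/Results convention::

    model = SingleTurnoverModel(dataset, kd=0.5, kdd=0.1)
    res = model.fit(n_starts=16, seed=1)
    print(res.summary())
    res.rates, res.pooled_rel_error_pct, res.michaelis_constants()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .reaction_model import (
    InitialConditions,
    KineticCurve,
    RateConstants,
    simulate_states,
)

__all__ = [
    "SingleTurnoverDataset",
    "FitSpec",
    "MichaelisConstants",
    "SingleTurnoverModel",
    "SingleTurnoverResults",
    "FitError",
    "fit_rate_constants",
    "michaelis_constants",
    "pooled_relative_error",
    "DEFAULT_BOUNDS",
]

FREE_PARAMS = ("k1", "k2", "k3", "k_minus3", "k4")

#: Default box bounds bracketing literature magnitudes for flavin
#: monooxygenase kinetics (k1, k3 in 1/(M*s); k2, k_minus3, k4 in 1/s).
DEFAULT_BOUNDS = {
    "k1": (1e4, 1e9),
    "k2": (1e0, 1e4),
    "k3": (1e4, 1e9),
    "k_minus3": (1e-3, 1e2),
    "k4": (1e-3, 1e2),
}


class FitError(RuntimeError):
    """Raised when no optimization start converges."""


@dataclass
class SingleTurnoverDataset:
    """A set of bioluminescence curves differing only in aldehyde concentration.

    Attributes
    ----------
    curves : list of KineticCurve
        One intensity curve per aldehyde concentration.
    L0, F0 : float
        Shared post-mixing luciferase and FMNH2 concentrations, M.
    A0_list : list of float
        Post-mixing decanal concentration of each curve, M.
    """

    curves: list
    L0: float = 1e-6
    F0: float = 15e-6
    A0_list: Sequence[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.A0_list) != len(self.curves):
            raise ValueError("need one aldehyde concentration per curve")
        if len(self.curves) == 0:
            raise ValueError("dataset is empty")
        for a in self.A0_list:
            if a < 0:
                raise ValueError("aldehyde concentrations must be nonnegative")

    def __len__(self) -> int:
        return len(self.curves)

    @classmethod
    def from_curves(cls, curves: Sequence[KineticCurve]) -> "SingleTurnoverDataset":
        """Build a dataset from curves whose meta carries L0_M/F0_M/A0_M."""
        A0 = [c.meta["A0_M"] for c in curves]
        L0 = {c.meta["L0_M"] for c in curves}
        F0 = {c.meta["F0_M"] for c in curves}
        if len(L0) != 1 or len(F0) != 1:
            raise ValueError("curves do not share luciferase/flavin concentrations")
        return cls(curves=list(curves), L0=L0.pop(), F0=F0.pop(), A0_list=A0)


@dataclass
class FitSpec:
    """Declarative description of one global fit (thin wrapper interface)."""

    dataset: SingleTurnoverDataset
    kd: float
    kdd: float
    bounds: dict | None = None
    x0: RateConstants | None = None
    n_starts: int = 16
    seed: int = 0


@dataclass(frozen=True)
class MichaelisConstants:
    """Michaelis constants implied by the elementary rate constants (M)."""

    KM_F: float  # for reduced flavin: k2 / k1
    KM_a: float  # for decanal: (k_minus3 + k4) / k3


def michaelis_constants(rates: RateConstants) -> MichaelisConstants:
    """KM for reduced flavin (k2/k1) and decanal ((k_minus3 + k4)/k3)."""
    if rates.k1 <= 0 or rates.k3 <= 0:
        raise ZeroDivisionError("k1 and k3 must be positive to form Michaelis constants")
    return MichaelisConstants(
        KM_F=rates.k2 / rates.k1,
        KM_a=(rates.k_minus3 + rates.k4) / rates.k3,
    )


def pooled_relative_error(model_curves, data_curves):
    """Relative L2 fit error, pooled over curves and per curve, in percent.

    pooled = 100 * ||y_model - y_data||_2 / ||y_data||_2 with the norms taken
    over all points of all curves concatenated.

    Returns
    -------
    (pooled_pct, per_curve_pct) : (float, list of float)
    """
    if len(model_curves) != len(data_curves):
        raise ValueError("curve count mismatch")
    res_sq, dat_sq, per_curve = 0.0, 0.0, []
    for m, d in zip(model_curves, data_curves):
        ym = np.asarray(m.y if hasattr(m, "y") else m, dtype=float)
        yd = np.asarray(d.y if hasattr(d, "y") else d, dtype=float)
        if ym.shape != yd.shape:
            raise ValueError("grid mismatch between model and data curve")
        r = float(np.sum((ym - yd) ** 2))
        s = float(np.sum(yd**2))
        if s == 0.0:
            raise ZeroDivisionError("all-zero data curve: relative error undefined")
        per_curve.append(100.0 * np.sqrt(r / s))
        res_sq += r
        dat_sq += s
    return 100.0 * float(np.sqrt(res_sq / dat_sq)), per_curve


class SingleTurnoverModel:
    """Kinetic model of a five-curve single-turnover dataset.

    Parameters
    ----------
    dataset : SingleTurnoverDataset
    kd, kdd : float
        Dark-decay constants (1/s), fixed during the fit; obtained from the
        absorbance experiments (see :mod:`luxkin.dark_decay`).
    bounds : dict, optional
        ``{name: (lo, hi)}`` overrides of :data:`DEFAULT_BOUNDS`; lower bounds
        must be positive (the search runs in log10 space).
    ode_rtol : float
        Relative tolerance of the inner ODE solves.
    """

    def __init__(self, dataset, kd, kdd, bounds=None, ode_rtol=1e-8):
        if kd < 0 or kdd < 0:
            raise ValueError("kd and kdd must be nonnegative")
        self.dataset = dataset
        self.kd = float(kd)
        self.kdd = float(kdd)
        self.ode_rtol = float(ode_rtol)
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        for name in FREE_PARAMS:
            lo, hi = self.bounds[name]
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name} must satisfy 0 < lo < hi")
        self._y_data = [np.asarray(c.y, dtype=float) for c in dataset.curves]
        self._y_norm = np.sqrt(sum(float(np.sum(y**2)) for y in self._y_data))
        if self._y_norm == 0:
            raise ValueError("dataset has all-zero intensities")

    # -- parameter transforms -------------------------------------------------

    def _theta_to_rates(self, theta, scale=1.0) -> RateConstants:
        k = 10.0 ** np.asarray(theta, dtype=float)
        return RateConstants(
            k1=k[0], k2=k[1], k3=k[2], k_minus3=k[3], k4=k[4],
            kd=self.kd, kdd=self.kdd, scale=scale,
        )

    def _log_bounds(self):
        lo = np.log10([self.bounds[n][0] for n in FREE_PARAMS])
        hi = np.log10([self.bounds[n][1] for n in FREE_PARAMS])
        return lo, hi

    # -- objective ------------------------------------------------------------

    def _model_profiles(self, theta):
        """Unscaled model intensities k4*I2A(t) for every curve."""
        rates = self._theta_to_rates(theta)
        out = []
        for curve, A0 in zip(self.dataset.curves, self.dataset.A0_list):
            ic = InitialConditions(L0=self.dataset.L0, F0=self.dataset.F0, A0=A0)
            states = simulate_states(rates, ic, curve.t, rtol=self.ode_rtol)
            out.append(rates.k4 * states[:, 4])
        return out

    def _residuals(self, theta):
        profiles = self._model_profiles(theta)
        m = np.concatenate(profiles)
        y = np.concatenate(self._y_data)
        # model is linear in the shared intensity scale: solve it exactly
        mm = float(m @ m)
        scale = max(float(m @ y) / mm, 0.0) if mm > 0 else 0.0
        return scale * m - y, scale

    def _cost_residuals(self, theta):
        return self._residuals(theta)[0]

    # -- fitting --------------------------------------------------------------

    def _draw_starts(self, n_starts, seed, x0):
        lo, hi = self._log_bounds()
        starts = []
        if x0 is not None:
            t0 = np.log10([getattr(x0, n) for n in FREE_PARAMS])
            starts.append(np.clip(t0, lo, hi))
        else:
            starts.append(0.5 * (lo + hi))  # geometric center of the box
        rng = np.random.default_rng(seed)
        while len(starts) < n_starts:
            starts.append(rng.uniform(lo, hi))
        return starts

    def fit(
        self,
        n_starts=16,
        seed=0,
        x0=None,
        n_refine=3,
        triage_max_nfev=40,
        triage_rtol=1e-6,
        refine_cost_factor=10.0,
        max_nfev=200,
    ) -> "SingleTurnoverResults":
        """Run the multi-start global fit (triage + refinement).

        Every start is first optimized cheaply (ODE rtol ``triage_rtol``,
        at most ``triage_max_nfev`` objective evaluations); the ``n_refine``
        lowest-cost candidates are then polished at the model's full ODE
        tolerance with tight convergence criteria, and the best polished
        solution wins. The landscape has well-separated local basins (a
        collapsed-intermediate branch mimics the curves at high cost), so the
        cheap triage ranks basins reliably.

        Parameters
        ----------
        n_starts : int
            Number of starts: the first is ``x0`` (or the geometric center of
            the bounds box), the rest are log-uniform draws within the bounds.
            Deterministic given ``seed``.
        seed : int
            Seed for the start draws.
        x0 : RateConstants, optional
            Warm start.
        n_refine : int
            Number of triage winners polished at full tolerance.
        triage_max_nfev, triage_rtol : int, float
            Evaluation cap and ODE tolerance of the triage stage.
        refine_cost_factor : float
            Candidates whose triage cost exceeds the best triage cost by more
            than this factor are clearly-lost basins and are not polished.
        max_nfev : int
            Evaluation cap of each refinement.

        Returns
        -------
        SingleTurnoverResults
        """
        lo, hi = self._log_bounds()

        def _minimize(theta0, rtol, nfev_cap, tol):
            saved = self.ode_rtol
            self.ode_rtol = rtol
            try:
                return least_squares(
                    self._cost_residuals,
                    theta0,
                    bounds=(lo, hi),
                    method="trf",
                    xtol=tol,
                    ftol=tol,
                    gtol=tol,
                    max_nfev=nfev_cap,
                )
            finally:
                self.ode_rtol = saved

        triaged = []
        for idx, theta0 in enumerate(self._draw_starts(n_starts, seed, x0)):
            try:
                sol = _minimize(theta0, triage_rtol, triage_max_nfev, 1e-8)
            except Exception:  # a diverging start must not kill the sweep
                continue
            triaged.append((sol.cost, idx, sol))
        if not triaged:
            raise FitError(f"all {n_starts} optimization starts diverged")

        triaged.sort(key=lambda c: c[0])
        cost_cut = triaged[0][0] * refine_cost_factor
        candidates = [c for c in triaged[: max(n_refine, 1)] if c[0] <= cost_cut]
        refined = []
        for cost, idx, sol in candidates:
            try:
                polished = _minimize(sol.x, self.ode_rtol, max_nfev, 1e-12)
            except Exception:
                continue
            refined.append((polished.cost, idx, polished))
        if not refined:
            raise FitError(
                f"refinement failed for all {n_refine} triage winners "
                f"(triage costs: {[c for c, _, _ in triaged[:n_refine]]})"
            )
        refined.sort(key=lambda c: c[0])
        _, best_idx, best = refined[0]
        _, scale = self._residuals(best.x)
        rates = self._theta_to_rates(best.x, scale=scale)
        return SingleTurnoverResults(self, rates, best, best_idx, len(triaged))


class SingleTurnoverResults:
    """Estimates and diagnostics of a :class:`SingleTurnoverModel` fit.

    Attributes
    ----------
    rates : RateConstants
        Fitted rate constants (with the fixed kd/kdd and the fitted scale).
    rss : float
        Residual sum of squares.
    pooled_rel_error_pct : float
        100 * ||residual|| / ||data|| pooled over all curves.
    per_curve_rel_error_pct : list of float
    rel_stderr : dict
        Approximate relative standard error of each free rate constant, from
        the Gauss-Newton covariance in log10 space. Values >> 1 flag a
        practically unidentifiable parameter.
    param_correlations : ndarray
        Correlation matrix of the log10 parameter estimates (order
        :data:`FREE_PARAMS`). Entries near +/-1 mark sloppy directions:
        parameter combinations the data cannot separate, typical of a
        single-aldehyde-concentration dataset.
    """

    def __init__(self, model, rates, solution, start_index, n_converged):
        self.model = model
        self.rates = rates
        self.start_index = start_index
        self.n_converged = n_converged
        self.theta = solution.x
        self.rss = float(2.0 * solution.cost)
        self.nfev = solution.nfev
        self.status = solution.status
        self.message = solution.message
        fitted = self.fitted_curves()
        self.pooled_rel_error_pct, self.per_curve_rel_error_pct = pooled_relative_error(
            fitted, model.dataset.curves
        )
        self.rel_stderr, self.param_correlations = self._uncertainty(solution)

    def _uncertainty(self, solution):
        # Gauss-Newton covariance of log10-parameters; sigma^2 from residuals.
        J = solution.jac
        r = solution.fun
        n_par = len(solution.x)
        dof = max(len(r) - n_par, 1)
        sigma2 = float(r @ r) / dof
        JtJ = J.T @ J
        try:
            cov = sigma2 * np.linalg.pinv(JtJ)
            var = np.clip(np.diag(cov), 0.0, None)
            sd_log10 = np.sqrt(var)
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = cov / np.outer(np.sqrt(var), np.sqrt(var))
            corr = np.where(np.isfinite(corr), corr, 1.0)
        except np.linalg.LinAlgError:
            sd_log10 = np.full(n_par, np.inf)
            corr = np.full((n_par, n_par), 1.0)
        # relative error on the natural scale: |d k / k| = ln(10) * sd(log10 k)
        rel = {
            name: float(np.log(10.0) * sd)
            for name, sd in zip(FREE_PARAMS, sd_log10)
        }
        return rel, corr

    def fitted_curves(self):
        """Model curves on the data grids at the fitted parameters."""
        profiles = self.model._model_profiles(self.theta)
        out = []
        for curve, prof in zip(self.model.dataset.curves, profiles):
            out.append(
                KineticCurve(
                    t=curve.t,
                    y=self.rates.scale * prof,
                    signal_kind="bioluminescence",
                    meta=dict(curve.meta),
                )
            )
        return out

    def michaelis_constants(self) -> MichaelisConstants:
        return michaelis_constants(self.rates)

    @property
    def poorly_identified(self) -> list:
        """Parameters that the data do not pin down.

        A parameter is flagged when its relative standard error exceeds 100%
        or when it sits in a near-degenerate pair (|correlation| >= 0.99 of
        the log-estimates), i.e. only a combination of the pair is
        determined. A dataset with a single aldehyde concentration flags the
        aldehyde-binding parameters this way.
        """
        flagged = {
            n for n, v in self.rel_stderr.items() if not np.isfinite(v) or v > 1.0
        }
        corr = self.param_correlations
        for i, ni in enumerate(FREE_PARAMS):
            for j in range(i + 1, len(FREE_PARAMS)):
                if abs(corr[i, j]) >= 0.99:
                    flagged.update((ni, FREE_PARAMS[j]))
        return sorted(flagged)

    def as_dict(self) -> dict:
        km = self.michaelis_constants()
        return {
            "rates": self.rates.as_dict(),
            "rss": self.rss,
            "pooled_rel_error_pct": self.pooled_rel_error_pct,
            "per_curve_rel_error_pct": self.per_curve_rel_error_pct,
            "rel_stderr": self.rel_stderr,
            "poorly_identified": self.poorly_identified,
            "KM_F_M": km.KM_F,
            "KM_a_M": km.KM_a,
            "start_index": self.start_index,
            "n_converged": self.n_converged,
            "nfev": self.nfev,
            "status": self.status,
        }

    def summary(self) -> str:
        km = self.michaelis_constants()
        units = {"k1": "1/(M*s)", "k2": "1/s", "k3": "1/(M*s)", "k_minus3": "1/s", "k4": "1/s"}
        lines = [
            "Single-turnover global kinetic fit",
            "=" * 54,
            f"curves: {len(self.model.dataset)}   "
            f"points: {sum(len(c) for c in self.model.dataset.curves)}",
            f"fixed: kd = {self.rates.kd:g} 1/s, kdd = {self.rates.kdd:g} 1/s",
            "-" * 54,
            f"{'param':>9} {'estimate':>12} {'rel. SE':>9}  unit",
        ]
        for name in FREE_PARAMS:
            lines.append(
                f"{name:>9} {getattr(self.rates, name):>12.4g} "
                f"{self.rel_stderr[name]:>8.1%}  {units[name]}"
            )
        lines += [
            f"{'scale':>9} {self.rates.scale:>12.4g} {'':>9}  a.u.*s/M",
            "-" * 54,
            f"pooled relative error: {self.pooled_rel_error_pct:.2f}%   RSS: {self.rss:.4g}",
            f"K_M(FMNH2) = {km.KM_F * 1e6:.2f} uM   K_M(decanal) = {km.KM_a * 1e6:.2f} uM",
        ]
        if self.poorly_identified:
            lines.append(f"WARNING poorly identified: {', '.join(self.poorly_identified)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data and fitted curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for curve, fit in zip(self.model.dataset.curves, self.fitted_curves()):
            lbl = f"{curve.meta.get('A0_M', 0) * 1e6:g} uM"
            ax.plot(curve.t, curve.y, ".", ms=2, alpha=0.5)
            ax.plot(fit.t, fit.y, "-", label=lbl)
        ax.set_xlabel("time, s")
        ax.set_ylabel("intensity, a.u.")
        ax.legend(title="decanal", fontsize=8)
        return ax


def fit_rate_constants(spec: FitSpec) -> SingleTurnoverResults:
    """Functional wrapper: run the global fit described by a :class:`FitSpec`."""
    model = SingleTurnoverModel(spec.dataset, kd=spec.kd, kdd=spec.kdd, bounds=spec.bounds)
    return model.fit(n_starts=spec.n_starts, seed=spec.seed, x0=spec.x0)
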
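"""Mass-action ODE model of the single-turnover bacterial-luciferase reaction.

The reaction scheme
-------------------
Bacterial luciferase (L) binds reduced flavin mononucleotide (F, FMNH2) to
form Intermediate I, which binds dissolved oxygen to give the C(4a)-peroxyflavin
Intermediate II. Intermediate II either decays in the dark (rate ``kdd``,
releasing the enzyme and oxidized flavin) or binds a long-chain aldehyde (A,
decanal) to form Intermediate IIA, which reacts through the excited emitter
(Intermediate III, not resolved as a separate state) with the catalytic
constant ``k4``, emitting a photon and releasing the enzyme. Free FMNH2 is
meanwhile autoxidized by dissolved oxygen (apparent rate ``kd``), which is what
limits each enzyme molecule to essentially a single turnover.

State vector (all concentrations in M)::

    L, F, I1, I2, I2A, A, Fox, P

where ``Fox`` collects oxidized flavin produced by the dark pathways and ``P``
the carboxylic-acid/FMN product of the light pathway. Oxygen is
air-equilibrated excess and folded into the pseudo-first-order rate ``k2``.

Bioluminescence intensity is proportional to the flux through the emitting
step: ``y(t) = scale * k4 * [I2A](t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "InitialConditions",
    "KineticCurve",
    "SPECIES",
    "ode_rhs",
    "simulate_curve",
    "simulate_states",
    "bateman_oracle",
    "IntegrationError",
]

#: Order of the state variables in the packed state vector.
SPECIES = ("L", "F", "I1", "I2", "I2A", "A", "Fox", "P")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a trajectory."""


@dataclass(frozen=True)
class RateConstants:
    """Elementary rate constants of the reaction scheme.

    Parameters
    ----------
    k1 : float
        Flavin-binding rate, 1/(M*s).
    k2 : float
        Pseudo-first-order oxygen-binding rate, 1/s (dissolved O2 in excess).
    k3 : float
        Aldehyde-binding rate, 1/(M*s).
    k_minus3 : float
        Aldehyde dissociation rate, 1/s.
    k4 : float
        Catalytic constant of the light-emitting step, 1/s.
    kd : float
        Apparent autoxidation rate of free FMNH2, 1/s.
    kdd : float
        Dark-decay rate of the peroxyflavin Intermediate II, 1/s.
    scale : float
        Intensity scale factor (quantum yield times instrument gain),
        a.u.*s/M; nonnegative.
    """

    k1: float
    k2: float
    k3: float
    k_minus3: float
    k4: float
    kd: float
    kdd: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k_minus3", "k4", "kd", "kdd", "scale"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v!r}")

    def replace(self, **kwargs) -> "RateConstants":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "k_minus3": self.k_minus3,
            "k4": self.k4,
            "kd": self.kd,
            "kdd": self.kdd,
            "scale": self.scale,
        }


@dataclass(frozen=True)
class InitialConditions:
    """Post-mixing concentrations at t = 0 (all in M).

    Defaults are the study conditions of the single-turnover stopped-flow
    assay: 1 uM luciferase, 15 uM FMNH2, decanal varied over 10-50 uM.
    All intermediates and sinks start at zero.
    """

    L0: float = 1e-6
    F0: float = 15e-6
    A0: float = 50e-6

    def __post_init__(self) -> None:
        for name in ("L0", "F0", "A0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v!r}")

    def state0(self) -> np.ndarray:
        """Packed initial state vector in the :data:`SPECIES` order."""
        y0 = np.zeros(len(SPECIES))
        y0[0] = self.L0
        y0[1] = self.F0
        y0[5] = self.A0
        return y0


@dataclass
class KineticCurve:
    """A sampled time series of a kinetic signal.

    Attributes
    ----------
    t : ndarray
        Time grid in seconds, strictly increasing, starting at 0 by
        convention for simulated curves.
    y : ndarray
        Signal values (intensity in a.u. or absorbance in AU).
    signal_kind : str
        One of ``bioluminescence``, ``absorbance_445``, ``absorbance_380``.
    meta : dict
        Condition labels (cosolvent, wt %, viscosity in cP, decanal in uM...).
    """

    t: np.ndarray
    y: np.ndarray
    signal_kind: str = "bioluminescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1:
            raise ValueError("t and y must be one-dimensional")
        if len(self.t) != len(self.y):
            raise ValueError(f"length mismatch: {len(self.t)} times, {len(self.y)} values")
        if len(self.t) < 2:
            raise ValueError("a curve needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def _unpack_rates(rates: RateConstants):
    return (rates.k1, rates.k2, rates.k3, rates.k_minus3, rates.k4, rates.kd, rates.kdd)


def ode_rhs(
    state: Sequence[float],
    rates: RateConstants,
    *,
    pseudo_first_order: bool = False,
) -> np.ndarray:
    """Mass-action right-hand side d(state)/dt for the reaction scheme.

    Parameters
    ----------
    state : sequence of 8 floats
        Concentrations ``(L, F, I1, I2, I2A, A, Fox, P)`` in M.
    rates : RateConstants
    pseudo_first_order : bool
        If True, free luciferase and free aldehyde are treated as inexhaustible
        reservoirs (dL = dA = 0): the linear-chain limit used when L0 and A0
        are in large excess over F0.

    Returns
    -------
    ndarray
        Time derivatives in the same order, M/s.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (len(SPECIES),):
        raise ValueError(f"state must have {len(SPECIES)} components, got shape {y.shape}")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("state concentrations must be finite and nonnegative")
    k1, k2, k3, k_minus3, k4, kd, kdd = _unpack_rates(rates)
    L, F, I1, I2, I2A, A, Fox, P = y

    bind_F = k1 * L * F
    bind_A = k3 * I2 * A
    dark_I2 = kdd * I2
    emit = k4 * I2A
    release_A = k_minus3 * I2A

    d = np.empty_like(y)
    d[0] = -bind_F + dark_I2 + emit          # L: consumed on binding, recycled
    d[1] = -bind_F - kd * F                  # F: binding + autoxidation
    d[2] = bind_F - k2 * I1                  # Intermediate I
    d[3] = k2 * I1 - bind_A + release_A - dark_I2   # Intermediate II
    d[4] = bind_A - release_A - emit         # Intermediate IIA
    d[5] = -bind_A + release_A               # free aldehyde
    d[6] = kd * F + dark_I2                  # oxidized-flavin sink
    d[7] = emit                              # light-pathway product sink
    if pseudo_first_order:
        d[0] = 0.0
        d[5] = 0.0
    return d


def _rhs_raw(t, y, k1, k2, k3, k_minus3, k4, kd, kdd, pfo):
    # Hot path for solve_ivp: no validation, plain floats.
    L, F, I1, I2, I2A, A = y[0], y[1], y[2], y[3], y[4], y[5]
    bind_F = k1 * L * F
    bind_A = k3 * I2 * A
    dark_I2 = kdd * I2
    emit = k4 * I2A
    release_A = k_minus3 * I2A
    dL = 0.0 if pfo else -bind_F + dark_I2 + emit
    dA = 0.0 if pfo else -bind_A + release_A
    return (
        dL,
        -bind_F - kd * F,
        bind_F - k2 * I1,
        k2 * I1 - bind_A + release_A - dark_I2,
        bind_A - release_A - emit,
        dA,
        kd * F + dark_I2,
        emit,
    )


def _jac_raw(t, y, k1, k2, k3, k_minus3, k4, kd, kdd, pfo):
    L, F, I2, A = y[0], y[1], y[3], y[5]
    J = np.zeros((8, 8))
    # d(bind_F)/dL = k1*F, /dF = k1*L ; d(bind_A)/dI2 = k3*A, /dA = k3*I2
    if not pfo:
        J[0, 0] = -k1 * F
        J[0, 1] = -k1 * L
        J[0, 3] = kdd
        J[0, 4] = k4
        J[5, 3] = -k3 * A
        J[5, 4] = k_minus3
        J[5, 5] = -k3 * I2
    J[1, 0] = -k1 * F
    J[1, 1] = -k1 * L - kd
    J[2, 0] = k1 * F
    J[2, 1] = k1 * L
    J[2, 2] = -k2
    J[3, 2] = k2
    J[3, 3] = -k3 * A - kdd
    J[3, 4] = k_minus3
    J[3, 5] = -k3 * I2
    J[4, 3] = k3 * A
    J[4, 4] = -k_minus3 - k4
    J[4, 5] = k3 * I2
    J[6, 1] = kd
    J[6, 3] = kdd
    J[7, 4] = k4
    return J


def simulate_states(
    rates: RateConstants,
    ic: InitialConditions,
    t_grid: np.ndarray,
    *,
    pseudo_first_order: bool = False,
    rtol: float = 1e-8,
    atol_factor: float = 1e-12,
) -> np.ndarray:
    """Integrate the scheme and return the full state trajectory.

    Returns an array of shape ``(len(t_grid), 8)`` in the :data:`SPECIES`
    order. Uses LSODA (stiff-capable, adaptive) with an analytic Jacobian,
    rtol 1e-8 and atol ``atol_factor * max(F0, A0, L0)``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t_grid must be one-dimensional with at least 2 points")
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")

    conc_scale = max(ic.F0, ic.A0, ic.L0, 1e-30)
    args = (*_unpack_rates(rates), pseudo_first_order)
    sol = solve_ivp(
        _rhs_raw,
        (t[0], t[-1]),
        ic.state0(),
        method="LSODA",
        t_eval=t,
        args=args,
        jac=_jac_raw,
        rtol=rtol,
        atol=atol_factor * conc_scale,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed: {sol.message} "
            f"(rates={rates.as_dict()}, L0={ic.L0}, F0={ic.F0}, A0={ic.A0})"
        )
    states = sol.y.T
    # Clip solver-tolerance negatives; anything worse is a real failure.
    floor = -1e-9 * conc_scale
    if states.min() < floor:
        raise IntegrationError(
            f"negative concentration {states.min():.3e} beyond tolerance {floor:.3e}"
        )
    return np.clip(states, 0.0, None)


def simulate_curve(
    rates: RateConstants,
    ic: InitialConditions,
    t_grid: np.ndarray,
    *,
    pseudo_first_order: bool = False,
    rtol: float = 1e-8,
) -> KineticCurve:
    """Simulate a bioluminescence intensity curve y(t) = scale * k4 * [I2A](t).

    Parameters
    ----------
    rates : RateConstants
    ic : InitialConditions
        Post-mixing concentrations.
    t_grid : ndarray
        Output time grid in s, strictly increasing from 0 (default experiment
        length is 15 s).
    pseudo_first_order : bool
        Clamp free L and A at their initial values (excess-reservoir limit).
    """
    states = simulate_states(
        rates, ic, t_grid, pseudo_first_order=pseudo_first_order, rtol=rtol
    )
    y = rates.scale * rates.k4 * states[:, 4]
    meta = {"L0_M": ic.L0, "F0_M": ic.F0, "A0_M": ic.A0}
    return KineticCurve(t=np.asarray(t_grid, dtype=float), y=y, meta=meta)


def bateman_oracle(a: float, b: float, c: float, k4: float, F0: float, t) -> np.ndarray:
    """Closed-form concentration of the fourth species in a linear decay chain.

    Analytic oracle for the pseudo-first-order limit of the scheme: the chain
    ``F -> I1 -> I2 -> I2A -> P`` with first-order rates ``a = k1*L0``, ``b = k2``,
    ``c = k3*A0`` and ``k4``, starting from ``F(0) = F0``. Returns [I2A](t) by the
    standard sequential-first-order (Bateman) solution

        I2A(t) = F0 * a*b*c * sum_i exp(-lam_i t) / prod_{j != i}(lam_j - lam_i)

    over the four rates. Requires pairwise-distinct rates (perturb slightly
    for degenerate cases).
    """
    lam = np.array([a, b, c, k4], dtype=float)
    if np.any(lam <= 0):
        raise ValueError("all chain rates must be positive")
    if len(np.unique(lam)) != 4:
        raise ValueError("chain rates must be pairwise distinct (perturb to break ties)")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for i in range(4):
        denom = 1.0
        for j in range(4):
            if j != i:
                denom *= lam[j] - lam[i]
        out = out + np.exp(-lam[i] * t) / denom
    return F0 * a * b * c * out
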
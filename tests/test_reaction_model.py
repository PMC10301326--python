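"""The ODE right-hand side, the integrator, and the analytic Bateman oracle."""

import numpy as np
import pytest

from luxkin import (
    InitialConditions,
    RateConstants,
    bateman_oracle,
    ode_rhs,
    simulate_curve,
)
from luxkin.reaction_model import SPECIES, simulate_states

# Frozen by dense-grid RK4 integration (step 1e-5 s) of the linear chain
# F -> I1 -> I2 -> I2A -> P with a=5, b=100, c=1, k4=0.5 1/s, F0=1e-6 M.
BATEMAN_I2A_AT_1S = 4.276006776346e-07


def _random_state(rng):
    return rng.uniform(0.0, 1e-5, size=len(SPECIES))


def _random_rates(rng):
    return RateConstants(
        k1=10 ** rng.uniform(4, 8),
        k2=10 ** rng.uniform(0, 3),
        k3=10 ** rng.uniform(4, 7),
        k_minus3=10 ** rng.uniform(-2, 2),
        k4=10 ** rng.uniform(-2, 2),
        kd=rng.uniform(0, 2),
        kdd=rng.uniform(0, 1),
    )


class TestOdeRhs:
    def test_empty_system_is_stationary(self, true_rates):
        assert np.all(ode_rhs(np.zeros(8), true_rates) == 0.0)

    def test_blocked_entry_no_flux_into_chain(self, true_rates):
        # k1 = 0 and an empty chain: nothing can enter I1/I2/I2A/P
        rates = true_rates.replace(k1=0.0)
        state = np.array([1e-6, 15e-6, 0.0, 0.0, 0.0, 50e-6, 0.0, 0.0])
        d = ode_rhs(state, rates)
        for idx in (2, 3, 4, 7):  # I1, I2, I2A, P
            assert d[idx] == 0.0

    def test_flavin_derivatives_cancel_at_random_points(self):
        # total flavin F + I1 + I2 + I2A + Fox + P is conserved by construction
        rng = np.random.default_rng(42)
        for _ in range(1000):
            d = ode_rhs(_random_state(rng), _random_rates(rng))
            flavin_flux = d[1] + d[2] + d[3] + d[4] + d[6] + d[7]
            assert abs(flavin_flux) <= 1e-12 * np.max(np.abs(d))

    def test_aldehyde_derivatives_cancel_at_random_points(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            d = ode_rhs(_random_state(rng), _random_rates(rng))
            assert abs(d[5] + d[4] + d[7]) <= 1e-12 * np.max(np.abs(d))

    def test_negative_concentration_rejected(self, true_rates):
        state = np.zeros(8)
        state[1] = -1e-9
        with pytest.raises(ValueError):
            ode_rhs(state, true_rates)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(k1=-1, k2=1, k3=1, k_minus3=1, k4=1, kd=0, kdd=0)


class TestSimulateCurve:
    def test_no_enzyme_flavin_complex_zero_intensity(self, true_rates, t15, default_ic):
        curve = simulate_curve(true_rates.replace(k1=0.0), default_ic, t15)
        assert np.allclose(curve.y, 0.0, atol=1e-20)

    def test_no_aldehyde_zero_intensity(self, true_rates, t15):
        ic = InitialConditions(L0=1e-6, F0=15e-6, A0=0.0)
        curve = simulate_curve(true_rates, ic, t15)
        assert np.allclose(curve.y, 0.0, atol=1e-20)

    @pytest.mark.parametrize("A0_uM", [10.0, 30.0, 50.0])
    def test_mass_conservation_along_trajectory(self, true_rates, t15, A0_uM):
        ic = InitialConditions(L0=1e-6, F0=15e-6, A0=A0_uM * 1e-6)
        s = simulate_states(true_rates, ic, t15)
        flavin = s[:, 1] + s[:, 2] + s[:, 3] + s[:, 4] + s[:, 6] + s[:, 7]
        aldehyde = s[:, 5] + s[:, 4] + s[:, 7]
        assert np.max(np.abs(flavin - ic.F0)) / ic.F0 < 1e-6
        assert np.max(np.abs(aldehyde - ic.A0)) / ic.A0 < 1e-6
        assert s.min() >= -1e-9 * ic.F0

    def test_flash_like_shape(self, true_rates, t15, default_ic):
        # rises from zero to a peak within a few seconds, then decays
        curve = simulate_curve(true_rates, default_ic, t15)
        ipeak = int(np.argmax(curve.y))
        assert curve.y[0] == 0.0
        assert 0.1 < curve.t[ipeak] < 5.0
        assert curve.y[-1] < 0.05 * curve.y[ipeak]

    def test_grid_must_start_at_zero(self, true_rates, default_ic):
        with pytest.raises(ValueError):
            simulate_curve(true_rates, default_ic, np.linspace(1.0, 15.0, 100))

    def test_quantum_yield_monotone_in_kdd_and_k3(self, true_rates, t15, default_ic):
        # Q* falls as dark decay strengthens, rises as aldehyde binding speeds up
        areas_kdd = []
        for kdd in (0.01, 0.1, 0.5, 2.0):
            c = simulate_curve(true_rates.replace(kdd=kdd), default_ic, t15)
            areas_kdd.append(np.trapezoid(c.y, c.t))
        assert all(a >= b - 1e-9 * abs(a) for a, b in zip(areas_kdd, areas_kdd[1:]))

        areas_k3 = []
        for k3 in (1e4, 1e5, 1e6):
            c = simulate_curve(true_rates.replace(k3=k3), default_ic, t15)
            areas_k3.append(np.trapezoid(c.y, c.t))
        assert all(b >= a - 1e-9 * abs(b) for a, b in zip(areas_k3, areas_k3[1:]))


class TestBatemanOracle:
    def test_zero_at_start_and_drained_at_infinity(self):
        assert bateman_oracle(5.0, 100.0, 1.0, 0.5, 1e-6, 0.0) == 0.0
        assert bateman_oracle(5.0, 100.0, 1.0, 0.5, 1e-6, 1e4) < 1e-25

    def test_against_fine_step_integration(self):
        val = bateman_oracle(5.0, 100.0, 1.0, 0.5, 1e-6, 1.0)
        assert val == pytest.approx(BATEMAN_I2A_AT_1S, rel=1e-9)

    def test_repeated_rates_rejected(self):
        with pytest.raises(ValueError):
            bateman_oracle(1.0, 1.0, 2.0, 3.0, 1e-6, 0.5)

    def test_simulator_matches_oracle_in_pseudo_first_order_limit(self):
        # L and A clamped as excess reservoirs; kd = kdd = k_minus3 = 0:
        # the scheme collapses to the linear chain the closed form solves.
        L0, F0, A0 = 1e-3, 1e-6, 50e-6
        k1, k2, k3, k4 = 5e3, 100.0, 2e4, 0.5
        rates = RateConstants(k1=k1, k2=k2, k3=k3, k_minus3=0.0, k4=k4, kd=0.0, kdd=0.0)
        ic = InitialConditions(L0=L0, F0=F0, A0=A0)
        t = np.linspace(0.0, 15.0, 400)
        s = simulate_states(rates, ic, t, pseudo_first_order=True)
        expected = bateman_oracle(k1 * L0, k2, k3 * A0, k4, F0, t)
        scale = np.max(expected)
        assert np.max(np.abs(s[:, 4] - expected)) / scale < 1e-5
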
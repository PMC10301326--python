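"""Power-law viscosity fits, regime classification, Norrish water activity,
and Pearson correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from luxkin import (
    NorrishInput,
    ViscosityPoint,
    classify_diffusion_control,
    correlate,
    fit_power_law,
    mole_fractions,
    norrish_water_activity,
)
from luxkin.synthetic import generate_viscosity_series


def _points(eta, k):
    return [ViscosityPoint(eta=float(e), k=float(v)) for e, v in zip(eta, k)]


class TestFitPowerLaw:
    def test_exact_power_law_recovered_at_machine_precision(self):
        eta = np.linspace(1, 6, 10)
        fit = fit_power_law(_points(eta, 2.0 * eta**-1.0))
        assert fit.A == pytest.approx(2.0, rel=1e-10)
        assert fit.delta == pytest.approx(1.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_viscosity_independent_series_gives_zero_exponent(self):
        eta = np.linspace(1, 6, 8)
        fit = fit_power_law(_points(eta, np.full(8, 3.7)))
        assert fit.delta == pytest.approx(0.0, abs=1e-10)

    @given(c=st.floats(1e-3, 1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_exponent_invariant_to_rate_rescaling(self, c):
        pts, _ = generate_viscosity_series(A=1.0, delta=0.84, noise_fraction=0.05, seed=9)
        scaled = [
            ViscosityPoint(eta=p.eta, k=c * p.k, cosolvent=p.cosolvent) for p in pts
        ]
        f0 = fit_power_law(pts)
        f1 = fit_power_law(scaled)
        assert f1.delta == pytest.approx(f0.delta, rel=1e-8)
        assert f1.A == pytest.approx(c * f0.A, rel=1e-8)

    def test_noisy_exponent_recovery_within_tolerance(self):
        # the diffusion-near-limited regime of flavin autoxidation
        pts, truth = generate_viscosity_series(A=0.5, delta=0.84, noise_fraction=0.05, seed=2)
        fit = fit_power_law(pts)
        assert abs(fit.delta - truth["delta"]) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(_points([1, 2], [1.0, 0.5]))


class TestClassifyDiffusionControl:
    @pytest.mark.parametrize(
        "delta, regime",
        [
            (1.0, "diffusion_limited"),
            (0.05, "viscosity_independent"),
            (1.8, "overdamped"),
            (0.84, "diffusion_limited"),
            (0.5, "intermediate"),
        ],
    )
    def test_regimes(self, delta, regime):
        fit = fit_power_law(
            _points(np.linspace(1, 6, 12), 2.0 * np.linspace(1, 6, 12) ** -delta)
        )
        assert classify_diffusion_control(fit) == regime


class TestNorrish:
    def test_pure_water_unit_activity(self):
        inp = NorrishInput(kN=-2.0, molar_mass=342.3, wt_percent=0.0)
        assert norrish_water_activity(inp) == pytest.approx(1.0)

    def test_ideal_solution_reduces_to_raoult(self):
        inp = NorrishInput(kN=0.0, molar_mass=92.09, wt_percent=30.0)
        x_w, _ = mole_fractions(30.0, 92.09)
        assert norrish_water_activity(inp) == pytest.approx(x_w)

    def test_hand_evaluated_value(self):
        # x_s = 0.1 and kN = -2 give a_w = 0.9 * exp(-0.02) directly; choose
        # the molar mass / wt% pair that lands exactly on x_s = 0.1
        x_s = 0.1
        M = 100.0
        # invert mole-fraction formula for the weight fraction
        w = x_s * M / (x_s * M + (1 - x_s) * 18.015)
        inp = NorrishInput(kN=-2.0, molar_mass=M, wt_percent=100 * w)
        assert norrish_water_activity(inp) == pytest.approx(0.9 * np.exp(-0.02), rel=1e-12)

    @given(kN=st.floats(-8.0, 0.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_activity_decreases_with_cosolvent_for_nonpositive_kN(self, kN):
        aws = [
            norrish_water_activity(NorrishInput(kN=kN, molar_mass=180.16, wt_percent=w))
            for w in (0.0, 10.0, 20.0, 30.0, 40.0)
        ]
        assert all(a >= b for a, b in zip(aws, aws[1:]))

    def test_bad_molar_mass_rejected(self):
        with pytest.raises(ValueError):
            NorrishInput(kN=-2.0, molar_mass=0.0, wt_percent=10.0)


class TestCorrelate:
    def test_perfect_linear_relations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert correlate(x, 2 * x + 1).r == pytest.approx(1.0)
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_product_moment_formula(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(50)
        y = 0.6 * x + rng.standard_normal(50)
        r_direct = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert correlate(x, y).r == pytest.approx(r_direct, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
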
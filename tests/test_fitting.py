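"""Global rate-constant fitting: error metric, Michaelis constants, recovery,
identifiability diagnostics, determinism."""

import numpy as np
import pytest

from luxkin import (
    FitSpec,
    KineticCurve,
    SingleTurnoverDataset,
    SingleTurnoverModel,
    fit_rate_constants,
    michaelis_constants,
    pooled_relative_error,
)
from luxkin.synthetic import (
    DEFAULT_TRUE_RATES,
    NoiseModel,
    generate_bioluminescence_dataset,
)

FIT_NAMES = ("k1", "k2", "k3", "k_minus3", "k4")


class TestPooledRelativeError:
    def test_identical_curves_zero_error(self, true_rates, default_ic, t15):
        from luxkin import simulate_curve

        c = simulate_curve(true_rates, default_ic, t15)
        pooled, per = pooled_relative_error([c], [c])
        assert pooled == 0.0
        assert per == [0.0]

    def test_scalar_perturbation_gives_one_percent(self):
        t = np.linspace(0, 1, 50)
        y = np.sin(t) + 2
        data = KineticCurve(t=t, y=y)
        model = KineticCurve(t=t, y=1.01 * y)
        pooled, per = pooled_relative_error([model], [data])
        assert pooled == pytest.approx(1.0, rel=1e-12)

    def test_matches_elementwise_computation(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 1, 40)
        data = [KineticCurve(t=t, y=rng.uniform(1, 2, 40)) for _ in range(3)]
        model = [KineticCurve(t=t, y=c.y + rng.normal(0, 0.1, 40)) for c in data]
        pooled, per = pooled_relative_error(model, data)
        num = sum(float(np.sum((m.y - d.y) ** 2)) for m, d in zip(model, data))
        den = sum(float(np.sum(d.y**2)) for d in data)
        assert pooled == pytest.approx(100 * np.sqrt(num / den), rel=1e-12)
        assert len(per) == 3

    def test_all_zero_data_rejected(self):
        t = np.linspace(0, 1, 10)
        zero = KineticCurve(t=t, y=np.zeros(10))
        with pytest.raises(ZeroDivisionError):
            pooled_relative_error([zero], [zero])


class TestMichaelisConstants:
    def test_formulas(self, true_rates):
        km = michaelis_constants(true_rates)
        assert km.KM_F == pytest.approx(true_rates.k2 / true_rates.k1)
        assert km.KM_a == pytest.approx(
            (true_rates.k_minus3 + true_rates.k4) / true_rates.k3
        )

    def test_no_dissociation_reduces_to_k4_over_k3(self, true_rates):
        km = michaelis_constants(true_rates.replace(k_minus3=0.0))
        assert km.KM_a == pytest.approx(true_rates.k4 / true_rates.k3)

    def test_proportional_rates_identity(self, true_rates):
        km = michaelis_constants(true_rates.replace(k2=true_rates.k1 * 3e-6))
        assert km.KM_F == pytest.approx(3e-6)

    def test_fixture_rates_inside_buffer_windows(self, true_rates):
        # the fixture parameter set is built to sit in the physiological
        # windows: K_M(FMNH2) 1-2 uM, K_M(decanal) 25-50 uM
        km = michaelis_constants(true_rates)
        assert 1e-6 <= km.KM_F <= 2e-6
        assert 25e-6 <= km.KM_a <= 50e-6

    def test_zero_k1_rejected(self, true_rates):
        with pytest.raises(ZeroDivisionError):
            michaelis_constants(true_rates.replace(k1=0.0))


class TestGlobalFit:
    def test_truth_is_local_optimum_on_noise_free_data(self, true_rates):
        # pooled error at the generating parameters beats any 2x single-rate
        # perturbation
        t = np.linspace(0, 15, 300)
        noise = NoiseModel(multiplicative_sigma=0.0, additive_sigma=0.0)
        ds, _ = generate_bioluminescence_dataset(t_grid=t, noise=noise, seed=0)
        model = SingleTurnoverModel(ds, kd=true_rates.kd, kdd=true_rates.kdd)
        theta_true = np.log10([getattr(true_rates, n) for n in FIT_NAMES])
        r_true, _ = model._residuals(theta_true)
        cost_true = float(r_true @ r_true)
        for i in range(5):
            theta = theta_true.copy()
            theta[i] += np.log10(2.0)
            r, _ = model._residuals(theta)
            assert float(r @ r) > cost_true

    def test_single_concentration_flags_unidentifiable_binding(self, t15):
        # with one aldehyde concentration, k3 and k_minus3 only enter through
        # lumped combinations: the fit must flag them instead of silently
        # reporting precise values
        ds5, truth = generate_bioluminescence_dataset(t_grid=t15, seed=6)
        ds1 = SingleTurnoverDataset(
            curves=ds5.curves[2:3], L0=ds5.L0, F0=ds5.F0, A0_list=ds5.A0_list[2:3]
        )
        model = SingleTurnoverModel(ds1, kd=0.5, kdd=0.1, ode_rtol=1e-7)
        res = model.fit(n_starts=4, seed=6, n_refine=1)
        flagged = set(res.poorly_identified)
        assert flagged & {"k3", "k_minus3"}

    def test_determinism_same_spec_same_seed(self):
        t = np.linspace(0, 15, 300)
        ds, _ = generate_bioluminescence_dataset(t_grid=t, seed=2)
        spec = FitSpec(dataset=ds, kd=0.5, kdd=0.1, n_starts=3, seed=11)
        a = fit_rate_constants(spec)
        b = fit_rate_constants(spec)
        assert a.rates == b.rates
        assert a.rss == b.rss
        assert a.start_index == b.start_index

    def test_invalid_specs_rejected(self, t15):
        ds, _ = generate_bioluminescence_dataset(t_grid=t15, seed=0)
        with pytest.raises(ValueError):
            SingleTurnoverModel(ds, kd=-0.1, kdd=0.1)
        with pytest.raises(ValueError):
            SingleTurnoverModel(ds, kd=0.5, kdd=0.1, bounds={"k1": (0.0, 1e9)})
        with pytest.raises(ValueError):
            SingleTurnoverDataset(curves=ds.curves, A0_list=[1e-6])
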
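"""Model-free spectral densities, rate predictions, τ_m inversion,
build-up fitting, η→O² conversion, and the aggregate comparisons.

The high-precision reference values were computed independently by
arbitrary-precision (sympy) evaluation of the stated closed forms.
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methyldyn.constants import DEFAULT_CONSTANTS
from methyldyn.exceptions import InsufficientDataError, MethylDynError
from methyldyn.modelfree import (
    EnvironmentComparison,
    ModelFreeParams,
    buildup_ratio,
    compare_environments,
    estimate_tau_m,
    eta_to_o2_axis,
    fit_eta,
    fit_order_parameter_set,
    o2_axis_to_eta,
    predict_n15_rates,
    r1r2_exchange_screen,
    spectral_density,
    summarize_set,
    temperature_slope,
)
from methyldyn.probes import BuildupSeries, RelaxationRecord
from methyldyn.synth import make_backbone_dataset

from conftest import make_probe, make_set

# frozen arbitrary-precision reference values
J_REF = 1.07875536693707254e-10  # S2=0.85, tau_m=21.9 ns, tau_e=50 ps, w=2*pi*60.8e6
R1_REF = 0.52874264880330675  # S2=0.87, tau_m=24 ns, tau_e=0, 600 MHz, defaults
R2_REF = 29.82322786152056
ETA_REF = 28.453379619653939  # eta for O2=0.36 at tau_m=21.9 ns, defaults


class TestSpectralDensity:
    def test_rigid_zero_frequency_closed_form(self):
        p = ModelFreeParams(S2=1.0, tau_m=20e-9)
        assert float(spectral_density(0.0, p)) == pytest.approx(0.4 * 20e-9, rel=1e-14)

    def test_zero_amplitude_zero_internal_time_vanishes(self):
        p = ModelFreeParams(S2=0.0, tau_m=20e-9, tau_e=0.0)
        w = np.array([0.0, 1e8, 1e9])
        np.testing.assert_array_equal(spectral_density(w, p), np.zeros(3))

    def test_against_arbitrary_precision_reference(self):
        p = ModelFreeParams(S2=0.85, tau_m=21.9e-9, tau_e=50e-12)
        val = float(spectral_density(2 * math.pi * 60.8e6, p))
        assert val == pytest.approx(J_REF, rel=1e-12)


class TestPredictRates:
    def test_against_arbitrary_precision_reference(self):
        p = ModelFreeParams(S2=0.87, tau_m=24e-9)
        r1, r2 = predict_n15_rates(p, 600.0)
        assert r1 == pytest.approx(R1_REF, rel=1e-12)
        assert r2 == pytest.approx(R2_REF, rel=1e-12)

    def test_exchange_adds_to_r2_only(self):
        base = ModelFreeParams(S2=0.85, tau_m=20e-9)
        with_rex = ModelFreeParams(S2=0.85, tau_m=20e-9, R_ex=10.0)
        r1a, r2a = predict_n15_rates(base, 600.0)
        r1b, r2b = predict_n15_rates(with_rex, 600.0)
        assert r1b == r1a
        assert r2b - r2a == pytest.approx(10.0, abs=1e-12)

    def test_r2_over_r1_increases_with_tau_m(self):
        taus = np.linspace(1e-9, 50e-9, 25)
        ratios = []
        for tm in taus:
            r1, r2 = predict_n15_rates(ModelFreeParams(S2=0.9, tau_m=tm), 600.0)
            ratios.append(r2 / r1)
        assert np.all(np.diff(ratios) > 0)

    @pytest.mark.parametrize("field", [500.0, 700.0, 900.0])
    @pytest.mark.parametrize("s2", [0.2, 0.6, 1.0])
    def test_r2_dominates_r1_in_slow_tumbling_regime(self, field, s2):
        for tm_ns in (4.0, 10.0, 30.0):
            r1, r2 = predict_n15_rates(ModelFreeParams(S2=s2, tau_m=tm_ns * 1e-9), field)
            assert r2 >= r1


class TestEstimateTauM:
    def test_noiseless_inverse_identity(self):
        records, _ = make_backbone_dataset(tau_m_ns=20.0, n_residues=20, noise_frac=0.0, seed=3)
        est = estimate_tau_m(records)
        assert est.tau_m_ns == pytest.approx(20.0, abs=1e-3)
        assert est.n_residues_used >= 15

    def test_noisy_recovery_unbiased(self):
        # Monte-Carlo check at a scale suited to a unit test; the 200-seed
        # bias bound lives in the acceptance suite.
        estimates = []
        for seed in range(20):
            records, _ = make_backbone_dataset(
                tau_m_ns=20.0, n_residues=20, noise_frac=0.02, seed=seed
            )
            estimates.append(estimate_tau_m(records).tau_m_ns)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 20.0) < 3 * se + 0.02

    def test_exchange_contaminated_residues_are_trimmed(self):
        records, truth = make_backbone_dataset(
            tau_m_ns=20.0, n_residues=20, noise_frac=0.005,
            rex_fraction=0.25, rex_value=8.0, seed=7,
        )
        est = estimate_tau_m(records, trim=True)
        assert est.tau_m_ns == pytest.approx(20.0, rel=0.02)

    def test_too_few_records_rejected(self):
        records, _ = make_backbone_dataset(n_residues=4, seed=0)
        with pytest.raises(InsufficientDataError):
            estimate_tau_m(records)


class TestExchangeScreen:
    def test_planted_outlier_is_the_only_flag(self):
        records, truth = make_backbone_dataset(
            tau_m_ns=20.0, n_residues=20, noise_frac=0.005,
            rex_fraction=0.05, rex_value=20.0, seed=1,
        )
        flags = r1r2_exchange_screen(records)
        assert set(np.flatnonzero(flags)) == set(truth["rex_outliers"])

    def test_constant_products_flag_nothing(self):
        records = [
            RelaxationRecord(i, 0.5, 0.0, 25.0, 0.0, 600.0, 323.15) for i in range(1, 9)
        ]
        assert not r1r2_exchange_screen(records).any()


class TestFitEta:
    DELAYS = (0.004, 0.008, 0.012, 0.016, 0.020)

    def _series(self, eta, delta=0.0, sigma=0.0, seed=0, delays=None):
        delays = np.array(delays if delays is not None else self.DELAYS)
        clean = buildup_ratio(delays, eta, delta)
        rng = np.random.default_rng(seed)
        noisy = clean + sigma * rng.standard_normal(len(delays)) if sigma else clean
        return BuildupSeries(
            make_probe(1, "ILE"), tuple(delays), tuple(noisy),
            tuple(np.full(len(delays), sigma)), 323.15,
        )

    def test_noiseless_delta_zero_inversion(self):
        fit = fit_eta(self._series(30.0), n_mc=0)
        assert fit.eta == pytest.approx(30.0, rel=1e-6)

    def test_zero_eta_recovered(self):
        fit = fit_eta(self._series(0.0), n_mc=0)
        assert fit.eta == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_two_parameter_inversion(self):
        fit = fit_eta(self._series(25.0, delta=5.0), n_mc=0)
        assert fit.eta == pytest.approx(25.0, rel=1e-4)
        assert fit.delta == pytest.approx(5.0, rel=1e-4)

    def test_few_points_default_to_fixed_delta(self):
        series = self._series(20.0, delays=(0.004, 0.010, 0.016))
        fit = fit_eta(series, n_mc=0)
        assert fit.fixed_delta
        assert fit.delta == 0.0

    def test_eta_err_scales_as_inverse_sqrt_points(self):
        sigma = 0.01
        few = self._series(25.0, sigma=sigma, seed=5, delays=np.linspace(0.002, 0.024, 6))
        many = self._series(25.0, sigma=sigma, seed=6, delays=np.linspace(0.002, 0.024, 24))
        err_few = fit_eta(few, n_mc=400, seed=1).eta_err
        err_many = fit_eta(many, n_mc=400, seed=2).eta_err
        assert err_few / err_many == pytest.approx(2.0, rel=0.20)


class TestEtaConversion:
    def test_zero_eta_gives_zero_order_parameter(self):
        assert eta_to_o2_axis(0.0, 21.9e-9) == 0.0

    def test_linear_in_eta_and_inverse_in_tau_m(self):
        o2 = eta_to_o2_axis(10.0, 20e-9)
        assert eta_to_o2_axis(20.0, 20e-9) == pytest.approx(2 * o2, rel=1e-14)
        assert eta_to_o2_axis(10.0, 40e-9) == pytest.approx(o2 / 2, rel=1e-14)

    def test_reference_eta_for_typical_order_parameter(self):
        assert o2_axis_to_eta(0.36, 21.9e-9) == pytest.approx(ETA_REF, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        o2=st.floats(min_value=1e-3, max_value=1.0),
        tau_ns=st.floats(min_value=1.0, max_value=100.0),
    )
    def test_round_trip_is_identity(self, o2, tau_ns):
        eta = o2_axis_to_eta(o2, tau_ns * 1e-9)
        assert eta_to_o2_axis(eta, tau_ns * 1e-9) == pytest.approx(o2, rel=1e-12)

    def test_out_of_range_conversion_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            eta_to_o2_axis(-1.0, 20e-9)


class TestTemperatureSlope:
    def test_published_style_arithmetic(self):
        # ensemble at 50 degC with mean 0.36; every probe rigidifies by
        # +0.055 at 35 degC -> mean 0.415 and dO2/dT = -0.0037 K^-1 (2 s.f.)
        hot = make_set(np.full(90, 0.36), temperature_K=323.15)
        cold = make_set(np.full(90, 0.415), temperature_K=308.15)
        res = temperature_slope(hot, cold)
        assert res.mean_delta == pytest.approx(0.055, abs=1e-12)
        assert np.mean(cold.values) == pytest.approx(0.415)
        assert res.slope_per_K == pytest.approx(-0.0037, abs=5e-5)
        assert res.n_paired == 90

    def test_argument_order_does_not_matter(self):
        hot = make_set([0.3, 0.4], temperature_K=323.15)
        cold = make_set([0.35, 0.45], temperature_K=308.15)
        assert temperature_slope(hot, cold) == temperature_slope(cold, hot)

    def test_identical_sets_give_zero_slope(self):
        a = make_set([0.3, 0.4, 0.5], temperature_K=323.15)
        b = make_set([0.3, 0.4, 0.5], temperature_K=308.15)
        res = temperature_slope(a, b)
        assert res.mean_delta == 0.0
        assert res.slope_per_K == 0.0

    def test_random_per_probe_shifts_recover_mean(self):
        rng = np.random.default_rng(42)
        base = rng.uniform(0.2, 0.6, size=90)
        deltas = rng.normal(0.05, 0.01, size=90)
        hot = make_set(base, temperature_K=323.15)
        cold = make_set(base + deltas, temperature_K=308.15)
        res = temperature_slope(hot, cold)
        se = 0.01 / np.sqrt(90)
        assert abs(res.mean_delta - deltas.mean()) < 1e-12
        assert abs(res.slope_per_K - (-0.05 / 15.0)) < 3 * se / 15.0 + abs(
            deltas.mean() - 0.05
        ) / 15.0


class TestCompareEnvironments:
    def test_identical_sets_are_perfectly_correlated(self):
        a = make_set([0.2, 0.4, 0.6, 0.8])
        b = make_set([0.2, 0.4, 0.6, 0.8], environment="bicelle")
        res = compare_environments(a, b)
        assert res == EnvironmentComparison(1.0, 1.0, 0.0, 4)

    def test_variance_calibrated_noise_gives_expected_r2(self):
        # additive noise sized for an expected R2 of 0.9 at n=50
        rng = np.random.default_rng(3)
        x = rng.uniform(0.15, 0.75, size=50)
        sigma = np.sqrt(x.var() * (1 / 0.9 - 1))
        y = x + rng.normal(0.0, sigma, size=50)
        res = compare_environments(
            make_set(x), make_set(np.clip(y, 0.01, 0.99), environment="bicelle")
        )
        assert 0.82 <= res.r_squared <= 0.98

    def test_too_few_pairs_rejected(self):
        a = make_set([0.2, 0.4])
        b = make_set([0.2, 0.4], environment="bicelle")
        with pytest.raises(InsufficientDataError):
            compare_environments(a, b)


class TestSummarize:
    def test_arithmetic_mean(self):
        mean_o2, mean_err, n = summarize_set(make_set([0.2, 0.4, 0.6], errors=[0.01, 0.02, 0.03]))
        assert mean_o2 == pytest.approx(0.4)
        assert mean_err == pytest.approx(0.02)
        assert n == 3

    def test_single_entry(self):
        assert summarize_set(make_set([0.5]))[0] == 0.5

    def test_empty_set_rejected(self):
        from methyldyn.probes import OrderParameterSet

        with pytest.raises(InsufficientDataError):
            summarize_set(OrderParameterSet([]))


class TestFitOrderParameterSet:
    def test_noiseless_pipeline_recovers_truth(self):
        from methyldyn.synth import PSRII_LIKE, make_methyl_dataset

        ds = make_methyl_dataset(
            preset=PSRII_LIKE, n_probes=12, sigma_ratio=0.0,
            environments=("micelle",), seed=5,
        )
        opset = fit_order_parameter_set(
            ds.buildups["micelle"], tau_m_ns=21.9, environment="micelle", n_mc=0, seed=0
        )
        np.testing.assert_allclose(
            opset.values, ds.truth_sets["micelle"].values, rtol=1e-4
        )
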
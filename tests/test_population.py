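"""Tests for virtual patient population synthesis from H-Score statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trimersim import (
    FAP_RANGES,
    INDICATION_PRESETS,
    IndicationPopulation,
    decompose_hscore,
    effect_distribution,
    fit_hscore_distribution,
    indication_population,
    omega_from_samples,
    pct_above_threshold,
    sample_avg_fap,
    simulate_hscores,
    simulate_population,
)


class TestOmegaFromSamples:
    def test_constant_samples_give_zero(self):
        assert omega_from_samples([20.0] * 10) == 0.0

    def test_cv_of_one_gives_sqrt_log_two(self):
        # closed form: sd == mean -> omega = sqrt(log 2)
        x = np.array([10.0, 30.0])
        sd, mean = x.std(ddof=1), x.mean()
        expected = math.sqrt(math.log(1 + (sd / mean) ** 2))
        assert omega_from_samples(x) == pytest.approx(expected, rel=1e-12)
        assert omega_from_samples([1.0, 1.0 + math.sqrt(2) * 1.0]) > 0

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(7)
        omega = 0.6
        samples = 20.0 * np.exp(rng.normal(0, omega, 100_000))
        assert omega_from_samples(samples) == pytest.approx(omega, rel=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            omega_from_samples([5.0])
        with pytest.raises(ValueError):
            omega_from_samples([5.0, -1.0])


class TestSimulateHscores:
    def test_zero_omega_collapses_to_median(self):
        pop = IndicationPopulation("x", theta=20.0, omega=0.0, n_virtual=100)
        assert np.all(simulate_hscores(pop) == 20.0)

    def test_sample_median_near_theta(self):
        pop = IndicationPopulation("colon", theta=20.0, omega=0.5,
                                   n_virtual=5000, seed=3)
        med = np.median(simulate_hscores(pop))
        assert med == pytest.approx(20.0, rel=0.03)

    def test_log_samples_normal(self):
        pop = IndicationPopulation("colon", theta=20.0, omega=0.5,
                                   n_virtual=5000, seed=5)
        _, p = stats.normaltest(np.log(simulate_hscores(pop)))
        assert p > 0.01

    def test_capped_at_scale_maximum(self):
        pop = IndicationPopulation("high", theta=150.0, omega=1.0,
                                   n_virtual=2000, seed=1)
        x = simulate_hscores(pop)
        assert x.max() <= 300.0 and x.min() > 0

    @pytest.mark.parametrize("theta", [5.0, 20.0, 100.0])
    @pytest.mark.parametrize("omega", [0.3, 0.8])
    def test_parameter_recovery(self, theta, omega):
        """(theta, omega) recovered within 5% at n = 5,000, including where
        the 300-point cap truncates the upper tail."""
        pop = IndicationPopulation("x", theta=theta, omega=omega,
                                   n_virtual=5000, seed=11)
        theta_hat, omega_hat = fit_hscore_distribution(simulate_hscores(pop))
        assert theta_hat == pytest.approx(theta, rel=0.05)
        assert omega_hat == pytest.approx(omega, rel=0.05)


class TestDecomposeHscore:
    def test_scale_maximum_unique_point(self):
        assert decompose_hscore(300.0, 0) == (100.0, 0.0, 0.0)

    def test_zero_hscore(self):
        assert decompose_hscore(0.0, 0) == (0.0, 0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decompose_hscore(301.0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hscore=st.floats(0.0, 300.0), seed=st.integers(0, 2**31 - 1))
    def test_identity_and_feasibility(self, hscore, seed):
        hi, me, lo = decompose_hscore(hscore, seed)
        assert hi >= 0 and me >= 0 and lo >= 0
        assert hi + me + lo <= 100.0 + 1e-9
        assert 3 * hi + 2 * me + lo == pytest.approx(hscore, abs=1e-9)

    def test_exact_reconstruction_over_many_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            h = rng.uniform(0.0, 300.0)
            hi, me, lo = decompose_hscore(h, rng)
            assert abs(3 * hi + 2 * me + lo - h) < 1e-9

    def test_thin_polytope_near_maximum(self):
        rng = np.random.default_rng(2)
        hi, me, lo = decompose_hscore(299.5, rng)
        assert 3 * hi + 2 * me + lo == pytest.approx(299.5, abs=1e-9)
        assert hi + me + lo <= 100.0 + 1e-9


class TestSampleAvgFap:
    def test_all_high_mean(self):
        rng = np.random.default_rng(0)
        draws = [sample_avg_fap((100.0, 0.0, 0.0), rng) for _ in range(4000)]
        lo, hi = FAP_RANGES["high"]
        assert np.mean(draws) == pytest.approx((lo + hi) / 2, rel=0.02)

    def test_empty_areas_give_zero(self):
        assert sample_avg_fap((0.0, 0.0, 0.0), 0) == 0.0

    def test_all_low_draws_stay_in_range(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_avg_fap((0.0, 0.0, 100.0), rng)
                          for _ in range(500)])
        assert np.all((draws >= 300.0) & (draws <= 1000.0))

    def test_invalid_area_triple_rejected(self):
        with pytest.raises(ValueError):
            sample_avg_fap((60.0, 50.0, 0.0), 0)


class TestPctAboveThreshold:
    def test_examples(self):
        assert pct_above_threshold([1, 2, 3, 4], 2.5) == 50.0
        assert pct_above_threshold([1, 2, 3], 0.0) == 100.0
        assert pct_above_threshold([1, 2, 3], 10.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pct_above_threshold([], 1.0)

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(8, 1, 500)
        thresholds = np.geomspace(10, 1e6, 20)
        pcts = [pct_above_threshold(x, t) for t in thresholds]
        assert np.all(np.diff(pcts) <= 0)


class TestPopulationPipeline:
    def test_cohort_columns_and_invariants(self):
        pop = indication_population("colon", n_virtual=300, seed=0)
        df = simulate_population(pop)
        assert pop.theta == 20.0 and not pop.assumed
        assert len(df) == 300
        recon = 3 * df.high_area + 2 * df.med_area + df.low_area
        assert np.allclose(recon, df.hscore, atol=1e-9)
        assert (df.avg_fap >= 0).all()
        assert (df.high_area + df.med_area + df.low_area <= 100 + 1e-9).all()

    def test_all_presets_valid(self):
        for name in INDICATION_PRESETS:
            pop = indication_population(name, n_virtual=10)
            assert 0 < pop.theta <= 300 and pop.omega >= 0

    def test_unknown_indication_rejected(self):
        with pytest.raises(KeyError):
            indication_population("plasma")

    def test_seeded_reproducibility(self):
        a = simulate_population(indication_population("colon", 50, seed=9))
        b = simulate_population(indication_population("colon", 50, seed=9))
        assert a.equals(b)


class TestEffectDistribution:
    def test_zero_fap_population_has_zero_effect(self, ref_mol):
        out = effect_distribution(np.zeros(5), ref_mol)
        assert out["median"] == 0.0 and out["whisker_hi"] == 0.0

    def test_single_sample_median_is_its_effect(self, ref_mol):
        out = effect_distribution([3000.0], ref_mol)
        assert out["median"] == out["q1"] == out["q3"]
        assert 0 < out["median"] < 100

    def test_enhanced_molecule_dominates(self, ref_mol, enh_mol):
        """At equal avidity the higher-affinity molecule's median effect is
        at least the reference molecule's on the same patients."""
        pop = indication_population("colon", n_virtual=120, seed=2)
        fap = simulate_population(pop)["avg_fap"].to_numpy()
        ref = effect_distribution(fap, ref_mol)
        enh = effect_distribution(fap, enh_mol)
        assert enh["median"] >= ref["median"]
        assert enh["q3"] >= ref["q3"]

    def test_median_increases_with_expression(self, ref_mol):
        lo = effect_distribution([500.0, 800.0, 1200.0], ref_mol)
        hi = effect_distribution([5000.0, 8000.0, 12000.0], ref_mol)
        assert hi["median"] > lo["median"]
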
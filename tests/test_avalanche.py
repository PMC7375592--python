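import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aseforecast.avalanche import (AvalancheCatalog, AvalancheEvent, average_shape,
                                   bin_average_size_duration, compare_power_vs_exponential,
                                   compute_baseline, fit_size_duration,
                                   fit_truncated_power_law, log_binned_density,
                                   pool_catalogs, sample_truncated_exponential,
                                   sample_truncated_power_law, scaling_relation_gamma,
                                   segment_avalanches)
from aseforecast.series import UniformSeries


def _series(values, dt=1.0):
    return UniformSeries(0.0, dt, np.asarray(values, dtype=float))


def _catalog_from_pairs(pairs, dt=1.0):
    """Catalog of synthetic events with prescribed (T, S)."""
    events = []
    for i, (T, S) in enumerate(pairs):
        n = int(round(T / dt))
        traj = np.full(n, S / (n * dt))
        events.append(AvalancheEvent(start_time=float(i * 1000), duration=T,
                                     size=S, trajectory=traj))
    return AvalancheCatalog(events=tuple(events), baseline=0.0, dt=dt)


class TestBaseline:
    def test_mean_and_fraction(self):
        s = _series([1, 2, 3])
        assert compute_baseline(s, 1.0) == pytest.approx(2.0)
        assert compute_baseline(s, 0.1) == pytest.approx(0.2)

    def test_nonpositive_fraction(self):
        with pytest.raises(ValueError):
            compute_baseline(_series([1, 2, 3]), -1.0)


class TestSegmentation:
    def test_hand_computed_event(self):
        cat = segment_avalanches(_series([0, 2, 4, 2, 0]), baseline=1.0)
        assert len(cat) == 1
        e = cat.events[0]
        assert e.duration == 3.0
        assert e.size == pytest.approx(5.0)
        np.testing.assert_allclose(e.trajectory, [1.0, 3.0, 1.0])
        assert e.start_time == 1.0

    def test_boundary_runs_excluded(self):
        cat = segment_avalanches(_series([2, 0, 2]), baseline=1.0)
        assert len(cat) == 0
        full = segment_avalanches(_series([2, 0, 2]), baseline=1.0,
                                  include_truncated=True)
        assert len(full) == 2 and all(e.truncated for e in full.events)

    def test_constant_at_baseline_is_empty(self):
        cat = segment_avalanches(_series([1, 1, 1, 1]), baseline=1.0)
        assert len(cat) == 0

    def test_dt_scales_duration_and_size(self):
        cat = segment_avalanches(_series([0, 2, 4, 2, 0], dt=0.5), baseline=1.0)
        assert cat.events[0].duration == pytest.approx(1.5)
        assert cat.events[0].size == pytest.approx(2.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=60),
           st.floats(-2, 2, allow_nan=False))
    def test_size_conservation(self, values, baseline):
        # sum of all event sizes (incl. truncated) equals the rectangle-rule
        # integral of the positive excess
        s = _series(values)
        cat = segment_avalanches(s, baseline, include_truncated=True)
        total = sum(e.size for e in cat.events)
        expect = np.maximum(np.asarray(values) - baseline, 0.0).sum() * s.dt
        assert total == pytest.approx(expect, abs=1e-12)


class TestLogBinnedDensity:
    def test_identical_values_single_bin(self):
        d = log_binned_density(np.full(7, 3.0), bins_per_decade=4)
        assert (d.counts > 0).sum() == 1
        assert d.counts.sum() == 7

    def test_continuous_density_conserves_count(self, rng):
        vals = rng.uniform(0.5, 200.0, size=1000)
        d = log_binned_density(vals, bins_per_decade=6)
        total = float((d.densities * np.diff(d.bin_edges)).sum())
        assert total == pytest.approx(1000, rel=1e-9)

    def test_powerlaw_slope_recovered(self):
        # inverse-CDF oracle: p(x) ~ x^{-1.5} on [1, 100]
        x = sample_truncated_power_law(1.5, 1, 100, 10 ** 5,
                                       np.random.default_rng(5))
        d = log_binned_density(x, bins_per_decade=5)
        occ = d.densities > 0
        slope = np.polyfit(np.log10(d.centers[occ]), np.log10(d.densities[occ]), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.1)

    def test_discrete_normalization(self):
        # durations {1,1,2,3} at dt=1 in one bin [1, 10^0.5): 4 events over
        # 3 admissible integer durations -> density 4/3
        d = log_binned_density([1.0, 1.0, 2.0, 3.0], bins_per_decade=2,
                               discrete_dt=1.0)
        assert d.densities[0] == pytest.approx(4 / 3)
        assert d.counts[0] == 4

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_binned_density([1.0, 0.0], 5)


class TestPowerLawMLE:
    def test_recovers_generating_exponent(self):
        x = sample_truncated_power_law(1.5, 1, 100, 10 ** 5,
                                       np.random.default_rng(11))
        fit = fit_truncated_power_law(x, 1, 100)
        assert 1.48 <= fit.exponent <= 1.52
        assert fit.n_used == 10 ** 5

    def test_insufficient_support_errors_with_count(self):
        with pytest.raises(ValueError, match="got 0"):
            fit_truncated_power_law([0.5, 200.0], 1, 100)

    def test_deterministic(self):
        x = sample_truncated_power_law(1.3, 1, 50, 500, np.random.default_rng(1))
        f1 = fit_truncated_power_law(x, 1, 50)
        _ = fit_truncated_power_law(x * 1.0, 1, 50)
        f2 = fit_truncated_power_law(x, 1, 50)
        assert f1.exponent == f2.exponent and f1.loglik == f2.loglik

    def test_consistency_bias_shrinks_with_n(self):
        # mean absolute estimation error over fixed-seed replicates must
        # decrease from n=1e3 to n=1e5
        errs = []
        for n in (10 ** 3, 10 ** 4, 10 ** 5):
            e = [abs(fit_truncated_power_law(
                sample_truncated_power_law(1.5, 1, 100, n,
                                           np.random.default_rng(100 + r)),
                1, 100).exponent - 1.5) for r in range(5)]
            errs.append(np.mean(e))
        assert errs[2] < errs[0]
        assert errs[2] < 0.02

    def test_ci_covers_truth(self):
        x = sample_truncated_power_law(1.5, 1, 100, 10 ** 4,
                                       np.random.default_rng(3))
        fit = fit_truncated_power_law(x, 1, 100)
        assert abs(fit.exponent - 1.5) <= 2 * fit.ci95


class TestModelComparison:
    def test_powerlaw_data_supports_powerlaw(self):
        x = sample_truncated_power_law(1.5, 1, 100, 10 ** 4,
                                       np.random.default_rng(21))
        cmp_ = compare_power_vs_exponential(x, 1, 100)
        assert cmp_.akaike_weight_power > 0.9999

    def test_exponential_data_rejects_powerlaw(self):
        x = sample_truncated_exponential(0.5, 1, 100, 10 ** 4,
                                         np.random.default_rng(22))
        cmp_ = compare_power_vs_exponential(x, 1, 100)
        assert cmp_.akaike_weight_power < 0.01
        assert cmp_.exp_rate == pytest.approx(0.5, abs=0.05)

    def test_fixed_exponent_has_zero_parameters(self):
        x = sample_truncated_power_law(1.5, 1, 100, 10 ** 4,
                                       np.random.default_rng(23))
        cmp_ = compare_power_vs_exponential(x, 1, 100, fixed_exponent=1.5)
        assert cmp_.power_fit.aic == pytest.approx(-2.0 * cmp_.power_fit.loglik)
        assert cmp_.akaike_weight_power > 0.9999

    def test_weight_formula_invariant(self):
        # the pairwise weight depends only on the AIC difference
        x = sample_truncated_power_law(1.5, 1, 100, 2000, np.random.default_rng(4))
        cmp_ = compare_power_vs_exponential(x, 1, 100)
        expect = 1.0 / (1.0 + math.exp((cmp_.aic_power - cmp_.aic_exp) / 2.0))
        assert cmp_.akaike_weight_power == pytest.approx(expect, abs=1e-12)


class TestSizeDuration:
    def test_single_duration_single_pair(self):
        cat = _catalog_from_pairs([(4.0, 10.0), (4.0, 14.0)])
        pairs = bin_average_size_duration(cat)
        assert len(pairs) == 1
        assert pairs[0][1] == pytest.approx(12.0)

    def test_exact_power_law_recovered(self):
        cat = _catalog_from_pairs([(T, 2.0 * T ** 1.5) for T in
                                   [1, 2, 4, 8, 16, 32, 64]])
        pairs = bin_average_size_duration(cat, bins_per_decade=10)
        fit = fit_size_duration(pairs)
        assert fit.gamma == pytest.approx(1.5, abs=0.02)

    def test_free_fit_exact(self):
        pairs = [(T, 2.0 * T ** 1.5) for T in (1.0, 3.0, 10.0, 30.0)]
        fit = fit_size_duration(pairs)
        assert fit.b == pytest.approx(2.0, abs=1e-9)
        assert fit.gamma == pytest.approx(1.5, abs=1e-9)

    def test_fixed_gamma_hand_example(self):
        # both points sit on S = 3 T^{3/2}
        fit = fit_size_duration([(1.0, 3.0), (4.0, 24.0)], gamma=1.5)
        assert fit.fixed_gamma
        assert fit.b == pytest.approx(3.0, abs=1e-9)

    def test_noisy_monte_carlo(self):
        rng = np.random.default_rng(6)
        T = rng.uniform(1, 100, size=200)
        S = 5.0 * T ** 1.5 * np.exp(rng.normal(0, 0.1, size=200))
        fit = fit_size_duration(list(zip(T, S)), gamma=1.5)
        assert fit.b == pytest.approx(5.0, rel=0.10)

    def test_one_pair_free_gamma_errors(self):
        with pytest.raises(ValueError):
            fit_size_duration([(1.0, 3.0)])

    def test_empty_catalog_errors(self):
        cat = AvalancheCatalog(events=(), baseline=0.0, dt=1.0)
        with pytest.raises(ValueError):
            bin_average_size_duration(cat)


class TestAverageShape:
    def test_triangular_event_symmetric_unit_area(self):
        cat = _series([0, 1, 2, 3, 2, 1, 0])
        catalog = segment_avalanches(cat, baseline=0.5)
        shape = average_shape(catalog, n_grid=101)
        assert shape.integral() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(shape.mean_excess, shape.mean_excess[::-1],
                                   atol=1e-12)

    def test_identical_events_equal_single(self):
        traj = np.array([1.0, 3.0, 2.0])
        one = AvalancheCatalog(events=(AvalancheEvent(0.0, 3.0, 6.0, traj),),
                               baseline=0.0, dt=1.0)
        many = AvalancheCatalog(
            events=tuple(AvalancheEvent(10.0 * i, 3.0, 6.0, traj) for i in range(5)),
            baseline=0.0, dt=1.0)
        np.testing.assert_allclose(average_shape(one).mean_excess,
                                   average_shape(many).mean_excess, atol=1e-12)

    def test_scale_invariance(self):
        # rescaling every event by (c*S, c*T) leaves the curve unchanged
        rng = np.random.default_rng(8)
        events = tuple(
            AvalancheEvent(float(i), float(n), float(n), rng.uniform(0.5, 2, n))
            for i, n in enumerate([3, 5, 9, 17]))
        cat = AvalancheCatalog(events=events, baseline=0.0, dt=1.0)
        c = 7.3
        scaled = AvalancheCatalog(
            events=tuple(AvalancheEvent(e.start_time, c * e.duration, c * e.size,
                                        c * e.trajectory) for e in events),
            baseline=0.0, dt=c)
        np.testing.assert_allclose(average_shape(cat).mean_excess,
                                   average_shape(scaled).mean_excess, atol=1e-12)

    def test_no_qualifying_events_errors(self):
        cat = AvalancheCatalog(
            events=(AvalancheEvent(0.0, 1.0, 1.0, np.array([1.0])),),
            baseline=0.0, dt=1.0)
        with pytest.raises(ValueError):
            average_shape(cat, min_samples_per_event=2)


class TestScalingRelation:
    @pytest.mark.parametrize("alpha,tau,expected", [
        (1.5, 4.0 / 3.0, 1.5),
        (2.0, 2.0, 1.0),
        (1.53, 1.25, 2.12),
    ])
    def test_identity(self, alpha, tau, expected):
        assert scaling_relation_gamma(alpha, tau) == pytest.approx(expected)

    def test_tau_one_undefined(self):
        with pytest.raises(ValueError):
            scaling_relation_gamma(1.5, 1.0)


class TestPoolCatalogs:
    def test_pool_of_one_is_identity(self):
        cat = _catalog_from_pairs([(2.0, 5.0), (4.0, 9.0)])
        pooled = pool_catalogs([cat])
        assert pooled.events == cat.events

    def test_pool_counts_and_order(self):
        a = _catalog_from_pairs([(2.0, 5.0)] * 3)
        b = _catalog_from_pairs([(3.0, 7.0)] * 4)
        pooled = pool_catalogs([a, b])
        assert len(pooled) == 7
        starts = [e.start_time for e in pooled.events]
        assert starts == sorted(starts)

    def test_mismatched_dt_rejected(self):
        a = _catalog_from_pairs([(2.0, 5.0)], dt=1.0)
        b = _catalog_from_pairs([(2.0, 5.0)], dt=2.0)
        with pytest.raises(ValueError):
            pool_catalogs([a, b])


class TestBaselineInsensitivity:
    def test_exponent_stable_across_reference_levels(self, marginal_series):
        # the duration exponent must agree (joint 95% CIs) whether events
        # are cut at 0.5x, 1.0x or 1.5x the series mean
        fits = []
        for frac in (0.5, 1.0, 1.5):
            cat = segment_avalanches(marginal_series,
                                     compute_baseline(marginal_series, frac))
            fits.append(fit_truncated_power_law(cat.durations, 0.95, 100))
        for i in range(len(fits)):
            for j in range(i + 1, len(fits)):
                gap = abs(fits[i].exponent - fits[j].exponent)
                assert gap <= fits[i].ci95 + fits[j].ci95
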
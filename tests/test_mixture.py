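"""CDF mixture fitting: plotting positions, parameter recovery, nesting,
model comparison arithmetic and sharing fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafmorph import mixture
from leafmorph.errors import (
    DataError,
    FitError,
    InsufficientReferenceError,
)
from leafmorph.mixture import (
    ForcedTwoComponentFit,
    NormalCDFFit,
    SharingRule,
    compare_models,
    empirical_cdf,
    fit_forced_two_component,
    fit_one_component,
    fit_pterochrozinae_reference,
    normal_cdf,
    sharing_fraction,
    two_component_cdf,
)


class TestEmpiricalCDF:
    def test_hazen_plotting_positions(self):
        ecdf = empirical_cdf([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(ecdf.probs, [0.125, 0.375, 0.625, 0.875])

    def test_sort_invariance(self):
        a = empirical_cdf([3.0, 1.0, 2.0, 5.0, 4.0])
        b = empirical_cdf([5.0, 4.0, 3.0, 2.0, 1.0])
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.probs, b.probs)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=60))
    def test_probs_strictly_inside_unit_interval(self, values):
        ecdf = empirical_cdf(values)
        assert np.all((ecdf.probs > 0) & (ecdf.probs < 1))
        assert np.all(np.diff(ecdf.values) >= 0)

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            empirical_cdf([1.0, 2.0, np.nan, 4.0, 5.0])

    def test_fitting_requires_five_observations(self):
        with pytest.raises(DataError):
            fit_one_component(empirical_cdf([1.0, 2.0, 3.0, 4.0]))


class TestOneComponentFit:
    def test_recovers_known_normal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 2.0, 1000)
        fit = fit_one_component(empirical_cdf(x))
        se_mean = 2.0 / np.sqrt(1000)
        se_sd = 2.0 / np.sqrt(2 * 999)
        assert abs(fit.a1 - 5.0) < 3 * se_mean
        assert abs(fit.a2 - 2.0) < 3 * se_sd
        assert fit.rss >= 0 and fit.n == 1000

    def test_symmetric_data_centres_at_zero(self):
        fit = fit_one_component(empirical_cdf([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert abs(fit.a1) < 1e-6

    def test_model_value_at_mean_is_half(self):
        fit = fit_one_component(empirical_cdf([1.0, 2.0, 3.0, 4.0, 7.0]))
        assert fit.predict(fit.a1) == pytest.approx(0.5, abs=1e-14)

    def test_zero_variance_is_fit_error(self):
        with pytest.raises(FitError):
            fit_one_component(empirical_cdf([2.0] * 10))


class TestForcedTwoComponentFit:
    def test_recovers_known_mixture(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(10, 1, 700), rng.normal(3, 1, 300)])
        fit = fit_forced_two_component(empirical_cdf(x), forced_mean=3.0)
        assert fit.a5 == pytest.approx(0.7, abs=0.05)
        assert fit.a3 == pytest.approx(10.0, abs=0.2)
        assert fit.a1 == 3.0

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mixing_weight_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 40)
        fit = fit_forced_two_component(empirical_cdf(x),
                                       forced_mean=rng.uniform(-5, 5))
        assert 0.0 <= fit.a5 <= 1.0
        assert fit.a2 > 0 and fit.a4 > 0

    def test_nesting_reduction_at_zero_weight(self):
        # the two-component model with A5 = 0 IS the one-component model
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(-5, 15, 50))
        delta = (two_component_cdf(x, 3.0, 1.2, 8.0, 2.0, 0.0)
                 - normal_cdf(x, 3.0, 1.2))
        assert np.max(np.abs(delta)) < 1e-12

    def test_grid_oracle_never_beats_optimizer(self):
        rng = np.random.default_rng(5)
        for _ in range(2):
            x = np.concatenate([rng.normal(0, 1, 14),
                                rng.normal(2.5, 0.8, 26)])
            ecdf = empirical_cdf(x)
            one = fit_one_component(ecdf)
            fit = fit_forced_two_component(ecdf, 0.0, one_fit=one)
            oracle = mixture.grid_search_rss(ecdf, 0.0)
            assert fit.rss <= oracle * (1 + 1e-9) + 1e-12


class TestReferenceFit:
    def test_recovers_reference_component_mean(self, default_table):
        cfg_mean = 0.36  # mimicking ratio_wl mean of the default generator
        fit = fit_pterochrozinae_reference(default_table, "ratio_wl")
        n = int(default_table["is_pterochrozinae"].sum())
        se = 0.05 / np.sqrt(n)
        assert abs(fit.a1 - cfg_mean) < 3 * se

    def test_near_constant_reference(self):
        import pandas as pd
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "is_pterochrozinae": [True] * 8,
            "ratio_wl": 0.4 + rng.normal(0, 1e-4, 8),
        })
        fit = fit_pterochrozinae_reference(table, "ratio_wl")
        assert fit.a1 == pytest.approx(0.4, abs=1e-3)

    def test_insufficient_reference_rows(self, default_table):
        small = default_table.copy()
        small["is_pterochrozinae"] = [True] * 3 + [False] * (len(small) - 3)
        with pytest.raises(InsufficientReferenceError):
            fit_pterochrozinae_reference(small, "ratio_wl")


class TestCompareModels:
    def test_identical_fits_prefer_one_component(self):
        one = NormalCDFFit(a1=0, a2=1, rss=1.0, n=253)
        two = ForcedTwoComponentFit(a1=0, a2=1, a3=0, a4=1, a5=0.0,
                                    rss=1.0, n=253)
        comp = compare_models(one, two)
        assert comp.f_stat == 0.0
        assert comp.p_value == 1.0
        assert comp.preferred == "one_component"

    def test_f_statistic_arithmetic(self):
        one = NormalCDFFit(a1=0, a2=1, rss=2.0, n=253)
        two = ForcedTwoComponentFit(a1=0, a2=1, a3=3, a4=1, a5=0.5,
                                    rss=1.0, n=253)
        comp = compare_models(one, two)
        assert comp.f_stat == pytest.approx(124.5)
        assert comp.df_num == 2 and comp.df_den == 249

    def test_mismatched_sample_sizes_rejected(self):
        one = NormalCDFFit(a1=0, a2=1, rss=2.0, n=100)
        two = ForcedTwoComponentFit(a1=0, a2=1, a3=3, a4=1, a5=0.5,
                                    rss=1.0, n=253)
        with pytest.raises(DataError):
            compare_models(one, two)

    def test_nesting_violation_recovered_by_refit(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 60)
        ecdf = empirical_cdf(x)
        one = fit_one_component(ecdf)
        # fabricate a bad two-component fit (worse rss than the null)
        bad = ForcedTwoComponentFit(a1=0.0, a2=1.0, a3=5.0, a4=0.1,
                                    a5=0.9, rss=one.rss * 10, n=60)
        comp = compare_models(one, bad, ecdf=ecdf, forced_mean=0.0)
        assert comp.f_stat >= 0.0

    def test_preference_requires_all_three_criteria(self):
        # a tiny rss improvement: F significant only with large n, but the
        # BIC penalty can still refuse the extra parameters
        one = NormalCDFFit(a1=0, a2=1, rss=1.0, n=50)
        two = ForcedTwoComponentFit(a1=0, a2=1, a3=1, a4=1, a5=0.1,
                                    rss=0.9, n=50)
        comp = compare_models(one, two)
        agree = (comp.p_value < 0.01 and comp.delta_aic < 0
                 and comp.delta_bic < 0)
        assert (comp.preferred == "two_component") == agree


class TestSharingFraction:
    def test_disjoint_query_shares_nothing(self):
        rule = SharingRule(half_width=0.5)
        assert sharing_fraction(100.0, [1.0, 2.0, 3.0], rule) == 0.0

    def test_identical_values_share_fully(self):
        rule = SharingRule(half_width=0.01)
        assert sharing_fraction(2.0, [2.0] * 7, rule) == 1.0

    def test_uniform_grid_count(self):
        # brute-force oracle: direct count of grid points in the interval
        grid = np.arange(1, 101) / 100.0
        rule = SharingRule(half_width=0.105)
        expected = np.sum(np.abs(grid - 0.5) <= 0.105) / 100.0
        assert expected == 0.21
        assert sharing_fraction(0.5, grid, rule) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            sharing_fraction(1.0, [], SharingRule(half_width=1.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hw1=st.floats(0, 2), hw2=st.floats(0, 2),
           query=st.floats(-3, 3))
    def test_monotone_in_half_width(self, hw1, hw2, query):
        group = np.linspace(-2, 2, 41)
        lo, hi = sorted([hw1, hw2])
        f_lo = sharing_fraction(query, group, SharingRule(half_width=lo))
        f_hi = sharing_fraction(query, group, SharingRule(half_width=hi))
        assert 0.0 <= f_lo <= f_hi <= 1.0
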
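"""YLDs, draw summaries, standardisation, aggregation, HAQ regression."""

import numpy as np
import pandas as pd
import pytest

import hearburden as hb
from hearburden.burden import (
    BurdenTable,
    StandardPopulation,
    age_standardize,
    aggregate,
    compute_ylds,
    haq_regression,
    percent_change,
    summarize_draws,
)
from hearburden.severity import DisabilityWeightTable, HealthState


class TestSummarizeDraws:
    def test_thousand_draws_use_25th_and_975th_order_statistics(self):
        mean, lo, hi = summarize_draws(np.arange(1, 1001))
        assert (lo, hi) == (25, 975)
        assert mean == pytest.approx(500.5)

    def test_constant_draws(self):
        assert summarize_draws([3.2] * 10) == (3.2, 3.2, 3.2)

    def test_hundred_draws_nearest_rank(self):
        _, lo, hi = summarize_draws(np.arange(1, 101))
        assert (lo, hi) == (3, 98)

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            summarize_draws([])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=500)
        a = summarize_draws(draws)
        b = summarize_draws(np.sort(draws)[::-1])
        assert a == pytest.approx(b, rel=1e-12)


def _cells(n=1):
    return pd.DataFrame(
        {"location": ["a"] * n, "year": [2019] * n, "sex": ["female"] * n, "age_low": [40] * n}
    )


def _pop(persons=1.0):
    return pd.DataFrame(
        {"location": ["a"], "year": [2019], "sex": ["female"], "age_low": [40], "persons": [persons]}
    )


class TestComputeYlds:
    def test_unit_prevalence_yields_disability_weight(self):
        dw = DisabilityWeightTable.default()
        surface = {("mild", False): np.ones((1, 4))}
        table = compute_ylds(surface, _cells(), dw, _pop(), dw_uncertainty=False)
        assert np.allclose(table.ylds, 0.010)

    def test_two_states_combine_linearly(self):
        """0.1 x 0.027 + 0.1 x 0.074 = 0.0101 YLD per person-year."""
        dw = DisabilityWeightTable.default()
        surface = {
            ("moderate", False): np.full((1, 4), 0.1),
            ("moderate", True): np.full((1, 4), 0.1),
        }
        table = compute_ylds(surface, _cells(), dw, _pop(), dw_uncertainty=False)
        assert table.ylds.sum(axis=0)[0] == pytest.approx(0.0101)

    def test_zero_prevalence_zero_ylds(self):
        dw = DisabilityWeightTable.default()
        table = compute_ylds({("severe", True): np.zeros((1, 4))}, _cells(), dw, _pop())
        assert np.all(table.ylds == 0)

    def test_doubling_prevalence_doubles_ylds(self):
        dw = DisabilityWeightTable.default()
        a = compute_ylds({("mild", False): np.full((1, 4), 0.2)}, _cells(), dw, _pop(), seed=5)
        b = compute_ylds({("mild", False): np.full((1, 4), 0.4)}, _cells(), dw, _pop(), seed=5)
        np.testing.assert_allclose(2 * a.ylds, b.ylds)

    def test_unmatched_state_errors(self):
        dw = DisabilityWeightTable(
            {HealthState("mild", False): (0.01, 0.004, 0.019)}
        )
        with pytest.raises(KeyError):
            compute_ylds({("severe", False): np.ones((1, 2))}, _cells(), dw, _pop())

    def test_missing_population_errors(self):
        dw = DisabilityWeightTable.default()
        pop = _pop().assign(year=1990)
        with pytest.raises(ValueError, match="population"):
            compute_ylds({("mild", False): np.ones((1, 2))}, _cells(), dw, pop)

    def test_weight_uncertainty_spreads_draws(self):
        dw = DisabilityWeightTable.default()
        table = compute_ylds(
            {("mild", False): np.ones((1, 500))}, _cells(), dw, _pop(), dw_uncertainty=True, seed=1
        )
        assert table.ylds.std() > 0
        mean, lo, hi = summarize_draws(table.ylds[0])
        assert 0.004 < lo < mean < hi < 0.03  # spans the printed interval scale


class TestAgeStandardize:
    def test_constant_rate_is_fixed_point(self):
        std = StandardPopulation(weights=pd.Series([0.3, 0.7], index=[0, 5]))
        rates = pd.Series([0.12, 0.12], index=[0, 5])
        assert age_standardize(rates, standard=std) == pytest.approx(0.12)

    def test_equal_weights_average(self):
        std = StandardPopulation(weights=pd.Series([0.5, 0.5], index=[0, 5]))
        rates = pd.Series([0.1, 0.3], index=[0, 5])
        assert age_standardize(rates, standard=std) == pytest.approx(0.2)

    def test_missing_age_group_errors(self):
        std = StandardPopulation(weights=pd.Series([0.5, 0.5], index=[0, 5]))
        with pytest.raises(ValueError):
            age_standardize(pd.Series([0.1], index=[0]), standard=std)

    def test_draw_level_standardisation(self):
        std = StandardPopulation(weights=pd.Series([0.5, 0.5], index=[0, 5]))
        rates = np.array([[0.1, 0.2], [0.3, 0.4]])  # (ages, draws)
        out = age_standardize(rates, age_lows=[0, 5], standard=std)
        np.testing.assert_allclose(out, [0.2, 0.3])

    def test_packaged_standard_sums_to_one(self):
        std = StandardPopulation.default()
        assert std.weights.sum() == pytest.approx(1.0)
        assert list(std.weights.index) == list(range(0, 100, 5))


class TestAggregate:
    def _table(self, locations, counts, n_draws=6):
        frame = pd.DataFrame(
            {
                "location": locations,
                "year": 2019,
                "sex": "female",
                "age_low": 40,
                "state": "mild",
            }
        )
        cases = np.array([[c] * n_draws for c in counts], dtype=float)
        return BurdenTable(frame=frame, cases=cases, ylds=cases * 0.01)

    def test_single_location_region_is_identity(self):
        table = self._table(["a"], [5.0])
        out = aggregate(table, {"a": "r1"}, include_global=False)
        assert np.allclose(out.cases, 5.0)

    def test_counts_add_at_draw_level(self):
        table = self._table(["a", "b"], [3.0, 4.0])
        out = aggregate(table, {"a": "r1", "b": "r1"}, include_global=False)
        assert np.allclose(out.cases, 7.0)

    def test_global_equals_sum_of_regions(self):
        table = self._table(["a", "b", "c"], [3.0, 4.0, 5.0])
        out = aggregate(table, {"a": "r1", "b": "r1", "c": "r2"})
        glob = out.cases[(out.frame["location"] == "global").to_numpy()]
        regs = out.cases[(out.frame["location"] != "global").to_numpy()]
        np.testing.assert_allclose(glob.sum(axis=0), regs.sum(axis=0))

    def test_region_interval_narrower_than_summed_member_intervals(self):
        rng = np.random.default_rng(4)
        n_draws = 400
        frame = pd.DataFrame(
            {"location": ["a", "b"], "year": 2019, "sex": "female", "age_low": 40, "state": "mild"}
        )
        cases = rng.normal(100, 10, (2, n_draws))
        table = BurdenTable(frame=frame, cases=cases, ylds=np.zeros_like(cases))
        out = aggregate(table, {"a": "r1", "b": "r1"}, include_global=False)
        _, lo, hi = summarize_draws(out.cases[0])
        widths = [summarize_draws(cases[i])[2] - summarize_draws(cases[i])[1] for i in range(2)]
        assert (hi - lo) <= sum(widths)

    def test_unmapped_location_errors(self):
        with pytest.raises(ValueError, match="hierarchy"):
            aggregate(self._table(["a"], [1.0]), {})


class TestPercentChange:
    def test_no_change_is_zero(self):
        assert percent_change(np.ones(10), np.ones(10))[0] == pytest.approx(0.0)

    def test_point_estimates_1990_to_2019(self):
        """225.3 to 403.3 million is a 79.0% increase on point estimates."""
        mean, _, _ = percent_change(225.3, 403.3)
        assert round(mean, 1) == 79.0

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            percent_change(np.array([1.0, 0.0]), np.array([2.0, 2.0]))

    def test_draw_level_interval(self):
        rng = np.random.default_rng(2)
        a = rng.normal(100, 5, 1000)
        b = rng.normal(150, 5, 1000)
        mean, lo, hi = percent_change(a, b)
        assert lo < mean < hi
        assert mean == pytest.approx(50, abs=5)


class TestHaqRegression:
    def test_perfect_linear_relationship(self):
        haq = pd.Series(np.linspace(20, 90, 30), index=[f"l{i}" for i in range(30)])
        ylds = 500 - 3 * haq
        slope, intercept, r2 = haq_regression(ylds, haq)
        assert slope == pytest.approx(-3.0)
        assert r2 == pytest.approx(1.0)

    def test_permuted_haq_explains_nothing(self):
        rng = np.random.default_rng(3)
        haq = pd.Series(rng.uniform(20, 90, 200), index=[f"l{i}" for i in range(200)])
        ylds = pd.Series(rng.normal(300, 30, 200), index=haq.index)
        _, _, r2 = haq_regression(ylds, haq)
        assert abs(r2) < 0.05

    def test_negative_slope_when_burden_concentrates_at_low_haq(self):
        """Higher healthcare access tracks lower loss burden in the default world."""
        truth = hb.make_truth(hb.WorldConfig(), seed=11)
        std = StandardPopulation(weights=pd.Series(1.0, index=list(range(0, 100, 5))))
        mp = truth.moderate_plus().groupby(["location", "age_low"]).mean()
        asr = mp.groupby("location").apply(lambda g: age_standardize(g.droplevel(0), standard=std))
        haq = truth.covariates[truth.covariates["year"] == 2019].set_index("location")["haq"]
        slope, _, _ = haq_regression(asr, haq)
        assert slope < 0

    def test_pipeline_haq_fit_is_finite(self, tiny_result):
        slope, intercept, r2 = tiny_result.haq_fit
        assert np.isfinite([slope, intercept, r2]).all()
        assert r2 <= 1.0

    def test_constant_haq_errors(self):
        haq = pd.Series([50.0] * 5, index=list("abcde"))
        ylds = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        with pytest.raises(ValueError):
            haq_regression(ylds, haq)

    def test_too_few_locations_errors(self):
        haq = pd.Series([50.0, 60.0], index=list("ab"))
        with pytest.raises(ValueError):
            haq_regression(haq, haq)


def test_burden_summaries_are_ordered(tiny_result):
    summary = tiny_result.burden_regional.summary()
    for name in ("cases", "ylds"):
        assert (summary[f"{name}_lower"] <= summary[f"{name}_mean"] + 1e-12).all()
        assert (summary[f"{name}_mean"] <= summary[f"{name}_upper"] + 1e-12).all()
        assert (summary[f"{name}_mean"] >= 0).all()
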
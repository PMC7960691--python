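"""Sex splitting, severity crosswalks and age splitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

import hearburden as hb
from hearburden.harmonize import (
    CrosswalkModel,
    PrevalenceDatum,
    age_split,
    apply_crosswalk,
    apply_sex_split,
    fit_crosswalk,
    fit_sex_ratio,
    process_all,
    reference_range_for,
)


def _pair(location, age_low, pf, pm, n=5000, year=2019):
    common = dict(
        location=location,
        year=year,
        age_low=age_low,
        age_high=age_low + 5,
        db_low=35.0,
        db_high=math.inf,
        effective_sample_size=n,
    )
    return [
        PrevalenceDatum(sex="female", prevalence=pf, **common),
        PrevalenceDatum(sex="male", prevalence=pm, **common),
    ]


def _flat_population(locations, years, value=1000.0):
    rows = []
    for loc in locations:
        for year in years:
            for sex in ("female", "male"):
                for age in range(0, 100, 5):
                    rows.append(
                        {"location": loc, "year": year, "sex": sex, "age_low": age, "persons": value}
                    )
    return pd.DataFrame(rows)


class TestSexRatio:
    def test_equal_prevalence_gives_zero_log_ratio(self):
        data = sum((_pair(f"loc{i}", 40, 0.2, 0.2) for i in range(5)), [])
        model = fit_sex_ratio(data, trim=0.0)
        assert model.log_ratio(40)[0] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_true_ratio_from_simulated_pairs(self):
        """Simulation oracle: 500 binomial pairs generated at ratio 1.5."""
        rng = np.random.default_rng(42)
        true_ratio, n = 1.5, 4000
        data = []
        for i in range(500):
            pm = rng.uniform(0.05, 0.2)
            pf = min(true_ratio * pm, 0.95)
            xf, xm = rng.binomial(n, pf), rng.binomial(n, pm)
            data.extend(_pair(f"loc{i}", 40, xf / n, xm / n, n=n))
        model = fit_sex_ratio(data, trim=0.0)
        est, se, tau2 = model.log_ratio(40)
        assert abs(est - math.log(true_ratio)) <= 2 * math.sqrt(se**2 + tau2 / 500)

    def test_trimming_removes_gross_outlier(self):
        rng = np.random.default_rng(7)
        clean = []
        for i in range(20):
            pm = 0.1 + 0.01 * rng.standard_normal()
            clean.extend(_pair(f"loc{i}", 40, min(1.2 * pm, 1), pm))
        outlier = _pair("loc_out", 40, 0.9, 0.05)
        oracle = fit_sex_ratio(clean, trim=0.0).log_ratio(40)
        trimmed = fit_sex_ratio(clean + outlier, trim=0.1).log_ratio(40)
        assert abs(trimmed[0] - oracle[0]) <= 2 * oracle[1]

    def test_requires_pairs(self):
        lone = [_pair("a", 40, 0.2, 0.2)[0]]  # female row only
        with pytest.raises(ValueError):
            fit_sex_ratio(lone)


class TestSexSplit:
    def _model(self, log_ratio):
        by_age = pd.DataFrame(
            {"log_ratio": [log_ratio], "se": [0.0], "tau2": [0.0], "n_pairs": [10]},
            index=pd.Index([40.0], name="age_low"),
        )
        return hb.SexRatioModel(by_age=by_age, pooled=(log_ratio, 0.0, 0.0), trim=0.1)

    def _datum(self, p):
        return PrevalenceDatum("a", 2019, "both", 40, 45, 35, math.inf, p, 1000)

    def test_unit_ratio_equal_populations(self):
        pop = _flat_population(["a"], [2019])
        f, m = apply_sex_split(self._datum(0.15), self._model(0.0), pop)
        assert f.prevalence == pytest.approx(0.15) and m.prevalence == pytest.approx(0.15)

    def test_zero_prevalence_splits_to_zero(self):
        pop = _flat_population(["a"], [2019])
        f, m = apply_sex_split(self._datum(0.0), self._model(0.5), pop)
        assert f.prevalence == 0.0 and m.prevalence == 0.0

    def test_ratio_two_equal_populations(self):
        """p_f = 2 p_m and (p_f + p_m)/2 = 0.15 solve to 0.20 / 0.10."""
        pop = _flat_population(["a"], [2019])
        f, m = apply_sex_split(self._datum(0.15), self._model(math.log(2)), pop)
        assert f.prevalence == pytest.approx(0.20, abs=1e-12)
        assert m.prevalence == pytest.approx(0.10, abs=1e-12)

    @pytest.mark.parametrize("log_ratio, p", [(0.3, 0.07), (-0.5, 0.4), (1.1, 0.02)])
    def test_conserves_expected_cases(self, log_ratio, p):
        pop = _flat_population(["a"], [2019])
        pop.loc[pop["sex"] == "female", "persons"] = 1700.0
        f, m = apply_sex_split(self._datum(p), self._model(log_ratio), pop)
        lhs = 1700 * f.prevalence + 1000 * m.prevalence
        assert lhs == pytest.approx(2700 * p, abs=1e-9)
        assert f.prevalence == pytest.approx(math.exp(log_ratio) * m.prevalence, rel=1e-12)

    def test_zero_population_errors(self):
        pop = _flat_population(["a"], [2019], value=0.0)
        with pytest.raises(ValueError):
            apply_sex_split(self._datum(0.1), self._model(0.0), pop)


class TestCrosswalk:
    def test_identical_range_gives_zero_coefficient(self, records):
        model = fit_crosswalk(records, [(35.0, math.inf)])
        (_, coef, _) = model.lookup(35.0, math.inf)
        assert coef == pytest.approx(0.0, abs=1e-12)

    def test_subset_range_gives_nonpositive_coefficient(self, records):
        model = fit_crosswalk(records, [(25.0, math.inf)])
        ref, coef, _ = model.lookup(25.0, math.inf)
        assert ref == (20.0, math.inf)
        assert coef <= 0  # [25, inf) is a subset of [20, inf)

    def test_nearest_boundary_snapping(self):
        scheme = hb.SeverityScheme.default()
        assert reference_range_for((30.0, math.inf), scheme) == (35.0, math.inf)
        assert reference_range_for((25.0, math.inf), scheme) == (20.0, math.inf)

    def test_recovers_truth_logit_difference(self, truth, records):
        """Oracle: the exact logit difference computed on the generative truth."""
        model = fit_crosswalk(records, [(30.0, math.inf)])
        _, coef, se = model.lookup(30.0, math.inf)
        # truth P(pta >= 30) = moderate_plus + mild * P(within-band draw >= 30)
        tail = beta_dist.sf((30 - 20) / 15, 1.2, 2.2)
        prev = truth.prevalence
        p_alt = prev[list(hb.CATEGORY_ORDER[2:])].sum(axis=1) + prev["mild"] * tail
        p_ref = prev[list(hb.CATEGORY_ORDER[2:])].sum(axis=1)
        cells = pd.DataFrame({"alt": p_alt, "ref": p_ref}).reset_index()
        by_cell = cells.groupby(["sex", "age_low"])[["alt", "ref"]].mean()
        oracle = float(np.mean(logit(by_cell["alt"]) - logit(by_cell["ref"])))
        assert abs(coef - oracle) <= 2 * se

    def test_apply_zero_coefficient_is_identity(self):
        model = CrosswalkModel({(30.0, math.inf): ((35.0, math.inf), 0.0, 0.01, 10)})
        d = PrevalenceDatum("a", 2019, "female", 40, 45, 30, math.inf, 0.25, 400)
        out = apply_crosswalk(d, model)
        assert out.prevalence == pytest.approx(0.25, abs=1e-12)
        assert out.definition == "reference"
        assert (out.db_low, out.db_high) == (35.0, math.inf)

    def test_apply_matches_closed_form(self):
        model = CrosswalkModel({(30.0, math.inf): ((35.0, math.inf), 0.4, 0.01, 10)})
        d = PrevalenceDatum("a", 2019, "female", 40, 45, 30, math.inf, 0.5, 400)
        out = apply_crosswalk(d, model)
        assert out.prevalence == pytest.approx(float(expit(-0.4)), abs=1e-9)

    def test_round_trip_inverts(self):
        fwd = CrosswalkModel({(30.0, math.inf): ((35.0, math.inf), 0.37, 0.01, 10)})
        bwd = CrosswalkModel({(35.0, math.inf): ((35.0, math.inf), -0.37, 0.01, 10)})
        d = PrevalenceDatum("a", 2019, "female", 40, 45, 30, math.inf, 0.31, 400)
        back = apply_crosswalk(apply_crosswalk(d, fwd), bwd)
        assert back.prevalence == pytest.approx(0.31, abs=1e-12)

    def test_boundary_prevalence_uses_continuity_offset(self):
        model = CrosswalkModel({(30.0, math.inf): ((35.0, math.inf), 0.0, 0.01, 10)})
        d = PrevalenceDatum("a", 2019, "female", 40, 45, 30, math.inf, 0.0, 100)
        out = apply_crosswalk(d, model)
        assert 0 < out.prevalence < 0.01  # half a case over n+1

    def test_missing_range_errors(self):
        model = CrosswalkModel({})
        d = PrevalenceDatum("a", 2019, "female", 40, 45, 30, math.inf, 0.2, 100)
        with pytest.raises(KeyError):
            apply_crosswalk(d, model)


class TestAgeSplit:
    def _pattern(self, values):
        return pd.Series(values, index=pd.Index(range(0, 100, 5), name="age_low"))

    def test_flat_pattern_replicates_prevalence(self):
        pop = _flat_population(["a"], [2019])
        d = PrevalenceDatum("a", 2019, "female", 20, 50, 35, math.inf, 0.15, 3000)
        parts = age_split(d, self._pattern([1.0] * 20), pop)
        assert len(parts) == 6
        assert all(p.prevalence == pytest.approx(0.15, abs=1e-12) for p in parts)

    def test_doubling_pattern_equal_populations(self):
        """Pattern (1, 2) with equal populations and mean 0.15 gives 0.10 / 0.20."""
        pop = _flat_population(["a"], [2019])
        pattern = self._pattern([1.0] * 20)
        pattern.loc[45] = 2.0
        d = PrevalenceDatum("a", 2019, "female", 40, 65, 35, math.inf, 0.15, 1000)
        # restrict to a two-group span via a 25-year datum over 40-65, groups 40..60
        d2 = PrevalenceDatum("a", 2019, "female", 40, 50, 35, math.inf, 0.15, 1000)
        parts = age_split(d2, pattern, pop, max_span=5)
        assert parts[0].prevalence == pytest.approx(0.10, abs=1e-12)
        assert parts[1].prevalence == pytest.approx(0.20, abs=1e-12)

    def test_short_span_passes_through(self):
        pop = _flat_population(["a"], [2019])
        d = PrevalenceDatum("a", 2019, "female", 40, 45, 35, math.inf, 0.2, 500)
        assert age_split(d, self._pattern([1.0] * 20), pop) == [d]

    def test_twenty_year_span_passes_through(self):
        pop = _flat_population(["a"], [2019])
        d = PrevalenceDatum("a", 2019, "female", 40, 60, 35, math.inf, 0.2, 500)
        assert age_split(d, self._pattern([1.0] * 20), pop) == [d]

    def test_conserves_expected_cases_with_uneven_population(self):
        pop = _flat_population(["a"], [2019])
        rng = np.random.default_rng(3)
        pop["persons"] = rng.uniform(500, 2000, len(pop))
        pattern = self._pattern(np.linspace(0.5, 4.0, 20))
        d = PrevalenceDatum("a", 2019, "male", 20, 60, 35, math.inf, 0.08, 2000)
        parts = age_split(d, pattern, pop)
        pops = [
            pop[
                (pop["sex"] == "male") & (pop["age_low"] == p.age_low) & (pop["year"] == 2019)
            ]["persons"].sum()
            for p in parts
        ]
        total = sum(pops)
        assert sum(n * p.prevalence for n, p in zip(pops, parts)) == pytest.approx(
            total * 0.08, rel=1e-9
        )

    def test_missing_pattern_errors(self):
        pop = _flat_population(["a"], [2019])
        pattern = pd.Series([1.0], index=pd.Index([0], name="age_low"))
        d = PrevalenceDatum("a", 2019, "female", 20, 60, 35, math.inf, 0.1, 500)
        with pytest.raises(ValueError):
            age_split(d, pattern, pop)


def test_pipeline_idempotent_on_reference_rows(records, truth, population):
    """Reference, sex-specific, 5-year rows pass through the whole stage unchanged."""
    survey = hb.tabulate_survey(records, severity_ranges=[(35.0, math.inf)])
    sex_model = fit_sex_ratio(survey)
    crosswalk = fit_crosswalk(records, [(30.0, math.inf)])
    pattern = truth.moderate_plus().groupby("age_low").mean()
    subset = survey[:40]
    out = process_all(subset, sex_model, crosswalk, pattern, population)
    assert out == subset
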
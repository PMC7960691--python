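"""Forecast regression: trend recovery, projection identities, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import hearburden as hb
from hearburden.burden import StandardPopulation, age_standardize, percent_change
from hearburden.forecast import fit_forecast, project

YEARS = (1990, 1995, 2000, 2005, 2010, 2015, 2019)
AGES = tuple(range(0, 100, 5))


def _rates(rate_fn, regions=("r1", "r2"), years=YEARS, sexes=("female", "male")):
    rows = []
    for reg in regions:
        for sex in sexes:
            for year in years:
                for age in AGES:
                    rows.append(
                        {
                            "region": reg,
                            "sex": sex,
                            "year": year,
                            "age_low": age,
                            "rate": rate_fn(reg, sex, year, age),
                        }
                    )
    return pd.DataFrame(rows)


def _population(years, regions=("r1", "r2"), persons=1000.0, ageing=0.0):
    rows = []
    for reg in regions:
        for year in years:
            for sex in ("female", "male"):
                scale = 30.0 + ageing * (year - 2019)
                shape = np.exp(-np.asarray(AGES) / scale)
                shape = shape / shape.sum()
                for age, s in zip(AGES, shape):
                    rows.append(
                        {
                            "location": reg,
                            "year": year,
                            "sex": sex,
                            "age_low": age,
                            "persons": persons * s,
                        }
                    )
    return pd.DataFrame(rows)


HIER = {"r1": "r1", "r2": "r2"}


class TestFit:
    def test_constant_rates_give_flat_projection(self):
        rates = _rates(lambda reg, sex, year, age: 0.05)
        model = fit_forecast(rates, resamples=30, seed=1)
        pop = _population((2019, 2050))
        out = project(model, (2019, 2050), pop, HIER)
        summ = out.summary()
        g19 = summ[(summ.location == "global") & (summ.year == 2019)]["cases_mean"].sum()
        g50 = summ[(summ.location == "global") & (summ.year == 2050)]["cases_mean"].sum()
        assert g50 == pytest.approx(g19, rel=1e-6)

    def test_recovers_regional_logit_trends(self):
        """Known logit-linear year trends per region are recovered within 2 SE."""
        slopes = {"r1": 0.004, "r2": 0.012}
        rates = _rates(
            lambda reg, sex, year, age: float(
                expit(-3 + 0.03 * age + slopes[reg] * (year - 2005))
            )
        )
        model = fit_forecast(rates, resamples=100, seed=2)
        yr_mean = float(np.mean(rates["year"].unique()))
        for sex in ("female", "male"):
            draws = model.coef_draws[sex]
            k_basis = model.age_df
            year_idx = k_basis  # column order: basis, year, region ind, region x year
            inter_idx = k_basis + 2
            slope_r1 = draws[:, year_idx]
            slope_r2 = draws[:, year_idx] + draws[:, inter_idx]
            assert abs(slope_r1.mean() - slopes["r1"]) <= max(2 * slope_r1.std(), 1e-4)
            assert abs(slope_r2.mean() - slopes["r2"]) <= max(2 * slope_r2.std(), 1e-4)

    def test_same_seed_identical_draws(self):
        rates = _rates(lambda reg, sex, year, age: 0.05 + 0.001 * (year - 1990))
        a = fit_forecast(rates, resamples=20, seed=5)
        b = fit_forecast(rates, resamples=20, seed=5)
        np.testing.assert_array_equal(a.coef_draws["female"], b.coef_draws["female"])

    def test_in_sample_point_prediction_matches_fit(self):
        rates = _rates(lambda reg, sex, year, age: float(expit(-2 + 0.02 * age)))
        model = fit_forecast(rates, resamples=10, seed=3)
        sub = rates[(rates.sex == "female")]
        pred = model.predict_rates(
            "female", sub["region"].to_numpy(), sub["year"].to_numpy(), sub["age_low"].to_numpy(), draws=False
        )
        # zero-residual input: fitted values reproduce the inputs
        np.testing.assert_allclose(pred, sub["rate"].to_numpy(), atol=1e-10)

    def test_single_region_is_rank_deficient(self):
        rates = _rates(lambda *a: 0.05, regions=("r1",))
        with pytest.raises(ValueError, match="region"):
            fit_forecast(rates, resamples=5, seed=0)

    def test_single_year_rejected(self):
        rates = _rates(lambda *a: 0.05, years=(2019,))
        with pytest.raises(ValueError, match="year"):
            fit_forecast(rates, resamples=5, seed=0)


class TestProject:
    def test_population_doubling_doubles_cases(self):
        rates = _rates(lambda *a: 0.05)
        model = fit_forecast(rates, resamples=20, seed=1)
        pop1 = _population((2050,))
        pop2 = _population((2050,), persons=2000.0)
        c1 = project(model, (2050,), pop1, HIER).summary()["cases_mean"]
        c2 = project(model, (2050,), pop2, HIER).summary()["cases_mean"]
        np.testing.assert_allclose(2 * c1, c2, rtol=1e-12)

    def test_global_is_sum_of_regions_per_draw(self):
        rates = _rates(lambda reg, sex, year, age: 0.02 + (0.01 if reg == "r2" else 0))
        model = fit_forecast(rates, resamples=25, seed=2)
        out = project(model, (2040,), _population((2040,)), HIER)
        glob = out.cases[(out.frame["location"] == "global").to_numpy()]
        regions = out.cases[(out.frame["location"] != "global").to_numpy()]
        per_sex = out.frame[out.frame["location"] == "global"]["sex"].tolist()
        for i, sex in enumerate(per_sex):
            member = out.frame[(out.frame["location"] != "global") & (out.frame["sex"] == sex)]
            np.testing.assert_allclose(
                glob[i], out.cases[member.index.to_numpy()].sum(axis=0), rtol=1e-12
            )

    def test_ageing_population_raises_crude_but_not_standardised_prevalence(self):
        """Stable age-specific rates + ageing population: more cases, flat ASR."""
        rate_fn = lambda reg, sex, year, age: float(expit(-4 + 0.05 * age))  # noqa: E731
        rates = _rates(rate_fn)
        model = fit_forecast(rates, resamples=20, seed=4)
        pop = _population((2019, 2050), ageing=0.25)  # age scale grows into the future
        out = project(model, (2019, 2050), pop, HIER).summary()

        def crude(year):
            cases = out[(out.location == "global") & (out.year == year)]["cases_mean"].sum()
            persons = pop[pop.year == year]["persons"].sum()
            return cases / persons

        assert crude(2050) > crude(2019) * 1.05

        std = StandardPopulation(weights=pd.Series(1.0, index=list(AGES)))
        asr = {}
        for year in (2019, 2050):
            pred = model.predict_rates(
                "female",
                np.array(["r1"] * len(AGES)),
                np.full(len(AGES), year, dtype=float),
                np.array(AGES, dtype=float),
                draws=False,
            )
            asr[year] = age_standardize(pred, age_lows=AGES, standard=std)
        assert asr[2050] == pytest.approx(asr[2019], rel=0.02)

    def test_missing_population_year_errors(self):
        rates = _rates(lambda *a: 0.05)
        model = fit_forecast(rates, resamples=5, seed=0)
        with pytest.raises(ValueError, match="2050"):
            project(model, (2050,), _population((2019,)), HIER)

    def test_no_clipping_under_logit_link(self):
        rates = _rates(lambda *a: 0.05)
        model = fit_forecast(rates, resamples=5, seed=0)
        assert model.clip_count == 0
        out = project(model, (2050,), _population((2050,)), HIER)
        assert (out.cases >= 0).all()
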
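"""Forecasting severity-specific prevalence to mid-century.

Age-specific prevalence rates for the historical years (1990, 1995, ...,
2019) enter a sex-specific regression on the logit scale with year, region
and age as predictors, a region x year interaction and a cubic B-spline on
age.  The model is refitted 1000 times under a residual bootstrap; each
coefficient draw predicts rates for 2030/2040/2050, which are multiplied by
the forecasted population and aggregated to regional and global case counts.
The logit link keeps every predicted rate inside (0, 1); a clip counter is
still surfaced for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .burden import BurdenTable
from .prevalence import _spline_basis

log = logging.getLogger(__name__)


@dataclass
class ForecastModel:
    """Bootstrap coefficient draws of the region/year/age rate regression."""

    regions: tuple[str, ...]
    year_center: float
    age_df: int
    age_range: tuple[float, float]
    coef_draws: dict[str, np.ndarray]  # sex -> (resamples, k)
    coef_fit: dict[str, np.ndarray]  # sex -> (k,) point fit
    clip_count: int = 0

    def design(self, regions: np.ndarray, years: np.ndarray, ages: np.ndarray) -> np.ndarray:
        basis = _spline_basis(ages.astype(float) + 2.5, self.age_df, self.age_range)
        yr = (years - self.year_center)[:, None].astype(float)
        cols = [basis, yr]
        for reg in self.regions[1:]:
            ind = (regions == reg).astype(float)[:, None]
            cols.append(ind)
            cols.append(ind * yr)
        return np.column_stack(cols)

    def predict_rates(
        self, sex: str, regions: np.ndarray, years: np.ndarray, ages: np.ndarray, draws: bool = True
    ) -> np.ndarray:
        """Predicted prevalence rates; (n, resamples) or point (n,)."""
        X = self.design(regions, years, ages)
        if draws:
            return expit(X @ self.coef_draws[sex].T)
        return expit(X @ self.coef_fit[sex])


def fit_forecast(
    rates: pd.DataFrame,
    resamples: int = 1000,
    seed: int = 0,
    age_df: int = 6,
) -> ForecastModel:
    """Fit the forecasting regression on historical age-specific rates.

    ``rates`` needs columns ``region, sex, year, age_low, rate`` covering at
    least two input years with every region present in every year.
    """
    required = {"region", "sex", "year", "age_low", "rate"}
    if not required <= set(rates.columns):
        raise ValueError(f"rates frame must have columns {sorted(required)}")
    years = np.sort(rates["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least 2 input years to fit a trend")
    regions = tuple(sorted(rates["region"].unique()))
    if len(regions) < 2:
        raise ValueError("rank-deficient design: need at least 2 regions for region x year terms")
    for year in years:
        present = set(rates.loc[rates["year"] == year, "region"])
        if present != set(regions):
            raise ValueError(f"regions missing in year {year}: {sorted(set(regions) - present)}")

    ages = np.sort(rates["age_low"].unique()).astype(float)
    age_range = (float(ages.min()), float(ages.max() + 5.0))
    year_center = float(years.mean())
    rng = np.random.default_rng(seed)

    model = ForecastModel(
        regions=regions,
        year_center=year_center,
        age_df=age_df,
        age_range=age_range,
        coef_draws={},
        coef_fit={},
    )
    eps = 1e-9
    for sex, sub in rates.groupby("sex", observed=True):
        X = model.design(
            sub["region"].to_numpy(), sub["year"].to_numpy(dtype=float), sub["age_low"].to_numpy()
        )
        y = logit(np.clip(sub["rate"].to_numpy(dtype=float), eps, 1 - eps))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        if not np.all(np.isfinite(beta)):
            raise ValueError(f"forecast regression failed for sex {sex!r}")
        resid = y - X @ beta
        draws = np.empty((resamples, len(beta)))
        for r in range(resamples):
            y_star = X @ beta + rng.choice(resid, size=len(resid), replace=True)
            draws[r], *_ = np.linalg.lstsq(X, y_star, rcond=None)
        model.coef_fit[str(sex)] = beta
        model.coef_draws[str(sex)] = draws
    return model


def project(
    model: ForecastModel,
    years: Sequence[int],
    population_forecast: pd.DataFrame,
    hierarchy: Mapping[str, str],
    state_label: str = "moderate_plus",
) -> BurdenTable:
    """Project case counts for the requested years.

    Per coefficient draw, predicted age-specific rates are multiplied by the
    forecasted population (aggregated to regions via ``hierarchy``) and
    summed over ages; global counts are the draw-level sum of regions.
    Returns a :class:`~hearburden.burden.BurdenTable` whose rows are
    (region-or-global, year, sex, all-ages) case draws; the YLD block is zero
    (forecasts are of prevalent cases).
    """
    pop = population_forecast.copy()
    unmapped = sorted(set(pop["location"]) - set(hierarchy))
    if unmapped:
        raise ValueError(f"population locations not in hierarchy: {unmapped}")
    pop["region"] = pop["location"].map(dict(hierarchy))
    pop = pop.groupby(["region", "year", "sex", "age_low"], observed=True, as_index=False)["persons"].sum()

    frames, case_rows = [], []
    for year in years:
        sub_pop = pop[pop["year"] == year]
        if sub_pop.empty:
            raise ValueError(f"population forecast missing year {year}")
        for sex in model.coef_draws:
            ss = sub_pop[sub_pop["sex"] == sex]
            missing = set(model.regions) - set(ss["region"])
            if missing:
                raise ValueError(f"population forecast missing regions {sorted(missing)} in {year}")
            rates = model.predict_rates(
                sex,
                ss["region"].to_numpy(),
                ss["year"].to_numpy(dtype=float),
                ss["age_low"].to_numpy(dtype=float),
            )  # (rows, R)
            cases = rates * ss["persons"].to_numpy(dtype=float)[:, None]
            tmp = ss[["region"]].copy().reset_index(drop=True)
            for region, idx in tmp.groupby("region", observed=True).indices.items():
                frames.append({"location": region, "year": year, "sex": sex, "age_low": -1, "state": state_label})
                case_rows.append(cases[idx].sum(axis=0))
    frame = pd.DataFrame(frames)
    cases_arr = np.array(case_rows)

    # draw-level global totals per (year, sex)
    g_frames, g_rows = [], []
    for (year, sex), idx in frame.groupby(["year", "sex"], observed=True).indices.items():
        g_frames.append({"location": "global", "year": year, "sex": sex, "age_low": -1, "state": state_label})
        g_rows.append(cases_arr[idx].sum(axis=0))
    frame = pd.concat([frame, pd.DataFrame(g_frames)], ignore_index=True)
    cases_arr = np.vstack([cases_arr, np.array(g_rows)])
    return BurdenTable(frame=frame, cases=cases_arr, ylds=np.zeros_like(cases_arr))
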
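"""Years lived with disability, uncertainty summaries and aggregation.

YLD rate = prevalence x disability weight, per health state, per draw; counts
multiply the rate by population.  Uncertainty intervals follow the ordered-
draw convention: for D = 1000 the 95% interval is exactly the 25th and 975th
order statistics; for other D the nearest-rank 2.5/97.5 empirical percentiles
(which reproduce the 25th/975th rule at D = 1000).  Aggregation always sums
counts at draw level before summarising, so regional and global intervals
reflect the joint draws rather than naively added bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit, expit

from .prevalence import CELL_KEYS, DrawSurface
from .severity import DisabilityWeightTable, HealthState

__all__ = [
    "summarize_draws",
    "StandardPopulation",
    "BurdenTable",
    "compute_ylds",
    "age_standardize",
    "aggregate",
    "percent_change",
    "haq_regression",
]


def summarize_draws(draws: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """(mean, lower, upper) of a draw vector under the ordered-draw convention.

    Lower/upper are the nearest-rank 2.5% and 97.5% order statistics:
    ranks ceil(0.025 D) and ceil(0.975 D).  For D = 1000 these are the 25th
    and 975th ordered draws.
    """
    arr = np.asarray(draws, dtype=float)
    if arr.size < 1:
        raise ValueError("empty draw vector")
    if arr.size == 1:
        v = float(arr[0])
        return v, v, v
    s = np.sort(arr)
    d = arr.size
    lo = s[math.ceil(0.025 * d) - 1]
    hi = s[math.ceil(0.975 * d) - 1]
    return float(arr.mean()), float(lo), float(hi)


@dataclass
class StandardPopulation:
    """Age-group weights (summing to 1) for age standardisation."""

    weights: pd.Series  # index age_low

    def __post_init__(self) -> None:
        total = float(self.weights.sum())
        if total <= 0:
            raise ValueError("standard population weights must be positive")
        self.weights = self.weights / total

    @classmethod
    def default(cls) -> "StandardPopulation":
        """Packaged WHO World Standard-style weights."""
        with resources.files("hearburden.data").joinpath("standard_population.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t", comment="#")
        return cls(weights=frame.set_index("age_low")["weight"])

    @classmethod
    def from_population(cls, population: pd.DataFrame, year: int | None = None) -> "StandardPopulation":
        """Standard derived from a population table's own global age structure."""
        pop = population if year is None else population[population["year"] == year]
        return cls(weights=pop.groupby("age_low")["persons"].sum())


def age_standardize(
    rates: np.ndarray | pd.Series,
    age_lows: Sequence[float] | None = None,
    standard: StandardPopulation | None = None,
) -> float | np.ndarray:
    """Weighted sum of age-specific rates under a standard population.

    ``rates`` may be a Series indexed by age_low (point rates), a 1-D array
    with ``age_lows`` given, or a 2-D array ``(n_ages, D)`` of draws (returns
    a length-D vector).
    """
    standard = standard or StandardPopulation.default()
    if isinstance(rates, pd.Series):
        age_lows = rates.index.to_numpy(dtype=float)
        values = rates.to_numpy(dtype=float)
    else:
        if age_lows is None:
            raise ValueError("age_lows required when rates is an array")
        values = np.asarray(rates, dtype=float)
        age_lows = np.asarray(age_lows, dtype=float)
    missing = [a for a in standard.weights.index if a not in set(age_lows)]
    if missing:
        raise ValueError(f"rates missing standard age groups: {missing}")
    w = standard.weights.reindex(age_lows).to_numpy()
    if values.ndim == 1:
        return float(np.sum(w * values))
    return w @ values


@dataclass
class BurdenTable:
    """Draw-level case counts and YLDs per (location, year, sex, age, state)."""

    frame: pd.DataFrame  # columns: location, year, sex, age_low, state
    cases: np.ndarray  # (n_rows, D) persons
    ylds: np.ndarray  # (n_rows, D) person-years

    def __post_init__(self) -> None:
        if self.cases.shape != self.ylds.shape or self.cases.shape[0] != len(self.frame):
            raise ValueError("frame/cases/ylds shapes disagree")

    @property
    def n_draws(self) -> int:
        return self.cases.shape[1]

    def summary(self) -> pd.DataFrame:
        """Mean and 95% UI per row for both cases and YLDs."""
        out = self.frame.copy()
        for name, arr in (("cases", self.cases), ("ylds", self.ylds)):
            stats = np.array([summarize_draws(row) for row in arr])
            out[[f"{name}_mean", f"{name}_lower", f"{name}_upper"]] = stats
        return out

    def totals(self, by: Sequence[str]) -> "BurdenTable":
        """Sum draws over all keys not listed in ``by`` (draw-level addition)."""
        by = list(by)
        grouped = self.frame.groupby(by, observed=True, sort=True).indices
        keys, case_rows, yld_rows = [], [], []
        for key, idx in grouped.items():
            keys.append(key if isinstance(key, tuple) else (key,))
            case_rows.append(self.cases[idx].sum(axis=0))
            yld_rows.append(self.ylds[idx].sum(axis=0))
        frame = pd.DataFrame(keys, columns=by)
        return BurdenTable(frame=frame, cases=np.array(case_rows), ylds=np.array(yld_rows))


def _weight_draws(
    table: DisabilityWeightTable,
    state: HealthState,
    n_draws: int,
    uncertainty: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    w, lo, hi = table.interval(state)
    if not uncertainty or w <= 0 or hi <= lo or lo <= 0:
        return np.full(n_draws, w)
    # logit-normal matched to the printed 95% interval
    mu = logit(w)
    sigma = (logit(hi) - logit(lo)) / (2 * 1.959963984540054)
    return expit(rng.normal(mu, sigma, size=n_draws))


def compute_ylds(
    state_surface: Mapping[tuple, np.ndarray],
    cells: pd.DataFrame,
    dw_table: DisabilityWeightTable,
    population: pd.DataFrame,
    dw_uncertainty: bool = True,
    seed: int = 0,
) -> BurdenTable:
    """Convert health-state prevalence draws into case counts and YLDs.

    ``state_surface`` maps ``(severity, ringing)`` keys to ``(n_cells, D)``
    prevalence arrays over ``cells``; disability-weight uncertainty is
    propagated per draw from a logit-normal matched to each state's interval
    when ``dw_uncertainty`` is set.
    """
    rng = np.random.default_rng(seed)
    merged = cells[CELL_KEYS].merge(population, on=CELL_KEYS, how="left", validate="many_to_one")
    if merged["persons"].isna().any():
        bad = merged[merged["persons"].isna()][CELL_KEYS].head()
        raise ValueError(f"population missing for cells such as:\n{bad}")
    persons = merged["persons"].to_numpy(dtype=float)[:, None]

    frames, case_blocks, yld_blocks = [], [], []
    for key, prev in state_surface.items():
        severity, ringing = key[0], bool(key[-1])
        state = HealthState(severity, ringing)
        wd = _weight_draws(dw_table, state, prev.shape[1], dw_uncertainty, rng)
        frame = cells[CELL_KEYS].copy()
        frame["state"] = state.name
        frames.append(frame)
        case_blocks.append(prev * persons)
        yld_blocks.append(prev * wd[None, :] * persons)
    return BurdenTable(
        frame=pd.concat(frames, ignore_index=True),
        cases=np.vstack(case_blocks),
        ylds=np.vstack(yld_blocks),
    )


def aggregate(burden: BurdenTable, hierarchy: Mapping[str, str], include_global: bool = True) -> BurdenTable:
    """Aggregate a location-level table to regions (and optionally global).

    Counts are summed at draw level before any summarisation.
    """
    unmapped = sorted(set(burden.frame["location"]) - set(hierarchy))
    if unmapped:
        raise ValueError(f"locations not in hierarchy: {unmapped}")
    frame = burden.frame.copy()
    frame["location"] = frame["location"].map(dict(hierarchy))
    regional = BurdenTable(frame=frame, cases=burden.cases, ylds=burden.ylds).totals(
        ["location", "year", "sex", "age_low", "state"]
    )
    if not include_global:
        return regional
    gframe = regional.frame.copy()
    gframe["location"] = "global"
    global_tbl = BurdenTable(frame=gframe, cases=regional.cases, ylds=regional.ylds).totals(
        ["location", "year", "sex", "age_low", "state"]
    )
    return BurdenTable(
        frame=pd.concat([regional.frame, global_tbl.frame], ignore_index=True),
        cases=np.vstack([regional.cases, global_tbl.cases]),
        ylds=np.vstack([regional.ylds, global_tbl.ylds]),
    )


def percent_change(a: np.ndarray | float, b: np.ndarray | float) -> tuple[float, float, float]:
    """Draw-level percentage change 100 (b - a) / a, summarised.

    Scalars are treated as constant draws; any non-positive baseline draw is
    an error.
    """
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    b_arr = np.atleast_1d(np.asarray(b, dtype=float))
    if a_arr.size == 1 and b_arr.size > 1:
        a_arr = np.full_like(b_arr, a_arr[0])
    if b_arr.size == 1 and a_arr.size > 1:
        b_arr = np.full_like(a_arr, b_arr[0])
    if np.any(a_arr <= 0):
        raise ValueError("percent change undefined: baseline draw <= 0")
    changes = 100.0 * (b_arr - a_arr) / a_arr
    return summarize_draws(changes)


def haq_regression(asr_ylds: pd.Series, haq: pd.Series) -> tuple[float, float, float]:
    """OLS of age-standardised YLD rates on the HAQ index across locations.

    Returns ``(slope, intercept, adjusted r^2)``.
    """
    joined = pd.concat([asr_ylds.rename("yld"), haq.rename("haq")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 locations for the HAQ regression")
    if joined["haq"].nunique() < 2:
        raise ValueError("HAQ index is constant across locations")
    X = sm.add_constant(joined["haq"].to_numpy())
    fit = sm.OLS(joined["yld"].to_numpy(), X).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared_adj)
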
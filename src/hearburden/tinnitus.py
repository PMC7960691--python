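"""Splitting severity prevalence into with- and without-tinnitus health states.

The proportion of people with hearing impairment who experience ringing,
roaring or buzzing is estimated from audiometry microdata as a binomial
proportion per (severity, age group, sex) stratum, with sparse strata pooled
first over sex and then over adjacent age groups.  The split applies the same
proportion across all causes; uncertainty in the proportion is propagated by
sampling it per draw from its normal approximation (seeded, truncated to
[0, 1]).  The two states add back to the input exactly, draw by draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .causes import CauseSurface
from .prevalence import CELL_KEYS, DrawSurface
from .severity import SEVERITY_ORDER, SeverityScheme

log = logging.getLogger(__name__)


@dataclass
class TinnitusProportions:
    """Binomial tinnitus proportions per (severity, age_low, sex)."""

    table: pd.DataFrame  # columns: severity, age_low, sex, numerator, denominator, proportion, se

    def lookup(self, severity: str, age_low: float, sex: str) -> tuple[float, float]:
        t = self.table
        row = t[(t["severity"] == severity) & (t["age_low"] == age_low) & (t["sex"] == sex)]
        if row.empty:
            raise KeyError(f"no tinnitus proportion for stratum ({severity}, {age_low}, {sex})")
        return float(row["proportion"].iloc[0]), float(row["se"].iloc[0])


def estimate_tinnitus(
    microdata: pd.DataFrame,
    scheme: SeverityScheme | None = None,
    age_band_width: int = 5,
    min_denominator: int = 25,
) -> TinnitusProportions:
    """Tinnitus proportions among the impaired, by severity, age group and sex.

    Records below 20 dB are excluded from denominators.  Strata whose
    denominator falls below ``min_denominator`` are pooled: first both sexes
    within the (severity, age) cell, then over adjacent age groups within the
    severity, finally the severity's overall proportion.
    """
    scheme = scheme or SeverityScheme.default()
    impaired = microdata[microdata["better_ear_pta"] >= 20.0].copy()
    if impaired.empty:
        raise ValueError("no impaired records; cannot estimate tinnitus proportions")
    edges = [lo for _, lo, _ in scheme.categories] + [np.inf]
    impaired["severity"] = pd.cut(
        impaired["better_ear_pta"], bins=edges, right=False, labels=scheme.names
    ).astype(str)
    impaired["age_low"] = (impaired["age"] // age_band_width).astype(int) * age_band_width

    counts = (
        impaired.groupby(["severity", "age_low", "sex"], observed=True)["tinnitus"]
        .agg(numerator="sum", denominator="count")
        .reset_index()
    )
    # complete the grid: unobserved strata get zero denominators and pool below
    full = pd.MultiIndex.from_product(
        [list(scheme.names[1:]), sorted(impaired["age_low"].unique()), sorted(impaired["sex"].unique())],
        names=["severity", "age_low", "sex"],
    )
    counts = (
        counts.set_index(["severity", "age_low", "sex"]).reindex(full, fill_value=0).reset_index()
    )
    sex_pooled = (
        impaired.groupby(["severity", "age_low"], observed=True)["tinnitus"]
        .agg(numerator="sum", denominator="count")
        .reset_index()
    )
    sev_pooled = (
        impaired.groupby(["severity"], observed=True)["tinnitus"]
        .agg(numerator="sum", denominator="count")
        .reset_index()
        .set_index("severity")
    )

    age_lows = sorted(impaired["age_low"].unique())
    rows = []
    for _, row in counts.iterrows():
        x, n = float(row["numerator"]), float(row["denominator"])
        sev, age, sex = row["severity"], row["age_low"], row["sex"]
        if n < min_denominator:
            pooled = sex_pooled[(sex_pooled["severity"] == sev) & (sex_pooled["age_low"] == age)]
            if not pooled.empty:
                x, n = float(pooled["numerator"].iloc[0]), float(pooled["denominator"].iloc[0])
        if n < min_denominator:
            # widen over adjacent age groups until the denominator suffices
            idx = age_lows.index(age)
            width = 1
            while n < min_denominator and width < len(age_lows):
                lo_i, hi_i = max(0, idx - width), min(len(age_lows), idx + width + 1)
                pooled = sex_pooled[
                    (sex_pooled["severity"] == sev)
                    & (sex_pooled["age_low"].isin(age_lows[lo_i:hi_i]))
                ]
                x, n = float(pooled["numerator"].sum()), float(pooled["denominator"].sum())
                width += 1
        if n < min_denominator and sev in sev_pooled.index and sev_pooled.loc[sev, "denominator"] > 0:
            x = float(sev_pooled.loc[sev, "numerator"])
            n = float(sev_pooled.loc[sev, "denominator"])
        if n <= 0:  # severity absent everywhere: overall impaired proportion
            x = float(impaired["tinnitus"].sum())
            n = float(len(impaired))
        p = x / n
        se = float(np.sqrt(max(p * (1 - p), 0.25 / n) / n))
        rows.append(
            {
                "severity": sev,
                "age_low": float(age),
                "sex": sex,
                "numerator": x,
                "denominator": n,
                "proportion": p,
                "se": se,
            }
        )
    return TinnitusProportions(table=pd.DataFrame(rows))


def _proportion_draws(
    proportions: TinnitusProportions,
    cells: pd.DataFrame,
    severity: str,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-cell, per-draw tinnitus proportion array for one severity."""
    t = np.empty((len(cells), n_draws))
    missing = []
    cache: dict[tuple, np.ndarray] = {}
    for i, (age, sex) in enumerate(zip(cells["age_low"], cells["sex"])):
        key = (severity, float(age), sex)
        if key not in cache:
            try:
                p, se = proportions.lookup(severity, float(age), sex)
            except KeyError:
                missing.append(key)
                cache[key] = np.zeros(n_draws)
                continue
            cache[key] = np.clip(rng.normal(p, se, size=n_draws), 0.0, 1.0)
        t[i] = cache[key]
    if missing:
        raise KeyError(f"tinnitus proportions missing for strata: {sorted(set(missing))}")
    return t


def split_by_tinnitus(
    surface: DrawSurface | CauseSurface,
    proportions: TinnitusProportions,
    seed: int = 0,
) -> dict:
    """Split a severity (or severity x cause) surface into health states.

    Returns a dict keyed ``(severity, ringing)`` for a :class:`DrawSurface`
    input, or ``(severity, cause, ringing)`` for a :class:`CauseSurface`.
    The same per-stratum proportion draw is used across causes, so the
    with-ringing share is cause-invariant by construction and the two states
    sum back to the input exactly.
    """
    rng = np.random.default_rng(seed)
    cells = surface.cells
    out: dict = {}
    if isinstance(surface, CauseSurface):
        for sev in surface.severities:
            t = _proportion_draws(proportions, cells, sev, surface.n_draws, rng)
            for (s, cause), arr in surface.values.items():
                if s != sev:
                    continue
                out[(sev, cause, True)] = arr * t
                out[(sev, cause, False)] = arr * (1.0 - t)
    else:
        for sev in surface.categories:
            if sev == "normal":
                continue
            t = _proportion_draws(proportions, cells, sev, surface.n_draws, rng)
            arr = surface.values[sev]
            out[(sev, True)] = arr * t
            out[(sev, False)] = arr * (1.0 - t)
    return out
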
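"""Report tables: regional prevalent cases and age-standardised rates by severity.

The severity table mirrors the usual burden-study layout: one block per
hearing-loss category (all loss >= 20 dB, the moderate-plus envelope, mild,
and the five individual severities), one row per region plus global, with
prevalent cases in millions (rounded to 0.1) and age-standardised prevalence.
Printed envelope totals are the sums of the printed severity rows -- the
moderate-plus entry is computed as the sum of the five rounded severity
entries, and all-loss as mild plus moderate-plus -- so the displayed table is
additive by construction.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .burden import StandardPopulation, age_standardize
from .prevalence import CELL_KEYS, DrawSurface
from .severity import CATEGORY_ORDER

MODERATE_PLUS = list(CATEGORY_ORDER[2:])


def severity_table(
    surface: DrawSurface,
    population: pd.DataFrame,
    hierarchy: Mapping[str, str],
    year: int,
    standard: StandardPopulation | None = None,
) -> pd.DataFrame:
    """Cases (millions, 1 d.p.) and age-standardised rates by region and category.

    Envelope rows (``moderate_plus``, ``all_loss``) are sums of the rounded
    severity rows, guaranteeing additivity of the printed numbers.
    """
    standard = standard or StandardPopulation.from_population(population, year)
    cells = surface.cells[CELL_KEYS].copy()
    cells["region"] = cells["location"].map(dict(hierarchy))
    mask = (cells["year"] == year).to_numpy()
    pop = cells.merge(population, on=CELL_KEYS, how="left")
    persons = pop["persons"].to_numpy(dtype=float)

    regions = sorted(set(hierarchy.values()))
    rows = []
    for region in regions + ["global"]:
        in_region = mask if region == "global" else (mask & (cells["region"] == region).to_numpy())
        region_pop = persons[in_region]
        rounded = {}
        for cat in CATEGORY_ORDER[1:]:
            prev_mean = surface.values[cat][in_region].mean(axis=1)
            cases_m = float(np.sum(prev_mean * region_pop)) / 1e6
            rounded[cat] = round(cases_m, 1)
            # age-standardised rate: population-weighted age-specific rates
            sub = cells[in_region].assign(prev=prev_mean, persons=region_pop)
            by_age = sub.groupby("age_low").apply(
                lambda g: np.average(g["prev"], weights=g["persons"]), include_groups=False
            )
            asr = age_standardize(by_age, standard=standard)
            rows.append(
                {
                    "region": region,
                    "category": cat,
                    "cases_millions": rounded[cat],
                    "asr_percent": round(100 * asr, 1),
                }
            )
        mod_plus = round(sum(rounded[c] for c in MODERATE_PLUS), 1)
        rows.append(
            {"region": region, "category": "moderate_plus", "cases_millions": mod_plus, "asr_percent": np.nan}
        )
        rows.append(
            {
                "region": region,
                "category": "all_loss",
                "cases_millions": round(mod_plus + rounded["mild"], 1),
                "asr_percent": np.nan,
            }
        )
    return pd.DataFrame(rows)
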
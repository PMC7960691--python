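"""Parameter-recovery harness: does the pipeline recover its own truth?

The harness builds a single-location world, simulates large audiometry
surveys from the generative truth, pushes them through the estimation stages,
and asks whether the resulting 95% uncertainty intervals cover the generative
values.  Covered quantities: severity-specific prevalence (after both
squeezes), hearing-aid coverage, tinnitus proportions, and the under-5
otitis-media cause share.  A well-calibrated pipeline should cover the truth
in roughly 95% of strata; the checks ask for at least 90% pooled over
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causes import attribute_causes
from .hearing_aid import fit_coverage
from .prevalence import (
    CELL_KEYS,
    DrawSurface,
    ModelConfig,
    default_grid,
    fit_category_model,
    rename_category,
    squeeze_severities,
    squeeze_top_level,
)
from .severity import CATEGORY_ORDER, SEVERITY_ORDER, SeverityScheme
from .synthetic import (
    CAUSES,
    WorldConfig,
    make_truth,
    simulate_microdata,
    tabulate_causes,
    tabulate_coverage,
    tabulate_survey,
)
from .burden import summarize_draws
from .tinnitus import estimate_tinnitus

RECOVERY_WORLD = WorldConfig(n_regions=1, locations_per_region=1, years=(2019,))


@dataclass
class RecoveryCounts:
    """Covered / total stratum counts per recovered quantity."""

    covered: dict = field(default_factory=lambda: {k: 0 for k in ("severity_prevalence", "coverage", "tinnitus", "otitis_share")})
    total: dict = field(default_factory=lambda: {k: 0 for k in ("severity_prevalence", "coverage", "tinnitus", "otitis_share")})

    def add(self, quantity: str, hits: int, n: int) -> None:
        self.covered[quantity] += hits
        self.total[quantity] += n

    def fractions(self) -> dict[str, float]:
        return {k: self.covered[k] / self.total[k] for k in self.total if self.total[k] > 0}

    def update(self, other: "RecoveryCounts") -> None:
        for k in self.total:
            self.covered[k] += other.covered[k]
            self.total[k] += other.total[k]


def _interval(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise (lower, upper) of draw arrays under the ordered-draw rule."""
    stats = np.array([summarize_draws(row) for row in arr])
    return stats[:, 1], stats[:, 2]


def recovery_replicate(
    seed: int,
    n_per_stratum: int = 50_000,
    draws: int = 1000,
    world: WorldConfig = RECOVERY_WORLD,
) -> RecoveryCounts:
    """One replicate: simulate, estimate, and score interval coverage."""
    scheme = SeverityScheme.default()
    truth = make_truth(world, seed)
    records = simulate_microdata(truth, n_per_stratum, seed + 1)
    covs = truth.covariates
    grid = default_grid(covs, world.sexes, world.age_lows)
    counts = RecoveryCounts()

    def fit(rng_db: tuple[float, float], name: str, offset: int, sign: int) -> DrawSurface:
        rows = tabulate_survey(records, scheme, severity_ranges=[rng_db])
        mc = ModelConfig(
            covariate_sign=sign, draws=draws, seed=seed + 100 + offset, age_lows=tuple(world.age_lows)
        )
        return rename_category(fit_category_model(rows, mc, covs, grid), name)

    normal = fit((0.0, 20.0), "normal", 0, +1)
    mild = fit((20.0, 35.0), "mild", 1, -1)
    mod_plus = fit((35.0, np.inf), "moderate_plus", 2, -1)
    normal, mild, mod_plus = squeeze_top_level(normal, mild, mod_plus)
    five = {
        s: fit(scheme.range_of(s), s, 3 + i, -1) for i, s in enumerate(SEVERITY_ORDER[1:])
    }
    five = squeeze_severities(five, mod_plus)

    truth_prev = truth.prevalence.reset_index()
    cell_index = pd.MultiIndex.from_frame(grid[CELL_KEYS])
    truth_aligned = truth_prev.set_index(CELL_KEYS).reindex(cell_index)
    for sev, surf in five.items():
        lo, hi = _interval(surf.values[sev])
        t = truth_aligned[sev].to_numpy()
        counts.add("severity_prevalence", int(((lo <= t) & (t <= hi)).sum()), len(t))

    cov_surface = fit_coverage(
        tabulate_coverage(records, scheme),
        ModelConfig(spline_df=3, draws=draws, seed=seed + 200, age_lows=tuple(world.age_lows)),
        grid,
    )
    for sev in SEVERITY_ORDER:
        lo, hi = _interval(cov_surface.values[sev])
        t = float(truth.coverage[sev])
        counts.add("coverage", int(((lo <= t) & (t <= hi)).sum()), len(lo))

    props = estimate_tinnitus(records, scheme).table
    t_truth = props["severity"].map(truth.tinnitus).to_numpy(dtype=float)
    lo = props["proportion"] - 1.959963984540054 * props["se"]
    hi = props["proportion"] + 1.959963984540054 * props["se"]
    hits = int(((lo.to_numpy() <= t_truth) & (t_truth <= hi.to_numpy())).sum())
    counts.add("tinnitus", hits, len(props))

    # under-5 otitis share via the attribution route
    loss = DrawSurface(
        cells=grid[CELL_KEYS].copy(),
        values={"mild": mild.values["mild"], **{s: five[s].values[s] for s in five}},
    )
    from .pipeline import _cause_models_from_obs

    rng = np.random.default_rng(seed + 300)
    cause_models = _cause_models_from_obs(tabulate_causes(records, scheme), loss, draws, rng)
    cause_surface = attribute_causes(loss, cause_models)
    share = cause_surface.cause_share("otitis_media")
    under5 = (grid["age_low"] == 0).to_numpy()
    lo, hi = _interval(share[under5])
    t = float(truth.cause_fractions.loc[0, "otitis_media"])
    counts.add("otitis_share", int(((lo <= t) & (t <= hi)).sum()), int(under5.sum()))
    return counts


def run_recovery(
    n_replicates: int = 10,
    seed: int = 0,
    n_per_stratum: int = 50_000,
    draws: int = 1000,
) -> RecoveryCounts:
    """Pool interval-coverage counts over seeded replicates."""
    totals = RecoveryCounts()
    for r in range(n_replicates):
        totals.update(recovery_replicate(seed + 1000 * r, n_per_stratum=n_per_stratum, draws=draws))
    return totals
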
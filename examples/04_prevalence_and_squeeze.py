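"""Nested prevalence models and the two sum-to-one squeezes.

Fits the three top-level models (no loss, mild, moderate-plus), rescales them
to sum to one, fits the five severity models, rescales them to the
moderate-plus envelope, and prints a stratum's severity composition with 95%
uncertainty intervals from 500 draws.
"""

import numpy as np

from hearburden import (
    ModelConfig,
    SEVERITY_ORDER,
    WorldConfig,
    make_truth,
    simulate_microdata,
    squeeze_severities,
    squeeze_top_level,
    summarize_draws,
    tabulate_survey,
)
from hearburden.prevalence import default_grid, fit_category_model, rename_category
from hearburden.severity import SeverityScheme

scheme = SeverityScheme.default()
world = WorldConfig(n_regions=1, locations_per_region=1, years=(2019,))
truth = make_truth(world, seed=5)
records = simulate_microdata(truth, n_per_stratum=20_000, seed=6)
grid = default_grid(truth.covariates, world.sexes, world.age_lows)


def fit(db_range, name, seed, sign=-1):
    rows = tabulate_survey(records, scheme, severity_ranges=[db_range])
    config = ModelConfig(draws=500, seed=seed, covariate_sign=sign)
    return rename_category(fit_category_model(rows, config, truth.covariates, grid), name)


normal = fit((0.0, 20.0), "normal", 10, sign=+1)
mild = fit((20.0, 35.0), "mild", 11)
mod_plus = fit((35.0, np.inf), "moderate_plus", 12)
normal, mild, mod_plus = squeeze_top_level(normal, mild, mod_plus)
five = {s: fit(scheme.range_of(s), s, 13 + i) for i, s in enumerate(SEVERITY_ORDER[1:])}
five = squeeze_severities(five, mod_plus)

row = (grid["sex"] == "female") & (grid["age_low"] == 70)
idx = np.flatnonzero(row.to_numpy())[0]
print("female, ages 70-74: estimated prevalence (mean [95% UI]) vs truth")
for sev in SEVERITY_ORDER[1:]:
    mean, lo, hi = summarize_draws(five[sev].values[sev][idx])
    t = truth.prevalence.loc[(truth.locations[0], 2019, "female", 70), sev]
    print(f"  {sev:18s} {mean:.4f} [{lo:.4f}, {hi:.4f}]   truth {t:.4f}")

total = normal.values["normal"] + mild.values["mild"] + mod_plus.values["moderate_plus"]
print(f"\nmax |normal + mild + moderate_plus - 1| = {np.abs(total - 1).max():.2e}")

# After both squeezes the categories account for the whole population exactly,
# and the severity intervals bracket the generative truth.
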
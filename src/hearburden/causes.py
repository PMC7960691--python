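"""Attribution of severity-specific hearing loss to underlying causes.

Four causes are carried: congenital birth defects, (chronic) otitis media,
meningitis, and age-related/other.  Below an age cutoff (default 20 years)
the four cause-specific prevalences are proportionally rescaled so they sum
to the total prevalence of each severity.  At and above the cutoff the three
named causes are kept as modelled and the residual -- total minus named -- is
assigned to age-related/other.  A negative residual (named causes exceeding
the total) is resolved by proportionally rescaling the named causes to the
total and setting the residual to zero; affected cell-draws are counted and
logged.  Additivity over causes is therefore exact by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .prevalence import CELL_KEYS, DrawSurface, check_aligned
from .synthetic import CAUSES

log = logging.getLogger(__name__)

NAMED_CAUSES: tuple[str, ...] = ("congenital", "otitis_media", "meningitis")
RESIDUAL_CAUSE = "age_other"


@dataclass
class CauseSurface:
    """Draw-level cause-specific prevalence: (severity, cause) -> (cells, D)."""

    cells: pd.DataFrame
    values: dict[tuple[str, str], np.ndarray]
    negative_residual_count: int = 0

    @property
    def severities(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(sev for sev, _ in self.values))

    @property
    def n_draws(self) -> int:
        return next(iter(self.values.values())).shape[1]

    def total_for(self, severity: str) -> np.ndarray:
        return np.sum([arr for (sev, _), arr in self.values.items() if sev == severity], axis=0)

    def cause_share(self, cause: str) -> np.ndarray:
        """Share of all-severity loss attributable to one cause, per cell/draw."""
        num = np.sum([arr for (_, c), arr in self.values.items() if c == cause], axis=0)
        den = np.sum(list(self.values.values()), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def attribute_causes(
    severity_prev: DrawSurface,
    cause_models: Mapping[str, DrawSurface],
    age_cutoff: float = 20.0,
) -> CauseSurface:
    """Split severity prevalence into causes.

    Parameters
    ----------
    severity_prev
        Surface whose categories are the severities to attribute (typically
        the five moderate-plus severities plus mild).
    cause_models
        Unscaled cause-specific surfaces, one per cause in
        ``("congenital", "otitis_media", "meningitis", "age_other")``, each
        holding the same severity categories as ``severity_prev``.
    """
    missing = [c for c in CAUSES if c not in cause_models]
    if missing:
        raise ValueError(f"cause models missing for: {missing}")
    check_aligned(severity_prev, *cause_models.values())
    ages = severity_prev.cells["age_low"].to_numpy(dtype=float)
    young = (ages < age_cutoff)[:, None]  # broadcast over draws

    values: dict[tuple[str, str], np.ndarray] = {}
    n_negative = 0
    for sev in severity_prev.categories:
        total = severity_prev.values[sev]
        model = {c: cause_models[c].values[sev] for c in CAUSES}
        for c in CAUSES:
            if np.any(model[c] < 0):
                raise ValueError(f"negative cause model values for ({sev}, {c})")

        # under the cutoff: proportional squeeze of all four causes
        all_sum = np.sum([model[c] for c in CAUSES], axis=0)
        bad = young & (all_sum <= 0) & (total > 0)
        if bad.any():
            raise ValueError(
                f"severity {sev!r}: all-cause model sum is zero below the age cutoff where total > 0"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            scale_young = np.where(all_sum > 0, total / np.where(all_sum > 0, all_sum, 1.0), 0.0)

        # at/above the cutoff: named causes kept, residual to age-related/other
        named_sum = np.sum([model[c] for c in NAMED_CAUSES], axis=0)
        residual = total - named_sum
        negative = ~young & (residual < 0)
        n_negative += int(negative.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            named_scale = np.where(
                negative & (named_sum > 0), total / np.where(named_sum > 0, named_sum, 1.0), 1.0
            )
        for c in NAMED_CAUSES:
            old = np.where(young, model[c] * scale_young, model[c] * named_scale)
            values[(sev, c)] = old
        values[(sev, RESIDUAL_CAUSE)] = np.where(
            young, model[RESIDUAL_CAUSE] * scale_young, np.clip(residual, 0.0, None)
        )
    if n_negative:
        log.warning("cause attribution: %d cell-draws had named causes exceeding the total", n_negative)
    return CauseSurface(
        cells=severity_prev.cells.copy(), values=values, negative_residual_count=n_negative
    )
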
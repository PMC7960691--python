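"""Hearing-aid coverage modelling and the one-category severity shift.

Coverage is the proportion of people at a given severity who use a hearing
aid.  The adjustment reclassifies that proportion one severity category lower
(aided mild counts as no loss), producing "adjusted" prevalence alongside the
"unadjusted" surface.  All outflows are computed from the unadjusted values
simultaneously -- the shift is a single reclassification, not an iterative
cascade -- so the all-category sum is conserved exactly and the adjusted
moderate-plus prevalence can only fall.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .harmonize import _continuity
from .prevalence import CELL_KEYS, DrawSurface, ModelConfig, _spline_basis, _wls, check_aligned
from .severity import CATEGORY_ORDER, SEVERITY_ORDER

log = logging.getLogger(__name__)


def fit_coverage(
    data: pd.DataFrame,
    config: ModelConfig,
    grid: pd.DataFrame | None = None,
) -> DrawSurface:
    """Fit severity-specific hearing-aid coverage surfaces with draws.

    ``data`` has columns ``location, year, sex, age_low, severity, users,
    total``.  Each severity is fitted as a logit-scale spline over age pooled
    across locations and years (coverage data are typically too sparse for
    geographic structure).  Severities with no data borrow the fit of the
    next lower severity (severity-gradient prior), and after fitting, draws
    are made non-decreasing in severity by a running maximum in severity
    order.  Coverage of the ``normal`` category is identically zero.
    """
    if data.empty or data["total"].sum() <= 0:
        raise ValueError("no usable coverage observations (all-zero sample sizes)")
    if grid is None:
        grid = data[CELL_KEYS].drop_duplicates().sort_values(CELL_KEYS).reset_index(drop=True)
    grid = grid.sort_values(CELL_KEYS).reset_index(drop=True)
    rng = np.random.default_rng(config.seed)
    age_range = (float(min(config.age_lows)), float(max(config.age_lows) + 5.0))
    age_g = grid["age_low"].to_numpy(dtype=float) + 2.5

    values: dict[str, np.ndarray] = {"normal": np.zeros((len(grid), config.draws))}
    prev_draws: np.ndarray | None = None
    for sev in SEVERITY_ORDER:
        sub = data[(data["severity"] == sev) & (data["total"] > 0)]
        if sub.empty:
            if prev_draws is None:
                raise ValueError(f"no coverage data for severity {sev!r} and no lower severity to borrow from")
            log.warning("no coverage data for %s; borrowing next-lower severity", sev)
            values[sev] = prev_draws.copy()
            continue
        n = sub["total"].to_numpy(dtype=float)
        p = np.array([_continuity(u / t, t) for u, t in zip(sub["users"], n)])
        y = logit(p)
        w = n * p * (1 - p)
        df = min(config.spline_df, 3, max(1, len(sub) - 1))
        X = _spline_basis(sub["age_low"].to_numpy(dtype=float) + 2.5, df, age_range)
        beta, cov_beta = _wls(X, y, w)
        resid = y - X @ beta
        q = float(np.sum(w * resid**2))
        tau2 = max(0.0, (q - max(len(sub) - X.shape[1], 1)) / float(np.sum(w)))
        Xg = _spline_basis(age_g, df, age_range)
        beta_d = rng.multivariate_normal(beta, cov_beta, size=config.draws, method="svd")
        lin = Xg @ beta_d.T
        if tau2 > 0:
            lin += rng.normal(0.0, np.sqrt(tau2), size=lin.shape)
        draws = expit(lin)
        if prev_draws is not None:
            draws = np.maximum(draws, prev_draws)  # severity-gradient prior
        values[sev] = draws
        prev_draws = draws
    return DrawSurface(cells=grid[CELL_KEYS].copy(), values=values)


def apply_aid_shift(prevalence: DrawSurface, coverage: DrawSurface) -> DrawSurface:
    """Shift the aided proportion of each severity one category lower.

    ``prevalence`` must hold all seven categories, be normalised (sum to one
    per cell/draw) and not yet adjusted.  Returns a new surface flagged
    ``aid_adjusted``; the input is untouched.
    """
    if prevalence.aid_adjusted:
        raise ValueError("surface is already hearing-aid adjusted; the shift must be applied exactly once")
    missing = [c for c in CATEGORY_ORDER if c not in prevalence.values]
    if missing:
        raise ValueError(f"prevalence surface missing categories: {missing}")
    check_aligned(prevalence, coverage)
    out: dict[str, np.ndarray] = {}
    outflow: dict[str, np.ndarray] = {}
    for sev in SEVERITY_ORDER:
        cov = coverage.values.get(sev)
        if cov is None:
            raise ValueError(f"coverage surface missing severity {sev!r}")
        if np.any((cov < 0) | (cov > 1)):
            raise ValueError(f"coverage outside [0, 1] for severity {sev!r}")
        outflow[sev] = prevalence.values[sev] * cov
    for i, cat in enumerate(CATEGORY_ORDER):
        arr = prevalence.values[cat].copy()
        if cat != "normal":
            arr -= outflow[cat]
        if i + 1 < len(CATEGORY_ORDER):
            arr += outflow[CATEGORY_ORDER[i + 1]]
        out[cat] = arr
    return DrawSurface(cells=prevalence.cells.copy(), values=out, aid_adjusted=True)
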
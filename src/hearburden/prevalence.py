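"""Smooth prevalence surfaces by severity category, with sum-to-one squeezes.

The estimation strategy is nested.  Three models first estimate no loss
(0-19 dB), mild loss (20-34 dB) and the moderate-to-complete envelope
(>= 35 dB); their results are rescaled to sum to one in every
(location, year, sex, age) stratum.  Five further models estimate the
individual severities from moderate upward and are rescaled so their sum
equals the envelope.  Uncertainty is carried as D draws per cell throughout
(default 1000), so every later arithmetic step propagates it exactly.

The per-category estimator here is a documented surrogate for a full Bayesian
compartmental meta-regression: a logit-scale penalty-free B-spline regression
over age with an SDI-like covariate (sign-constrained), location random
intercepts, a DerSimonian-Laird-style residual heterogeneity term, and
parametric draws from the asymptotic coefficient distribution.  Only its
inputs and outputs matter to the rest of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit, logit

from .harmonize import PrevalenceDatum, _continuity, data_to_frame

log = logging.getLogger(__name__)

CELL_KEYS = ["location", "year", "sex", "age_low"]


@dataclass
class ModelConfig:
    """Configuration of one surrogate category model.

    ``spline_df`` counts B-spline basis functions over age (including the
    intercept-like column); ``draws`` is the number of posterior-style samples
    per cell; ``covariate_sign`` constrains the SDI-like coefficient (-1: loss
    never increases with development; +1 for the no-loss category; 0: free).
    """

    spline_df: int = 10
    covariates: tuple[str, ...] = ("sdi",)
    covariate_sign: int = -1
    draws: int = 1000
    seed: int = 0
    age_lows: tuple[int, ...] = tuple(range(0, 100, 5))

    def __post_init__(self) -> None:
        if self.draws < 2:
            raise ValueError("draws must be >= 2")
        if self.spline_df < 1:
            raise ValueError("spline_df must be >= 1")


@dataclass
class DrawSurface:
    """Draw-level prevalence on a complete (location, year, sex, age) grid.

    ``cells`` has one row per stratum (columns ``location, year, sex,
    age_low``); ``values`` maps category name to an array of shape
    ``(n_cells, n_draws)``.  ``aid_adjusted`` records whether the hearing-aid
    shift has been applied, so it cannot be applied twice.
    """

    cells: pd.DataFrame
    values: dict[str, np.ndarray]
    aid_adjusted: bool = False

    def __post_init__(self) -> None:
        n = len(self.cells)
        for cat, arr in self.values.items():
            if arr.shape[0] != n:
                raise ValueError(f"category {cat!r}: {arr.shape[0]} rows for {n} cells")
        draws = {arr.shape[1] for arr in self.values.values()}
        if len(draws) > 1:
            raise ValueError("inconsistent draw counts across categories")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.values)

    @property
    def n_draws(self) -> int:
        return next(iter(self.values.values())).shape[1]

    def copy(self) -> "DrawSurface":
        return DrawSurface(
            cells=self.cells.copy(),
            values={k: v.copy() for k, v in self.values.items()},
            aid_adjusted=self.aid_adjusted,
        )

    def mean(self, category: str) -> pd.Series:
        return pd.Series(self.values[category].mean(axis=1), index=pd.MultiIndex.from_frame(self.cells[CELL_KEYS]))

    def summarize(self) -> pd.DataFrame:
        """Long summary frame: one row per cell x category with mean/lower/upper."""
        from .burden import summarize_draws

        rows = []
        for cat, arr in self.values.items():
            summ = np.apply_along_axis(lambda d: summarize_draws(d), 1, arr)
            frame = self.cells[CELL_KEYS].copy()
            frame["category"] = cat
            frame[["mean", "lower", "upper"]] = summ
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    def total(self) -> np.ndarray:
        """Sum over categories, shape (n_cells, n_draws)."""
        return np.sum([arr for arr in self.values.values()], axis=0)


def check_aligned(*surfaces: DrawSurface) -> None:
    first = surfaces[0]
    for s in surfaces[1:]:
        if len(s.cells) != len(first.cells) or not s.cells[CELL_KEYS].reset_index(drop=True).equals(
            first.cells[CELL_KEYS].reset_index(drop=True)
        ):
            raise ValueError("surfaces are not on identical cell grids")
        if s.n_draws != first.n_draws:
            raise ValueError("surfaces have different draw counts")


def combine(surfaces: Mapping[str, DrawSurface]) -> DrawSurface:
    """Merge single-category surfaces into one multi-category surface."""
    items = list(surfaces.items())
    check_aligned(*[s for _, s in items])
    values: dict[str, np.ndarray] = {}
    for name, surf in items:
        if len(surf.values) != 1:
            raise ValueError("combine expects single-category surfaces")
        values[name] = next(iter(surf.values.values()))
    return DrawSurface(cells=items[0][1].cells.copy(), values=values)


def _spline_basis(x: np.ndarray, df: int, x_range: tuple[float, float]) -> np.ndarray:
    """B-spline design matrix with ``df`` columns over ``x_range`` (degree 3)."""
    degree = 3 if df >= 4 else max(df - 1, 0)
    n_inner = df - degree - 1
    lo, hi = x_range
    inner = np.quantile(np.linspace(lo, hi, 101), np.linspace(0, 1, n_inner + 2)[1:-1]) if n_inner > 0 else []
    knots = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    basis = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
    return basis


def default_grid(
    covariates: pd.DataFrame, sexes: Sequence[str], age_lows: Sequence[int]
) -> pd.DataFrame:
    """Full (location, year, sex, age_low) grid from a covariate table."""
    base = covariates[["location", "year"]].drop_duplicates()
    sex_f = pd.DataFrame({"sex": list(sexes)})
    age_f = pd.DataFrame({"age_low": list(age_lows)})
    grid = base.merge(sex_f, how="cross").merge(age_f, how="cross")
    return grid.sort_values(CELL_KEYS).reset_index(drop=True)


def fit_category_model(
    data: Sequence[PrevalenceDatum] | pd.DataFrame,
    config: ModelConfig,
    covariates: pd.DataFrame,
    grid: pd.DataFrame | None = None,
) -> DrawSurface:
    """Fit one category's prevalence surface and sample draws.

    Parameters
    ----------
    data
        Processed reference-definition rows for a single category (sex in
        {female, male}, 5-year age bands).
    covariates
        Frame with columns ``location, year, sdi`` (and optionally others
        named in ``config.covariates``).
    grid
        Cells to predict on; defaults to every (location, year) in
        ``covariates`` crossed with the sexes present in ``data`` and
        ``config.age_lows``.

    Returns a single-category :class:`DrawSurface` keyed ``"value"``; rename
    via :func:`rename_category` or use directly.
    """
    frame = data if isinstance(data, pd.DataFrame) else data_to_frame(list(data))
    if frame.empty:
        raise ValueError("no data supplied")
    sexes = sorted(frame["sex"].unique())
    for sex in sexes:
        if sex not in ("female", "male"):
            raise ValueError(f"unsplit sex {sex!r} in model input; run harmonisation first")
    if grid is None:
        grid = default_grid(covariates, sexes, config.age_lows)
    grid = grid.sort_values(CELL_KEYS).reset_index(drop=True)
    rng = np.random.default_rng(config.seed)

    cov_cols = [c for c in config.covariates if c in covariates.columns]
    frame = frame.merge(covariates[["location", "year", *cov_cols]], on=["location", "year"], how="left")
    grid_m = grid.merge(covariates[["location", "year", *cov_cols]], on=["location", "year"], how="left")
    if grid_m[cov_cols].isna().any().any() if cov_cols else False:
        raise ValueError("covariates missing for some grid cells")

    age_range = (float(min(config.age_lows)), float(max(config.age_lows) + 5.0))
    draws_out = np.empty((len(grid), config.draws))

    for sex in grid["sex"].unique():
        sub = frame[frame["sex"] == sex]
        if sub.empty:
            raise ValueError(f"no data for sex {sex!r}")
        age_mid = (sub["age_low"].to_numpy() + sub["age_high"].to_numpy()) / 2.0
        n = sub["effective_sample_size"].to_numpy(dtype=float)
        p = np.array([_continuity(pi, ni) for pi, ni in zip(sub["prevalence"].to_numpy(), n)])
        y = logit(p)
        w = n * p * (1 - p)  # inverse delta-method variance of logit(p)

        basis = _spline_basis(age_mid, config.spline_df, age_range)
        use_cov = [c for c in cov_cols if sub[c].nunique() > 1]
        X = np.column_stack([basis] + [sub[c].to_numpy(dtype=float) for c in use_cov])

        beta, cov_beta = _wls(X, y, w)
        if use_cov and config.covariate_sign != 0:
            k = basis.shape[1]
            if np.sign(beta[k]) not in (0, config.covariate_sign):
                # sign-constrained covariate: project out and refit spline only
                use_cov = []
                X = basis
                beta, cov_beta = _wls(X, y, w)
        if not np.all(np.isfinite(beta)):
            raise RuntimeError(f"category model failed to converge for sex {sex!r}: non-finite coefficients")

        resid = y - X @ beta
        b_loc, var_loc, tau2 = _location_effects(sub["location"].to_numpy(), resid, w, X.shape[1])

        gsub_mask = (grid["sex"] == sex).to_numpy()
        gsub = grid_m[gsub_mask]
        gb = _spline_basis(gsub["age_low"].to_numpy(dtype=float) + 2.5, config.spline_df, age_range)
        Xg = np.column_stack([gb] + [gsub[c].to_numpy(dtype=float) for c in use_cov])

        beta_d = rng.multivariate_normal(beta, cov_beta, size=config.draws, method="svd")  # (D, k)
        lin = Xg @ beta_d.T  # (cells, D)
        locs = gsub["location"].to_numpy()
        for loc in np.unique(locs):
            mean_b = b_loc.get(loc, 0.0)
            sd_b = np.sqrt(var_loc.get(loc, 0.0))
            lin[locs == loc] += rng.normal(mean_b, sd_b, size=config.draws)[None, :]
        if tau2 > 0:
            lin += rng.normal(0.0, np.sqrt(tau2), size=lin.shape)
        draws_out[gsub_mask] = expit(lin)

    return DrawSurface(cells=grid[CELL_KEYS].copy(), values={"value": draws_out})


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(xtwx)
    return beta, cov


def _location_effects(
    locations: np.ndarray, resid: np.ndarray, w: np.ndarray, k_params: int
) -> tuple[dict, dict, float]:
    """Shrunk location random intercepts plus residual heterogeneity tau^2."""
    means, ses = {}, {}
    for loc in np.unique(locations):
        m = locations == loc
        means[loc] = float(np.sum(w[m] * resid[m]) / np.sum(w[m]))
        ses[loc] = float(1.0 / np.sqrt(np.sum(w[m])))
    if len(means) > 1:
        vals = np.array(list(means.values()))
        errs = np.array([ses[l] ** 2 for l in means])
        var_between = max(0.0, float(np.var(vals, ddof=1) - errs.mean()))
    else:
        var_between = 0.0
    b_loc, var_loc = {}, {}
    for loc in means:
        if var_between > 0:
            shrink = var_between / (var_between + ses[loc] ** 2)
            b_loc[loc] = shrink * means[loc]
            var_loc[loc] = 1.0 / (1.0 / var_between + 1.0 / ses[loc] ** 2)
        else:
            b_loc[loc] = 0.0
            var_loc[loc] = 0.0
    adj = resid - np.array([b_loc[l] for l in locations])
    q = float(np.sum(w * adj**2))
    dof = max(len(resid) - k_params - (len(means) - 1), 1)
    tau2 = max(0.0, (q - dof) / float(np.sum(w)))
    return b_loc, var_loc, tau2


def rename_category(surface: DrawSurface, name: str) -> DrawSurface:
    if len(surface.values) != 1:
        raise ValueError("rename_category expects a single-category surface")
    return DrawSurface(
        cells=surface.cells, values={name: next(iter(surface.values.values()))}, aid_adjusted=surface.aid_adjusted
    )


def squeeze_top_level(
    normal: DrawSurface, mild: DrawSurface, mod_plus: DrawSurface
) -> tuple[DrawSurface, DrawSurface, DrawSurface]:
    """Rescale the three top-level surfaces so they sum to one per cell/draw."""
    check_aligned(normal, mild, mod_plus)
    arrs = [next(iter(s.values.values())) for s in (normal, mild, mod_plus)]
    total = arrs[0] + arrs[1] + arrs[2]
    if np.any(total <= 0):
        raise ValueError("degenerate model: three-way prevalence sum is zero in some cell/draw")
    out = []
    for s, arr in zip((normal, mild, mod_plus), arrs):
        name = next(iter(s.values))
        out.append(DrawSurface(cells=s.cells.copy(), values={name: arr / total}))
    return tuple(out)


def squeeze_severities(
    five_surfaces: Mapping[str, DrawSurface], envelope: DrawSurface
) -> dict[str, DrawSurface]:
    """Rescale the five severity surfaces to the moderate-plus envelope.

    Where all five sub-models are zero but the envelope is positive, the
    envelope is distributed by the five models' global mean shares (logged).
    """
    surfaces = dict(five_surfaces)
    check_aligned(*surfaces.values(), envelope)
    env = next(iter(envelope.values.values()))
    arrs = {k: next(iter(s.values.values())) for k, s in surfaces.items()}
    stack = np.stack(list(arrs.values()))  # (5, cells, D)
    total = stack.sum(axis=0)
    degenerate = (total <= 0) & (env > 0)
    if degenerate.any():
        log.warning(
            "severity squeeze: %d cell-draws with zero sub-model mass; using global mean shares",
            int(degenerate.sum()),
        )
        global_shares = stack.mean(axis=(1, 2))
        global_shares = global_shares / global_shares.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, env / np.where(total > 0, total, 1.0), 0.0)
    out = {}
    for i, (name, arr) in enumerate(arrs.items()):
        scaled = arr * scale
        if degenerate.any():
            scaled = np.where(degenerate, env * global_shares[i], scaled)
        out[name] = DrawSurface(cells=envelope.cells.copy(), values={name: scaled})
    return out
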
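"""End-to-end orchestration of the burden pipeline on synthetic or file inputs.

Stage order: simulate -> process -> estimate -> adjust -> causes -> tinnitus
-> burden -> forecast.  Every stage's randomness derives from the run seed
with a fixed per-stage offset, so an identical configuration reproduces
byte-identical outputs.  Stage outputs are treated as immutable inputs to
later stages; the run manifest records seeds, row counts and (when an output
directory is configured) file checksums.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .burden import (
    BurdenTable,
    StandardPopulation,
    age_standardize,
    aggregate,
    compute_ylds,
    haq_regression,
    percent_change,
)
from .causes import CauseSurface, attribute_causes
from .forecast import ForecastModel, fit_forecast, project
from .harmonize import (
    CrosswalkModel,
    PrevalenceDatum,
    SexRatioModel,
    fit_crosswalk,
    fit_sex_ratio,
    process_all,
)
from .hearing_aid import apply_aid_shift, fit_coverage
from .prevalence import (
    CELL_KEYS,
    DrawSurface,
    ModelConfig,
    combine,
    default_grid,
    fit_category_model,
    rename_category,
    squeeze_severities,
    squeeze_top_level,
)
from .report import severity_table
from .severity import CATEGORY_ORDER, SEVERITY_ORDER, DisabilityWeightTable, SeverityScheme
from .synthetic import (
    CAUSES,
    EpidemicTruth,
    WorldConfig,
    make_population,
    make_truth,
    simulate_microdata,
    tabulate_causes,
    tabulate_coverage,
    tabulate_survey,
)
from .tinnitus import TinnitusProportions, estimate_tinnitus, split_by_tinnitus

log = logging.getLogger(__name__)

STAGES = ("simulate", "process", "estimate", "adjust", "causes", "tinnitus", "burden", "forecast")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    seed: int = 0
    draws: int = 1000
    n_per_stratum: int = 500
    trim: float = 0.1
    age_cutoff: float = 20.0
    spline_df: int = 10
    forecast_years: tuple[int, ...] = (2030, 2040, 2050)
    forecast_resamples: int = 200
    apply_aid_adjustment: bool = True
    dw_uncertainty: bool = True
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        world = WorldConfig(**raw.pop("world", {}))
        return cls(world=world, **raw)


@dataclass
class PipelineResult:
    """Everything a run produced, stage by stage."""

    config: RunConfig
    truth: EpidemicTruth | None = None
    population: pd.DataFrame | None = None
    records: pd.DataFrame | None = None
    survey: dict | None = None  # category name -> list[PrevalenceDatum]
    sex_model: SexRatioModel | None = None
    crosswalk: CrosswalkModel | None = None
    unadjusted: DrawSurface | None = None
    coverage: DrawSurface | None = None
    adjusted: DrawSurface | None = None
    cause_surface: CauseSurface | None = None
    tinnitus_props: TinnitusProportions | None = None
    states: dict | None = None
    burden_local: BurdenTable | None = None
    burden_regional: BurdenTable | None = None
    report: pd.DataFrame | None = None
    haq_fit: tuple | None = None
    forecast_model: ForecastModel | None = None
    forecast_cases: BurdenTable | None = None
    manifest: dict = field(default_factory=dict)


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (config.seed * 101 + STAGES.index(stage) * 1009) % (2**31 - 1)


def run_pipeline(config: RunConfig | None = None, through: str = "forecast") -> PipelineResult:
    """Execute the pipeline through the named stage (inclusive)."""
    config = config or RunConfig()
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; stages are {STAGES}")
    last = STAGES.index(through)
    res = PipelineResult(config=config)
    manifest: dict = {"stages": {}, "seed": config.seed}
    res.manifest = manifest
    out_dir = Path(config.output_dir) if config.output_dir else None
    scheme = SeverityScheme.default()

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = {"seed": _stage_seed(config, stage), **info}

    # ---- simulate -------------------------------------------------------
    seed = _stage_seed(config, "simulate")
    res.truth = make_truth(config.world, seed)
    res.population = make_population(res.truth, seed + 1)
    res.records = simulate_microdata(res.truth, config.n_per_stratum, seed + 2)

    # reference tabulations per model quantity; one third of locations report
    # the moderate-plus envelope as both-sex rows, another third in an
    # alternative dB range, to exercise harmonisation
    locs = list(res.truth.locations)
    loc_both = {l for i, l in enumerate(locs) if i % 3 == 1}
    loc_alt = {l for i, l in enumerate(locs) if i % 3 == 2}
    ranges = {
        "normal": (0.0, 20.0),
        "mild": (20.0, 35.0),
        "moderate_plus": (35.0, np.inf),
        **{s: scheme.range_of(s) for s in SEVERITY_ORDER[1:]},
    }
    survey: dict[str, list[PrevalenceDatum]] = {}
    for name, rng_db in ranges.items():
        rows = tabulate_survey(res.records, scheme, severity_ranges=[rng_db])
        if name == "moderate_plus":
            keep = [d for d in rows if d.location not in loc_both | loc_alt]
            both = tabulate_survey(
                res.records[res.records["location"].isin(loc_both)],
                scheme,
                severity_ranges=[rng_db],
                pool_sexes=True,
            )
            alt = tabulate_survey(
                res.records[res.records["location"].isin(loc_alt)],
                scheme,
                severity_ranges=[(30.0, np.inf)],
            )
            survey[name] = keep + both + alt
        else:
            survey[name] = rows
    res.survey = survey
    record("simulate", n_records=len(res.records), n_survey_rows=sum(map(len, survey.values())))
    if out_dir:
        hio.write_population(res.population, out_dir / "population.tsv")
        hio.write_survey(survey["moderate_plus"], out_dir / "survey_moderate_plus.tsv")
    if last == 0:
        return res

    # ---- process --------------------------------------------------------
    pairs = [d for d in survey["moderate_plus"] if d.sex in ("female", "male") and d.definition == "reference"]
    res.sex_model = fit_sex_ratio(pairs, trim=config.trim)
    res.crosswalk = fit_crosswalk(res.records, [(30.0, np.inf)], scheme)
    age_pattern = res.truth.moderate_plus().groupby("age_low").mean()
    processed = {
        name: process_all(rows, res.sex_model, res.crosswalk, age_pattern, res.population)
        for name, rows in survey.items()
    }
    res.survey = processed
    record("process", rows_out={k: len(v) for k, v in processed.items()})
    if last == 1:
        return res

    # ---- estimate -------------------------------------------------------
    covs = res.truth.covariates
    grid = default_grid(covs, config.world.sexes, config.world.age_lows)

    def fit(name: str, sign: int, offset: int) -> DrawSurface:
        mc = ModelConfig(
            spline_df=config.spline_df,
            covariate_sign=sign,
            draws=config.draws,
            seed=_stage_seed(config, "estimate") + offset,
            age_lows=tuple(config.world.age_lows),
        )
        return rename_category(fit_category_model(processed[name], mc, covs, grid), name)

    normal = fit("normal", +1, 0)
    mild = fit("mild", -1, 1)
    mod_plus = fit("moderate_plus", -1, 2)
    normal, mild, mod_plus = squeeze_top_level(normal, mild, mod_plus)
    five = {s: fit(s, -1, 3 + i) for i, s in enumerate(SEVERITY_ORDER[1:])}
    five = squeeze_severities(five, mod_plus)
    res.unadjusted = combine({"normal": normal, "mild": mild, **five})
    record("estimate", n_cells=len(grid), draws=config.draws)
    if last == 2:
        return res

    # ---- adjust ---------------------------------------------------------
    cov_obs = tabulate_coverage(res.records, scheme)
    mc_cov = ModelConfig(
        spline_df=3,
        draws=config.draws,
        seed=_stage_seed(config, "adjust"),
        age_lows=tuple(config.world.age_lows),
    )
    res.coverage = fit_coverage(cov_obs, mc_cov, grid)
    if config.apply_aid_adjustment:
        res.adjusted = apply_aid_shift(res.unadjusted, res.coverage)
    else:
        res.adjusted = res.unadjusted.copy()
        res.adjusted.aid_adjusted = True
    record("adjust", applied=config.apply_aid_adjustment)
    if last == 3:
        return res

    # ---- causes ---------------------------------------------------------
    loss_surface = DrawSurface(
        cells=res.adjusted.cells.copy(),
        values={s: res.adjusted.values[s] for s in SEVERITY_ORDER},
    )
    cause_obs = tabulate_causes(res.records, scheme)
    rng = np.random.default_rng(_stage_seed(config, "causes"))
    cause_models = _cause_models_from_obs(cause_obs, loss_surface, config.draws, rng)
    res.cause_surface = attribute_causes(loss_surface, cause_models, age_cutoff=config.age_cutoff)
    record("causes", negative_residuals=res.cause_surface.negative_residual_count)
    if last == 4:
        return res

    # ---- tinnitus -------------------------------------------------------
    res.tinnitus_props = estimate_tinnitus(res.records, scheme)
    res.states = split_by_tinnitus(loss_surface, res.tinnitus_props, seed=_stage_seed(config, "tinnitus"))
    record("tinnitus", n_states=len(res.states))
    if last == 5:
        return res

    # ---- burden ---------------------------------------------------------
    dw = DisabilityWeightTable.default()
    res.burden_local = compute_ylds(
        res.states,
        loss_surface.cells,
        dw,
        res.population,
        dw_uncertainty=config.dw_uncertainty,
        seed=_stage_seed(config, "burden"),
    )
    res.burden_regional = aggregate(res.burden_local, res.truth.regions)
    res.report = severity_table(res.adjusted, res.population, res.truth.regions, max(config.world.years))
    res.haq_fit = _haq_fit(res, standard_year=max(config.world.years))
    record("burden", n_rows=len(res.burden_local.frame))
    if out_dir:
        hio.write_table(res.burden_regional.summary(), out_dir / "burden_regional.tsv", "burden")
        hio.write_table(res.report, out_dir / "report_severity.tsv", "report")
    if last == 6:
        return res

    # ---- forecast -------------------------------------------------------
    rates = _regional_rates(res.adjusted, res.population, res.truth.regions)
    res.forecast_model = fit_forecast(
        rates, resamples=config.forecast_resamples, seed=_stage_seed(config, "forecast")
    )
    all_years = tuple(config.world.years) + tuple(config.forecast_years)
    pop_future = make_population(res.truth, _stage_seed(config, "simulate") + 1, years=all_years)
    proj_years = (max(config.world.years),) + tuple(config.forecast_years)
    res.forecast_cases = project(res.forecast_model, proj_years, pop_future, res.truth.regions)
    record("forecast", years=list(proj_years))
    if out_dir:
        hio.write_table(res.forecast_cases.summary(), out_dir / "forecast_cases.tsv", "forecast")
        (out_dir / "manifest.json").write_text(json.dumps(_manifest_with_checksums(manifest, out_dir), indent=2))
    return res


def _cause_models_from_obs(
    cause_obs: pd.DataFrame, loss_surface: DrawSurface, draws: int, rng: np.random.Generator
) -> dict[str, DrawSurface]:
    """Per-cause unscaled surfaces with binomial-normal draws, aligned to the grid.

    Strata with no observed cases receive a one-pseudo-case prior spread over
    the age group's pooled cause fractions, so the attribution's proportional
    squeeze below the cutoff always has positive mass to rescale.
    """
    cells = loss_surface.cells[CELL_KEYS].reset_index(drop=True)
    key = pd.MultiIndex.from_frame(cells)
    ages = cells["age_low"].to_numpy()
    pooled = cause_obs.groupby(["age_low", "cause"], observed=True)["cases"].sum().unstack(fill_value=0)
    pooled = pooled.reindex(columns=list(CAUSES), fill_value=0).astype(float) + 0.25
    pooled = pooled.div(pooled.sum(axis=1), axis=0)
    models: dict[str, DrawSurface] = {}
    for cause in CAUSES:
        prior_frac = pooled[cause].reindex(np.unique(ages)).fillna(1.0 / len(CAUSES))
        prior = prior_frac.loc[ages].to_numpy(dtype=float)
        values: dict[str, np.ndarray] = {}
        for sev in loss_surface.categories:
            sub = cause_obs[(cause_obs["cause"] == cause) & (cause_obs["severity"] == sev)]
            indexed = sub.set_index(CELL_KEYS)
            cases = indexed["cases"].reindex(key, fill_value=0.0).to_numpy(dtype=float)
            n = indexed["n"].reindex(key).to_numpy(dtype=float)
            finite = n[np.isfinite(n)]
            n = np.where(np.isfinite(n), n, float(np.median(finite)) if finite.size else 1.0)
            p = (cases + 0.25 * prior) / (n + 0.25)
            se = np.sqrt(np.maximum(p * (1 - p), 0.25 / n) / n)
            values[sev] = np.clip(p[:, None] + rng.normal(size=(len(p), draws)) * se[:, None], 1e-12, 1.0)
        models[cause] = DrawSurface(cells=cells.copy(), values=values)
    return models


def _haq_fit(res: PipelineResult, standard_year: int) -> tuple[float, float, float]:
    """OLS of location age-standardised YLD rates (per 100k) on the HAQ index."""
    standard = StandardPopulation.from_population(res.population, standard_year)
    totals = res.burden_local.totals(["location", "year", "age_low"])
    mask = totals.frame["year"] == standard_year
    frame = totals.frame[mask].copy()
    frame["ylds"] = totals.ylds[mask.to_numpy()].mean(axis=1)
    pop = res.population[res.population["year"] == standard_year]
    pop = pop.groupby(["location", "age_low"], as_index=False)["persons"].sum()
    frame = frame.merge(pop, on=["location", "age_low"])
    frame["rate"] = frame["ylds"] / frame["persons"]
    asr = frame.groupby("location").apply(
        lambda g: 1e5 * age_standardize(g.set_index("age_low")["rate"], standard=standard),
        include_groups=False,
    )
    haq = (
        res.truth.covariates[res.truth.covariates["year"] == standard_year]
        .set_index("location")["haq"]
    )
    return haq_regression(asr, haq)


def _regional_rates(
    surface: DrawSurface, population: pd.DataFrame, hierarchy: Mapping[str, str]
) -> pd.DataFrame:
    """Mean moderate-plus age-specific rates by region/sex/year (forecast input)."""
    mod_plus = np.sum([surface.values[s] for s in CATEGORY_ORDER[2:]], axis=0).mean(axis=1)
    frame = surface.cells[CELL_KEYS].copy()
    frame["rate_mean"] = mod_plus
    frame = frame.merge(population, on=CELL_KEYS, how="left")
    frame["region"] = frame["location"].map(dict(hierarchy))
    frame["cases"] = frame["rate_mean"] * frame["persons"]
    grouped = frame.groupby(["region", "sex", "year", "age_low"], as_index=False)[["cases", "persons"]].sum()
    grouped["rate"] = grouped["cases"] / grouped["persons"]
    return grouped[["region", "sex", "year", "age_low", "rate"]]


def _manifest_with_checksums(manifest: dict, out_dir: Path) -> dict:
    out = dict(manifest)
    out["checksums"] = {p.name: hio.checksum(p) for p in sorted(out_dir.glob("*.tsv"))}
    return out
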
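"""Synthetic hearing-loss world: ground truth, survey microdata, tabulation.

No population-representative audiometry microdata ship with this package, so
all downstream stages are exercised against a generative world with the
statistical structure the analysis assumes:

* better-ear pure-tone averages that increase and right-skew with age, with a
  small early-childhood bump in severe loss;
* hearing-aid coverage that rises with severity;
* tinnitus co-occurrence that rises with severity;
* cause mixtures dominated by otitis media / congenital defects / meningitis
  in childhood and by age-related and other causes in adults;
* a development covariate (SDI-like, in [0, 1]) that lowers loss prevalence,
  and a correlated healthcare-quality covariate (HAQ-like, 0-100).

``make_truth`` builds the exact generative quantities (an
:class:`EpidemicTruth`); ``simulate_microdata`` draws person-level audiometry
records from it; ``tabulate_survey`` turns records into survey-style
prevalence rows, including non-reference severity ranges and both-sex rows so
the harmonisation stage has something to do.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .severity import CATEGORY_ORDER, SEVERITY_ORDER, SeverityScheme

log = logging.getLogger(__name__)

CAUSES: tuple[str, ...] = ("congenital", "otitis_media", "meningitis", "age_other")

#: WHO-style region labels used when the default six-region world is built.
WHO_REGIONS: tuple[str, ...] = (
    "african",
    "americas",
    "eastern_mediterranean",
    "european",
    "south_east_asia",
    "western_pacific",
)


@dataclass(frozen=True)
class WorldConfig:
    """Generative parameters of the synthetic world.

    The defaults describe a desk-scale world: 6 regions x 3 locations,
    1990-2019 in 5-year steps (plus 2019), 2 sexes, twenty 5-year age groups.
    Epidemiological defaults are chosen so that any-loss prevalence rises
    steeply after middle age, the moderate-plus share grows with age with a
    small early-childhood bump, and cause mixtures flip from otitis media
    dominated in under-5s to age-related/other dominated in adults.
    """

    n_regions: int = 6
    locations_per_region: int = 3
    years: tuple[int, ...] = (1990, 1995, 2000, 2005, 2010, 2015, 2019)
    age_lows: tuple[int, ...] = tuple(range(0, 100, 5))
    sexes: tuple[str, ...] = ("female", "male")

    # any-loss (>=20 dB) logit model over age
    any_intercept: float = -3.2
    any_age_slope: float = 0.065
    any_age_onset: float = 25.0
    child_bump: float = 0.4
    sex_effect: float = 0.12  # male minus female, logit scale
    sdi_effect: float = -0.6  # per unit SDI, logit scale
    region_sd: float = 0.25
    location_sd: float = 0.12
    loss_scale: float = 1.0  # multiplies any-loss prevalence; 0 => all normal

    # moderate-plus share within any loss
    share_intercept: float = -1.6
    share_age_slope: float = 0.022
    share_child_bump: float = 1.0

    # conditional split of moderate-plus across the five severities
    severity_base_shares: tuple[float, ...] = (0.655, 0.210, 0.055, 0.047, 0.033)
    severity_tilt_child: float = 0.5
    severity_tilt_old: float = 0.012

    # severity-specific hearing-aid coverage and tinnitus proportions
    coverage_by_severity: Mapping[str, float] = field(
        default_factory=lambda: {
            "mild": 0.05,
            "moderate": 0.15,
            "moderately_severe": 0.25,
            "severe": 0.30,
            "profound": 0.32,
            "complete": 0.33,
        }
    )
    tinnitus_by_severity: Mapping[str, float] = field(
        default_factory=lambda: {
            "mild": 0.25,
            "moderate": 0.35,
            "moderately_severe": 0.40,
            "severe": 0.45,
            "profound": 0.50,
            "complete": 0.50,
        }
    )

    # cause mixture over age (unnormalised weights; see cause_fraction_table)
    cause_child_weights: tuple[float, ...] = (0.25, 0.637, 0.08, 0.033)
    cause_decay_years: tuple[float, ...] = (10.0, 15.0, 20.0)
    cause_age_other_onset: float = 15.0
    cause_age_other_scale: float = 12.0

    # population model
    pop_base_mean: float = 1_000_000.0
    pop_growth: float = 0.013  # annual
    pop_age_scale_1990: float = 28.0
    pop_ageing_per_year: float = 0.35  # age-scale growth per calendar year

    def __post_init__(self) -> None:
        for name, frac in [("loss_scale", self.loss_scale)]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        for mapping, label in [
            (self.coverage_by_severity, "coverage_by_severity"),
            (self.tinnitus_by_severity, "tinnitus_by_severity"),
        ]:
            for sev, v in mapping.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"{label}[{sev!r}] must lie in [0, 1], got {v}")
        if len(self.severity_base_shares) != 5 or any(s <= 0 for s in self.severity_base_shares):
            raise ValueError("severity_base_shares must be 5 positive numbers")
        if len(self.cause_child_weights) != 4 or any(w < 0 for w in self.cause_child_weights):
            raise ValueError("cause_child_weights must be 4 non-negative numbers")

    def region_names(self) -> tuple[str, ...]:
        if self.n_regions == len(WHO_REGIONS):
            return WHO_REGIONS
        return tuple(f"region_{i + 1}" for i in range(self.n_regions))


@dataclass
class EpidemicTruth:
    """Ground-truth generative quantities for one synthetic world.

    Attributes
    ----------
    prevalence
        MultiIndex (location, year, sex, age_low) x 7 category columns,
        summing to 1 across categories in every stratum.
    coverage, tinnitus
        Severity-indexed fractions (hearing-aid use; tinnitus co-occurrence).
    cause_fractions
        age_low x cause fractions among the impaired, summing to 1.
    covariates
        One row per (location, year) with ``sdi`` in [0, 1] and ``haq`` in
        [0, 100].
    """

    config: WorldConfig
    seed: int
    regions: dict[str, str]  # location -> region
    prevalence: pd.DataFrame
    coverage: pd.Series
    tinnitus: pd.Series
    cause_fractions: pd.DataFrame
    covariates: pd.DataFrame

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def validate(self, atol: float = 1e-9) -> None:
        prev = self.prevalence[list(CATEGORY_ORDER)]
        if ((prev.to_numpy() < -atol) | (prev.to_numpy() > 1 + atol)).any():
            raise ValueError("category prevalences outside [0, 1]")
        if not np.allclose(prev.sum(axis=1).to_numpy(), 1.0, atol=atol):
            raise ValueError("category prevalences do not sum to 1")
        if not np.allclose(self.cause_fractions.sum(axis=1).to_numpy(), 1.0, atol=atol):
            raise ValueError("cause fractions do not sum to 1")
        for series in (self.coverage, self.tinnitus):
            if ((series < 0) | (series > 1)).any():
                raise ValueError("coverage/tinnitus fractions outside [0, 1]")

    def moderate_plus(self) -> pd.Series:
        """True prevalence of >=35 dB loss per stratum."""
        return self.prevalence[list(CATEGORY_ORDER[2:])].sum(axis=1)


def _age_mid(age_lows: np.ndarray) -> np.ndarray:
    return age_lows + 2.5


def cause_fraction_table(config: WorldConfig) -> pd.DataFrame:
    """Cause fractions among the impaired by 5-year age group (rows sum to 1)."""
    a = _age_mid(np.asarray(config.age_lows, dtype=float))
    w_cong, w_om, w_men, w_other0 = config.cause_child_weights
    d_cong, d_om, d_men = config.cause_decay_years
    rel = np.clip(a - 2.5, 0.0, None)
    congenital = w_cong * np.exp(-rel / d_cong)
    otitis = w_om * np.exp(-rel / d_om)
    meningitis = w_men * np.exp(-rel / d_men)
    age_other = w_other0 + (1 - w_other0) * (
        1 - np.exp(-np.clip(a - config.cause_age_other_onset, 0.0, None) / config.cause_age_other_scale)
    )
    table = pd.DataFrame(
        {
            "congenital": congenital,
            "otitis_media": otitis,
            "meningitis": meningitis,
            "age_other": age_other,
        },
        index=pd.Index(config.age_lows, name="age_low"),
    )
    return table.div(table.sum(axis=1), axis=0)


def make_truth(config: WorldConfig | None = None, seed: int = 0) -> EpidemicTruth:
    """Build the ground-truth prevalence surfaces and ancillary quantities.

    Deterministic for a fixed ``(config, seed)``: region/location random
    effects, covariate trajectories and covariate noise all come from a single
    seeded generator.
    """
    config = config or WorldConfig()
    rng = np.random.default_rng(seed)

    region_names = config.region_names()
    regions: dict[str, str] = {}
    for r in region_names:
        for i in range(config.locations_per_region):
            regions[f"{r}_loc{i + 1}"] = r

    region_eff = dict(zip(region_names, rng.normal(0.0, config.region_sd, len(region_names))))
    loc_eff = {loc: rng.normal(0.0, config.location_sd) for loc in regions}

    # covariates: SDI drifts upward slowly; HAQ tracks SDI with noise
    sdi_region_base = dict(zip(region_names, rng.uniform(0.30, 0.80, len(region_names))))
    cov_rows = []
    for loc, reg in regions.items():
        base = np.clip(sdi_region_base[reg] + rng.normal(0.0, 0.05), 0.05, 0.9)
        for year in config.years:
            sdi = float(np.clip(base + 0.004 * (year - 1990), 0.0, 0.97))
            haq = float(np.clip(15.0 + 75.0 * sdi + rng.normal(0.0, 2.0), 0.0, 100.0))
            cov_rows.append({"location": loc, "year": year, "sdi": sdi, "haq": haq})
    covariates = pd.DataFrame(cov_rows)

    ages = np.asarray(config.age_lows, dtype=float)
    a = _age_mid(ages)
    bump = np.exp(-0.5 * ((a - 2.5) / 5.0) ** 2)
    base_any = (
        config.any_intercept
        + config.any_age_slope * np.clip(a - config.any_age_onset, 0.0, None)
        + config.child_bump * bump
    )
    base_share = (
        config.share_intercept
        + config.share_age_slope * np.clip(a - 30.0, 0.0, None)
        + config.share_child_bump * bump
    )
    tilt = config.severity_tilt_child * np.exp(-0.5 * ((a - 2.5) / 6.0) ** 2) + (
        config.severity_tilt_old * np.clip(a - 70.0, 0.0, None)
    )
    base_logshare = np.log(np.asarray(config.severity_base_shares))
    # (n_ages, 5): conditional split of moderate-plus across severities
    sev_w = np.exp(base_logshare[None, :] + tilt[:, None] * np.arange(5)[None, :])
    sev_split = sev_w / sev_w.sum(axis=1, keepdims=True)

    cov_idx = covariates.set_index(["location", "year"])
    index = pd.MultiIndex.from_product(
        [list(regions), config.years, config.sexes, config.age_lows],
        names=["location", "year", "sex", "age_low"],
    )
    frames = []
    for loc in regions:
        eff = region_eff[regions[loc]] + loc_eff[loc]
        for year in config.years:
            sdi = cov_idx.loc[(loc, year), "sdi"]
            for sex in config.sexes:
                sex_eff = (0.5 if sex == "male" else -0.5) * config.sex_effect
                logit_any = base_any + eff + sex_eff + config.sdi_effect * (sdi - 0.55)
                p_any = config.loss_scale * expit(logit_any)
                share = expit(base_share + 0.5 * sex_eff)
                p_mod = p_any * share
                block = np.empty((len(ages), len(CATEGORY_ORDER)))
                block[:, 0] = 1.0 - p_any
                block[:, 1] = p_any - p_mod
                block[:, 2:] = p_mod[:, None] * sev_split
                frames.append(block)
    prevalence = pd.DataFrame(
        np.vstack(frames), index=index, columns=list(CATEGORY_ORDER)
    )

    coverage = pd.Series(
        {"normal": 0.0, **{s: float(config.coverage_by_severity.get(s, 0.0)) for s in SEVERITY_ORDER}},
        name="coverage",
    )
    tinnitus = pd.Series(
        {s: float(config.tinnitus_by_severity.get(s, 0.0)) for s in SEVERITY_ORDER},
        name="tinnitus",
    )

    truth = EpidemicTruth(
        config=config,
        seed=seed,
        regions=regions,
        prevalence=prevalence,
        coverage=coverage,
        tinnitus=tinnitus,
        cause_fractions=cause_fraction_table(config),
        covariates=covariates,
    )
    truth.validate()
    return truth


def make_population(
    truth: EpidemicTruth,
    seed: int = 0,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Population counts by (location, year, sex, 5-year age group).

    The age pyramid is exponential with an age scale that grows over calendar
    time, so later years are both larger (growth) and older (ageing) -- the
    demographic regime under which stable age-specific rates still produce
    rising crude prevalence.  Pass future ``years`` to obtain the forecast
    population.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    years = tuple(years) if years is not None else cfg.years
    ages = np.asarray(cfg.age_lows, dtype=float)
    base_by_loc = {loc: cfg.pop_base_mean * rng.lognormal(0.0, 0.3) for loc in truth.locations}
    rows = []
    for loc in truth.locations:
        for year in years:
            scale = cfg.pop_age_scale_1990 + cfg.pop_ageing_per_year * (year - 1990)
            shape = np.exp(-ages / scale)
            shape /= shape.sum()
            total = base_by_loc[loc] * (1 + cfg.pop_growth) ** (year - 1990)
            for sex in cfg.sexes:
                persons = np.round(total * 0.5 * shape)
                for age_low, n in zip(cfg.age_lows, persons):
                    rows.append(
                        {"location": loc, "year": year, "sex": sex, "age_low": age_low, "persons": float(n)}
                    )
    return pd.DataFrame(rows)


def _pta_within_band(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if lo == 0.0:  # normal hearing: mildly right-skewed around ~8 dB
        return hi * rng.beta(1.6, 2.4, size)
    if math.isinf(hi):  # complete loss: exponential tail above 95 dB
        return lo + rng.exponential(8.0, size)
    return lo + (hi - lo) * rng.beta(1.2, 2.2, size)


def simulate_microdata(
    truth: EpidemicTruth,
    n_per_stratum: int,
    seed: int = 0,
    strata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw person-level audiometry records from the truth.

    One record per person with columns ``person_id, location, year, sex, age,
    better_ear_pta, uses_hearing_aid, tinnitus, cause``.  Severity-category
    membership is multinomial with the truth's category prevalences; the
    pure-tone average is then drawn within the category's dB band, so category
    mass matches the truth exactly in expectation.  Hearing-aid use and
    tinnitus are Bernoulli with the severity-specific truth fractions; causes
    follow the age-specific mixture and are ``"none"`` below 20 dB.

    Parameters
    ----------
    strata
        Optional frame with columns among (location, year) restricting which
        strata are simulated; default is the whole world.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    rng = np.random.default_rng(seed)
    scheme = SeverityScheme.default()
    prev = truth.prevalence
    if strata is not None:
        keep = pd.MultiIndex.from_frame(strata[["location", "year"]].drop_duplicates())
        mask = pd.MultiIndex.from_arrays(
            [prev.index.get_level_values("location"), prev.index.get_level_values("year")]
        ).isin(keep)
        prev = prev[mask]

    bands = {name: scheme.range_of(name) for name in CATEGORY_ORDER}
    cause_probs = truth.cause_fractions
    parts = []
    next_id = 0
    for (loc, year, sex, age_low), p in zip(prev.index, prev.to_numpy()):
        counts = rng.multinomial(n_per_stratum, p / p.sum())
        pta = np.empty(n_per_stratum)
        sev_idx = np.empty(n_per_stratum, dtype=int)
        pos = 0
        for ci, (name, cnt) in enumerate(zip(CATEGORY_ORDER, counts)):
            lo, hi = bands[name]
            pta[pos : pos + cnt] = _pta_within_band(rng, lo, hi, cnt)
            sev_idx[pos : pos + cnt] = ci
            pos += cnt
        impaired = sev_idx > 0
        cov = np.array([truth.coverage[CATEGORY_ORDER[i]] for i in range(7)])
        tin = np.array([0.0] + [truth.tinnitus[s] for s in SEVERITY_ORDER])
        uses_aid = rng.random(n_per_stratum) < cov[sev_idx]
        has_tin = rng.random(n_per_stratum) < tin[sev_idx]
        cause = np.full(n_per_stratum, "none", dtype=object)
        n_imp = int(impaired.sum())
        if n_imp:
            pc = cause_probs.loc[age_low].to_numpy()
            cause[impaired] = rng.choice(CAUSES, size=n_imp, p=pc / pc.sum())
        parts.append(
            pd.DataFrame(
                {
                    "person_id": np.arange(next_id, next_id + n_per_stratum),
                    "location": loc,
                    "year": year,
                    "sex": sex,
                    "age": age_low + rng.uniform(0.0, 5.0, n_per_stratum),
                    "better_ear_pta": pta,
                    "uses_hearing_aid": uses_aid,
                    "tinnitus": has_tin,
                    "cause": cause,
                }
            )
        )
        next_id += n_per_stratum
    records = pd.concat(parts, ignore_index=True)
    for col in ("location", "sex", "cause"):
        records[col] = records[col].astype("category")
    return records


def tabulate_survey(
    records: pd.DataFrame,
    scheme: SeverityScheme | None = None,
    age_band_width: int = 5,
    severity_ranges: Sequence[tuple[float, float]] | None = None,
    pool_sexes: bool = False,
) -> list:
    """Aggregate microdata into survey-style prevalence rows.

    Returns a list of :class:`~hearburden.harmonize.PrevalenceDatum`.  A row's
    definition flag is ``"reference"`` when its dB range endpoints both lie on
    scheme category boundaries, ``"alternative"`` otherwise.  Empty strata are
    omitted with a logged warning.
    """
    from .harmonize import PrevalenceDatum  # local import to avoid a cycle

    scheme = scheme or SeverityScheme.default()
    if severity_ranges is None:
        severity_ranges = [scheme.range_of(n) for n in scheme.names]
    boundaries = set(scheme.boundaries())

    frame = records.copy()
    frame["age_band"] = (frame["age"] // age_band_width).astype(int) * age_band_width
    group_cols = ["location", "year", "age_band"] + ([] if pool_sexes else ["sex"])

    out: list[PrevalenceDatum] = []
    for db_lo, db_hi in severity_ranges:
        if db_lo < 0:
            raise ValueError("severity ranges must lie within [0, inf) dB")
        affected = (frame["better_ear_pta"] >= db_lo) & (frame["better_ear_pta"] < db_hi)
        grouped = frame.assign(affected=affected).groupby(group_cols, observed=True)["affected"].agg(
            ["sum", "count"]
        )
        definition = "reference" if (db_lo in boundaries and db_hi in boundaries) else "alternative"
        for key, (n_aff, n_tot) in grouped.iterrows():
            if n_tot == 0:
                log.warning("empty stratum %s for range [%s, %s) omitted", key, db_lo, db_hi)
                continue
            key = key if isinstance(key, tuple) else (key,)
            rec = dict(zip(group_cols, key))
            out.append(
                PrevalenceDatum(
                    location=str(rec["location"]),
                    year=int(rec["year"]),
                    sex="both" if pool_sexes else str(rec["sex"]),
                    age_low=float(rec["age_band"]),
                    age_high=float(rec["age_band"] + age_band_width),
                    db_low=float(db_lo),
                    db_high=float(db_hi),
                    prevalence=float(n_aff / n_tot),
                    effective_sample_size=float(n_tot),
                    definition=definition,
                )
            )
    return out


def tabulate_coverage(
    records: pd.DataFrame,
    scheme: SeverityScheme | None = None,
    age_band_width: int = 5,
) -> pd.DataFrame:
    """Hearing-aid users / totals per (location, year, sex, age band, severity)."""
    scheme = scheme or SeverityScheme.default()
    frame = records[records["better_ear_pta"] >= 20.0].copy()
    edges = [lo for _, lo, _ in scheme.categories] + [np.inf]
    frame["severity"] = pd.cut(
        frame["better_ear_pta"], bins=edges, right=False, labels=scheme.names
    ).astype(str)
    frame["age_low"] = (frame["age"] // age_band_width).astype(int) * age_band_width
    grouped = (
        frame.groupby(["location", "year", "sex", "age_low", "severity"], observed=True)[
            "uses_hearing_aid"
        ]
        .agg(users="sum", total="count")
        .reset_index()
    )
    return grouped


def tabulate_causes(
    records: pd.DataFrame,
    scheme: SeverityScheme | None = None,
    age_band_width: int = 5,
) -> pd.DataFrame:
    """Cause-specific loss prevalence per (location, year, sex, age band, severity).

    ``prevalence`` is cases-of-(severity, cause) over the full stratum sample
    size, i.e. an unscaled cause-specific prevalence surface input.
    """
    scheme = scheme or SeverityScheme.default()
    frame = records.copy()
    frame["age_low"] = (frame["age"] // age_band_width).astype(int) * age_band_width
    totals = frame.groupby(["location", "year", "sex", "age_low"], observed=True).size().rename("n")
    impaired = frame[frame["better_ear_pta"] >= 20.0].copy()
    edges = [lo for _, lo, _ in scheme.categories] + [np.inf]
    impaired["severity"] = pd.cut(
        impaired["better_ear_pta"], bins=edges, right=False, labels=scheme.names
    ).astype(str)
    cases = (
        impaired.groupby(["location", "year", "sex", "age_low", "severity", "cause"], observed=True)
        .size()
        .rename("cases")
        .reset_index()
    )
    cases = cases.merge(totals.reset_index(), on=["location", "year", "sex", "age_low"])
    cases["prevalence"] = cases["cases"] / cases["n"]
    return cases
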
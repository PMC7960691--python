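"""Severity taxonomy for bilateral (better-ear) hearing loss.

Hearing loss is graded by the pure-tone average (PTA) of audiometric
thresholds at 0.5, 1, 2 and 4 kHz in the better-hearing ear, and reported in
seven mutually exclusive severity categories (normal through complete).  Each
non-normal severity carries two health states -- with and without tinnitus
("ringing") -- and each health state has a disability weight in [0, 1] used to
convert prevalence into years lived with disability.

The dB bands are implemented as half-open real intervals [db_low, db_high) so
that every non-negative pure-tone average maps to exactly one category; the
conventional printed integer ranges ("20-34 dB") correspond to [20, 35).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CATEGORY_ORDER",
    "SEVERITY_ORDER",
    "SeverityScheme",
    "HealthState",
    "DisabilityWeightTable",
    "classify_threshold",
    "lookup_weight",
]

#: Canonical category order, least to most severe.
CATEGORY_ORDER: tuple[str, ...] = (
    "normal",
    "mild",
    "moderate",
    "moderately_severe",
    "severe",
    "profound",
    "complete",
)

#: Loss categories only (everything above 20 dB).
SEVERITY_ORDER: tuple[str, ...] = CATEGORY_ORDER[1:]

#: Severities forming the moderate-to-complete envelope (>= 35 dB).
MODERATE_PLUS: tuple[str, ...] = CATEGORY_ORDER[2:]


@dataclass(frozen=True)
class SeverityScheme:
    """Ordered, contiguous dB-threshold categories over [0, inf).

    Parameters
    ----------
    categories
        Sequence of ``(name, db_low, db_high)`` with half-open ranges
        ``[db_low, db_high)``; the last range may be unbounded
        (``db_high = inf``).
    reference_frequencies_khz
        Frequencies averaged into the pure-tone average.
    """

    categories: tuple[tuple[str, float, float], ...]
    reference_frequencies_khz: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("scheme needs at least one category")
        if self.categories[0][1] != 0:
            raise ValueError("first category must start at 0 dB")
        prev_high = None
        for name, lo, hi in self.categories:
            if not lo < hi:
                raise ValueError(f"category {name!r}: require db_low < db_high")
            if prev_high is not None and lo != prev_high:
                raise ValueError("categories must be contiguous and ordered")
            prev_high = hi
        if not math.isinf(self.categories[-1][2]):
            raise ValueError("last category must be unbounded above")

    @classmethod
    def default(cls) -> "SeverityScheme":
        """The standard 7-category scheme (mild 20-34 dB ... complete 95+ dB)."""
        return cls(
            categories=(
                ("normal", 0.0, 20.0),
                ("mild", 20.0, 35.0),
                ("moderate", 35.0, 50.0),
                ("moderately_severe", 50.0, 65.0),
                ("severe", 65.0, 80.0),
                ("profound", 80.0, 95.0),
                ("complete", 95.0, math.inf),
            )
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.categories)

    def range_of(self, name: str) -> tuple[float, float]:
        for cat, lo, hi in self.categories:
            if cat == name:
                return (lo, hi)
        raise KeyError(f"unknown category {name!r}")

    def boundaries(self) -> tuple[float, ...]:
        """All category edges, including 0 and inf."""
        return tuple(lo for _, lo, _ in self.categories) + (math.inf,)

    def classify(self, pta_db: float) -> str:
        """Map a better-ear pure-tone average (dB) to its category name."""
        if not math.isfinite(pta_db) or pta_db < 0:
            raise ValueError(f"pure-tone average must be finite and >= 0, got {pta_db!r}")
        for name, lo, hi in self.categories:
            if lo <= pta_db < hi:
                return name
        raise AssertionError("unreachable: scheme covers [0, inf)")

    def loss_names(self) -> tuple[str, ...]:
        """Categories counting as any hearing loss (db_low >= 20)."""
        return tuple(n for n, lo, _ in self.categories if lo >= 20)

    def moderate_plus_names(self) -> tuple[str, ...]:
        """Categories in the moderate-to-complete envelope (db_low >= 35)."""
        return tuple(n for n, lo, _ in self.categories if lo >= 35)


@dataclass(frozen=True, order=True)
class HealthState:
    """A severity category crossed with tinnitus presence.

    ``normal`` admits no ringing variant; every other severity has exactly two
    states.
    """

    severity: str
    ringing: bool = False

    def __post_init__(self) -> None:
        if self.severity == "normal" and self.ringing:
            raise ValueError("'normal' hearing has no ringing health state")

    @property
    def name(self) -> str:
        return self.severity + ("_ringing" if self.ringing else "")


def all_health_states() -> tuple[HealthState, ...]:
    """The 13 health states: normal plus 6 severities x 2 ringing states."""
    states = [HealthState("normal", False)]
    for sev in SEVERITY_ORDER:
        states.append(HealthState(sev, False))
        states.append(HealthState(sev, True))
    return tuple(states)


class DisabilityWeightTable:
    """Health state -> (weight, lower, upper), all unitless fractions in [0, 1]."""

    def __init__(self, entries: Mapping[HealthState, tuple[float, float, float]]):
        self.entries = dict(entries)
        for state, (w, lo, hi) in self.entries.items():
            if not (0 <= lo <= w <= hi <= 1):
                raise ValueError(f"weights for {state.name} must satisfy 0<=lower<=weight<=upper<=1")
        for sev in SEVERITY_ORDER:
            plain = HealthState(sev, False)
            ring = HealthState(sev, True)
            if plain in self.entries and ring in self.entries:
                if self.entries[ring][0] < self.entries[plain][0]:
                    raise ValueError(f"ringing weight below non-ringing weight for {sev!r}")

    @classmethod
    def default(cls) -> "DisabilityWeightTable":
        """The packaged weight table (13 states)."""
        with resources.files("hearburden.data").joinpath("disability_weights.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t", comment="#")
        return cls.from_frame(frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DisabilityWeightTable":
        entries = {}
        for row in frame.itertuples(index=False):
            state = HealthState(row.severity, bool(row.ringing))
            entries[state] = (float(row.weight), float(row.lower), float(row.upper))
        return cls(entries)

    def weight(self, state: HealthState) -> float:
        """Point disability weight for a health state."""
        try:
            return self.entries[state][0]
        except KeyError:
            raise KeyError(f"no disability weight for state {state.name!r}") from None

    def interval(self, state: HealthState) -> tuple[float, float, float]:
        try:
            return self.entries[state]
        except KeyError:
            raise KeyError(f"no disability weight for state {state.name!r}") from None

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": s.name,
                "severity": s.severity,
                "ringing": int(s.ringing),
                "weight": w,
                "lower": lo,
                "upper": hi,
            }
            for s, (w, lo, hi) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def classify_threshold(pta_db: float, scheme: SeverityScheme | None = None) -> str:
    """Severity category containing a better-ear pure-tone average (dB)."""
    return (scheme or SeverityScheme.default()).classify(pta_db)


def lookup_weight(state: HealthState, table: DisabilityWeightTable | None = None) -> float:
    """Point disability weight for a health state."""
    return (table or DisabilityWeightTable.default()).weight(state)
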
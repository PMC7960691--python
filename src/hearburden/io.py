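"""Delimited-text input/output with versioned schema headers.

Every table this package writes is tab-separated text whose first line is a
comment of the form ``# hearburden-<schema> v1``; readers check it.  This
keeps all artefacts auditable with standard text tools.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .harmonize import PrevalenceDatum, data_to_frame, frame_to_data

SCHEMA_PREFIX = "# hearburden-"


def write_table(frame: pd.DataFrame, path: str | Path, schema: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX}{schema} v1\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(SCHEMA_PREFIX):
            raise ValueError(f"{path}: missing schema header line")
        if schema is not None and not header.startswith(f"{SCHEMA_PREFIX}{schema} "):
            raise ValueError(f"{path}: expected schema {schema!r}, found {header!r}")
        return pd.read_csv(fh, sep="\t")


def write_survey(data: Sequence[PrevalenceDatum], path: str | Path) -> Path:
    return write_table(data_to_frame(list(data)), path, "survey")


def read_survey(path: str | Path) -> list[PrevalenceDatum]:
    return frame_to_data(read_table(path, "survey"))


def write_population(population: pd.DataFrame, path: str | Path) -> Path:
    return write_table(population, path, "population")


def read_population(path: str | Path) -> pd.DataFrame:
    return read_table(path, "population")


def write_surface(surface, path: str | Path) -> Path:
    """Persist a DrawSurface as a long table (cell keys, category, draw, value)."""
    from .prevalence import CELL_KEYS

    frames = []
    for cat, arr in surface.values.items():
        base = surface.cells[CELL_KEYS]
        long = pd.DataFrame(arr, columns=[f"d{j}" for j in range(arr.shape[1])])
        long = pd.concat([base.reset_index(drop=True), long], axis=1)
        long.insert(len(CELL_KEYS), "category", cat)
        frames.append(long)
    return write_table(pd.concat(frames, ignore_index=True), path, "surface")


def read_surface(path: str | Path):
    from .prevalence import CELL_KEYS, DrawSurface

    frame = read_table(path, "surface")
    draw_cols = [c for c in frame.columns if c.startswith("d") and c[1:].isdigit()]
    values = {}
    cells = None
    for cat, sub in frame.groupby("category", observed=True, sort=False):
        sub = sub.reset_index(drop=True)
        if cells is None:
            cells = sub[CELL_KEYS].copy()
        values[cat] = sub[draw_cols].to_numpy()
    return DrawSurface(cells=cells, values=values)


def checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
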
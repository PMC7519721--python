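"""Readers and writers for multi-study population tables and result tables.

One row of a population table is one sampled population of one source
study: its study and species labels, locality in signed decimal degrees,
and the genetic-group label (clade or sub-clade membership as reported by
the source study).  Studies reporting separate nuclear and chloroplast
groupings are encoded as separate ``study_id`` rows per marker system, so
each study carries exactly one grouping.

All tables are comma-delimited UTF-8 text with mandatory headers; round
trips through disk are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd

from .qds_grid import GeoPoint

__all__ = ["Population", "StudySet", "StudyTableError", "read_populations", "write_populations"]

REQUIRED_COLUMNS = [
    "study_id",
    "species_id",
    "population_id",
    "latitude",
    "longitude",
    "genetic_group",
]


class StudyTableError(ValueError):
    """Schema or content error in a population table."""


@dataclass(frozen=True)
class Population:
    """One sampled population of one source study."""

    study_id: str
    species_id: str
    population_id: str
    location: GeoPoint
    genetic_group: str
    meta: Mapping[str, str] = field(default_factory=dict)

    @property
    def key(self):
        return (self.study_id, self.population_id)


@dataclass
class StudySet:
    """A corpus of populations from one or more source studies."""

    populations: List[Population]

    def __post_init__(self):
        seen = set()
        for p in self.populations:
            if p.key in seen:
                raise StudyTableError(f"duplicate (study_id, population_id) {p.key}")
            if not p.genetic_group:
                raise StudyTableError(f"population {p.key} has empty genetic_group")
            seen.add(p.key)

    @property
    def studies(self) -> Dict[str, List[Population]]:
        idx: Dict[str, List[Population]] = {}
        for p in self.populations:
            idx.setdefault(p.study_id, []).append(p)
        return idx

    def __len__(self) -> int:
        return len(self.populations)


def read_populations(path) -> StudySet:
    """Read and validate a population CSV into a :class:`StudySet`.

    The file needs the header ``study_id,species_id,population_id,latitude,
    longitude,genetic_group``; any further columns become free-form metadata.
    Errors report the offending 1-based data row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StudyTableError(f"missing required column(s): {missing}")
    meta_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    pops: List[Population] = []
    seen = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            lat = float(rec["latitude"])
            lon = float(rec["longitude"])
        except ValueError as exc:
            raise StudyTableError(f"row {i}: unparseable coordinate ({exc})") from None
        key = (rec["study_id"], rec["population_id"])
        if key in seen:
            raise StudyTableError(
                f"row {i}: duplicate (study_id, population_id) {key}, "
                f"first seen at row {seen[key]}"
            )
        seen[key] = i
        if not rec["genetic_group"]:
            raise StudyTableError(f"row {i}: empty genetic_group")
        pops.append(
            Population(
                study_id=rec["study_id"],
                species_id=rec["species_id"],
                population_id=rec["population_id"],
                location=GeoPoint(lat, lon),
                genetic_group=rec["genetic_group"],
                meta={c: rec[c] for c in meta_cols},
            )
        )
    return StudySet(pops)


def populations_frame(s: StudySet) -> pd.DataFrame:
    meta_cols: List[str] = []
    for p in s.populations:
        for c in p.meta:
            if c not in meta_cols:
                meta_cols.append(c)
    rows = []
    for p in s.populations:
        row = {
            "study_id": p.study_id,
            "species_id": p.species_id,
            "population_id": p.population_id,
            "latitude": p.location.latitude,
            "longitude": p.location.longitude,
            "genetic_group": p.genetic_group,
        }
        for c in meta_cols:
            row[c] = p.meta.get(c, "")
        rows.append(row)
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS + meta_cols)


def write_populations(s: StudySet, path) -> Path:
    """Write a :class:`StudySet` back to CSV (inverse of read_populations)."""
    path = Path(path)
    populations_frame(s).to_csv(path, index=False)
    return path
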
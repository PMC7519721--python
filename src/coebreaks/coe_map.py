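"""Centres of Endemism (CoEs) as quarter-degree-cell memberships.

A CoE map assigns QDS cells to named centres; cells belonging to no centre
are simply absent (the CoE mosaic does not tile the region completely).
The derived centre-adjacency graph supplies the boundaries across which
phylogeographic breaks are scored: two centres share a boundary when some
cell of one neighbours some cell of the other on the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Set, Tuple

import pandas as pd
from shapely.geometry import shape, Point

from .qds_grid import QDSCode, qds_centroid, qds_neighbors, iter_window

__all__ = ["CoEMap", "CoEMapError", "load_coe_map", "coe_adjacency", "boundary_cells"]

#: unordered pair of distinct CoE ids, canonically ordered for serialization
BoundaryId = Tuple[str, str]


class CoEMapError(ValueError):
    """Invalid or inconsistent CoE map input."""


def make_boundary(a: str, b: str) -> BoundaryId:
    if a == b:
        raise CoEMapError(f"boundary requires two distinct CoE ids, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass
class CoEMap:
    """Mapping of QDS cells to CoE ids plus optional sub-centre parentage."""

    cells: Dict[QDSCode, str]
    parent: Optional[Dict[str, str]] = None
    _adjacency_cache: Dict[str, FrozenSet[BoundaryId]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def coe_ids(self) -> Set[str]:
        return set(self.cells.values())

    def cells_of(self, coe_id: str) -> Set[QDSCode]:
        return {c for c, i in self.cells.items() if i == coe_id}

    def validate(self) -> None:
        if not self.cells:
            raise CoEMapError("CoE map is empty")

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "qds_code": c.text,
                "coe_id": i,
                "parent_id": (self.parent or {}).get(i, ""),
            }
            for c, i in sorted(self.cells.items(), key=lambda kv: kv[0].text)
        ]
        return pd.DataFrame(rows, columns=["qds_code", "coe_id", "parent_id"])


def _load_from_table(df: pd.DataFrame) -> CoEMap:
    if "qds_code" not in df.columns or "coe_id" not in df.columns:
        raise CoEMapError(
            f"cell table must have columns qds_code,coe_id; got {list(df.columns)}"
        )
    cells: Dict[QDSCode, str] = {}
    conflicts = []
    parent: Dict[str, str] = {}
    for _, row in df.iterrows():
        code = QDSCode.parse(str(row["qds_code"]).strip())
        coe = str(row["coe_id"]).strip()
        prev = cells.get(code)
        if prev is not None and prev != coe:
            conflicts.append(code.text)
        cells[code] = coe
        if "parent_id" in df.columns:
            p = str(row["parent_id"]).strip() if pd.notna(row["parent_id"]) else ""
            if p:
                parent[coe] = p
    if conflicts:
        raise CoEMapError(
            f"cells assigned to more than one CoE: {sorted(set(conflicts))}"
        )
    m = CoEMap(cells, parent or None)
    m.validate()
    return m


def _load_from_geojson(obj: dict) -> CoEMap:
    feats = obj.get("features")
    if feats is None:
        raise CoEMapError("GeoJSON input must be a FeatureCollection")
    cells: Dict[QDSCode, str] = {}
    conflicts = []
    parent: Dict[str, str] = {}
    for feat in feats:
        props = feat.get("properties") or {}
        if "coe_id" not in props:
            raise CoEMapError("each feature needs a 'coe_id' property")
        coe = str(props["coe_id"])
        geom = shape(feat["geometry"])
        lon_min, lat_min, lon_max, lat_max = geom.bounds
        for code in iter_window(lat_min, lat_max, lon_min, lon_max):
            ctr = qds_centroid(code)
            if geom.contains(Point(ctr.longitude, ctr.latitude)):
                prev = cells.get(code)
                if prev is not None and prev != coe:
                    conflicts.append(code.text)
                cells[code] = coe
        if props.get("parent_id"):
            parent[coe] = str(props["parent_id"])
    if conflicts:
        raise CoEMapError(
            f"cells assigned to more than one CoE: {sorted(set(conflicts))}"
        )
    m = CoEMap(cells, parent or None)
    m.validate()
    return m


def load_coe_map(source) -> CoEMap:
    """Load a CoE map from a cell-membership table or GeoJSON polygons.

    Accepts a path to a CSV with header ``qds_code,coe_id[,parent_id]``, a
    path to a GeoJSON FeatureCollection whose features carry a ``coe_id``
    property, an already-parsed GeoJSON dict, or a DataFrame.  Polygons are
    rasterized to QDS cells by cell-centroid containment.
    """
    if isinstance(source, pd.DataFrame):
        return _load_from_table(source)
    if isinstance(source, dict):
        return _load_from_geojson(source)
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _load_from_geojson(json.loads(text))
    return _load_from_table(pd.read_csv(path, dtype=str))


def coe_adjacency(m: CoEMap, mode: str = "rook") -> FrozenSet[BoundaryId]:
    """Set of CoE boundaries: pairs of centres with grid-neighbouring cells.

    ``mode`` selects the grid neighbourhood (rook = shared edge, queen =
    edge or corner).  The result is cached on the map.
    """
    cached = m._adjacency_cache.get(mode)
    if cached is not None:
        return cached
    edges: Set[BoundaryId] = set()
    for cell, coe in m.cells.items():
        for nb in qds_neighbors(cell, mode):
            other = m.cells.get(nb)
            if other is not None and other != coe:
                edges.add(make_boundary(coe, other))
    result = frozenset(edges)
    m._adjacency_cache[mode] = result
    return result


def boundary_cells(m: CoEMap, b: BoundaryId, mode: str = "rook") -> FrozenSet[QDSCode]:
    """Cells of either CoE of boundary ``b`` that touch the other CoE."""
    b = make_boundary(*b)
    if b not in coe_adjacency(m, mode):
        raise CoEMapError(f"CoEs {b[0]!r} and {b[1]!r} are not adjacent")
    a_id, b_id = b
    out: Set[QDSCode] = set()
    for cell, coe in m.cells.items():
        if coe not in b:
            continue
        other = b_id if coe == a_id else a_id
        if any(m.cells.get(nb) == other for nb in qds_neighbors(cell, mode)):
            out.add(cell)
    return frozenset(out)
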
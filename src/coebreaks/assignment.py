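"""Assigning populations to Centres of Endemism, with boundary uncertainty.

Each population is dropped onto the QDS grid and takes the CoE of its
cell; populations in unmapped cells are OUTSIDE and excluded from all
pairing.  Populations near a boundary between centres are hard to place,
so a null-promoting rule applies: they are flagged UNCERTAIN, and unless
their genetic group is unique among all populations of either candidate
centre (same study), their across-boundary pairs are scored as non-breaks.

"Near the boundary" is operationalized two ways, because mapping scale
alone does not fix it: the whole boundary cell (``buffer_cells=1``, the
conservative default at quarter-degree scale), or a great-circle distance
to the shared cell edge (``buffer_km``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Optional, Sequence

import pandas as pd

from .coe_map import CoEMap
from .qds_grid import GeoPoint, QDSCode, encode_qds, qds_bounds, qds_neighbors
from .study_io import Population, StudySet

__all__ = [
    "Status",
    "Assignment",
    "assign_population",
    "flag_uncertain",
    "resolve_uncertain",
    "assign_all",
]

EARTH_RADIUS_KM = 6371.0088


class Status(enum.Enum):
    ASSIGNED = "ASSIGNED"
    UNCERTAIN = "UNCERTAIN"
    OUTSIDE = "OUTSIDE"


@dataclass(frozen=True)
class Assignment:
    """CoE membership of one population.

    ``coe_id`` is the assigned centre when ASSIGNED and the containing
    centre when UNCERTAIN; ``candidates`` holds the containing centre plus
    adjacent alternatives when UNCERTAIN; ``unique_flag`` is True when an
    UNCERTAIN population's genetic group occurs in no other population of
    any candidate centre (same study), in which case it stays break-capable.
    """

    population: Population
    status: Status
    cell: Optional[QDSCode] = None
    coe_id: Optional[str] = None
    candidates: FrozenSet[str] = frozenset()
    unique_flag: bool = False

    def __post_init__(self):
        if self.status is Status.ASSIGNED:
            assert self.coe_id is not None and not self.candidates
        elif self.status is Status.UNCERTAIN:
            assert len(self.candidates) >= 2 and self.coe_id in self.candidates
        else:
            assert self.coe_id is None


def assign_population(p: Population, m: CoEMap) -> Assignment:
    """Assign ``p`` to the CoE of its quarter-degree cell, or OUTSIDE."""
    cell = encode_qds(p.location)
    coe = m.cells.get(cell)
    if coe is None:
        return Assignment(p, Status.OUTSIDE, cell=cell)
    return Assignment(p, Status.ASSIGNED, cell=cell, coe_id=coe)


def _haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    la1, lo1, la2, lo2 = map(math.radians, (a.latitude, a.longitude, b.latitude, b.longitude))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def _distance_to_shared_edge_km(p: GeoPoint, cell: QDSCode, neighbor: QDSCode) -> float:
    """Great-circle distance from ``p`` to the cell edge shared with ``neighbor``.

    The shared edge of two rook-neighbouring cells is a segment of constant
    latitude or longitude; the nearest point on it is found by clamping the
    free coordinate, which is exact for meridian edges and an excellent
    approximation at parallel edges over 0.25° spans.
    """
    lat1, lat2, lon1, lon2 = qds_bounds(cell)
    nlat1, nlat2, nlon1, nlon2 = qds_bounds(neighbor)
    if neighbor.row == cell.row:  # east/west neighbour: shared meridian edge
        edge_lon = lon2 if neighbor.col > cell.col else lon1
        nearest = GeoPoint(min(max(p.latitude, lat1), lat2), edge_lon)
    else:  # north/south neighbour: shared parallel edge
        edge_lat = lat1 if neighbor.row > cell.row else lat2
        nearest = GeoPoint(edge_lat, min(max(p.longitude, lon1), lon2))
    return _haversine_km(p, nearest)


def flag_uncertain(
    a: Assignment,
    m: CoEMap,
    buffer_cells: int = 0,
    buffer_km: float = 0.0,
    mode: str = "rook",
) -> Assignment:
    """Flag an ASSIGNED population as UNCERTAIN when it sits near a boundary.

    With ``buffer_cells >= 1`` the whole boundary cell counts as near; with
    ``buffer_km > 0`` the population must lie within that great-circle
    distance of a cell edge shared with another centre.  With both zero no
    population is ever flagged (uncertainty disabled).
    """
    if buffer_cells < 0 or buffer_km < 0:
        raise ValueError(
            f"buffers must be non-negative, got buffer_cells={buffer_cells}, "
            f"buffer_km={buffer_km}"
        )
    if a.status is not Status.ASSIGNED:
        return a
    if buffer_cells == 0 and buffer_km == 0:
        return a
    other_coes = set()
    for nb in qds_neighbors(a.cell, mode):
        coe = m.cells.get(nb)
        if coe is not None and coe != a.coe_id:
            if buffer_cells >= 1:
                other_coes.add(coe)
            elif (
                _distance_to_shared_edge_km(a.population.location, a.cell, nb)
                <= buffer_km
            ):
                other_coes.add(coe)
    if not other_coes:
        return a
    return replace(
        a,
        status=Status.UNCERTAIN,
        candidates=frozenset({a.coe_id} | other_coes),
    )


def resolve_uncertain(assignments: Sequence[Assignment], s: StudySet) -> List[Assignment]:
    """Set ``unique_flag`` on UNCERTAIN assignments by genetic uniqueness.

    An UNCERTAIN population is genetically unique when its group label
    matches no other population of the same study that is assigned to, or
    uncertain-within, any of its candidate centres.  Unique populations
    remain break-capable; non-unique ones are scored as non-breaks in
    across-boundary comparisons.  Comparison never crosses studies because
    group labels are not comparable between source studies.
    """
    by_study: Dict[str, List[Assignment]] = {}
    for a in assignments:
        by_study.setdefault(a.population.study_id, []).append(a)
    out: List[Assignment] = []
    for a in assignments:
        if a.status is not Status.UNCERTAIN:
            out.append(a)
            continue
        unique = True
        for other in by_study[a.population.study_id]:
            if other.population.key == a.population.key:
                continue
            if other.status is Status.OUTSIDE:
                continue
            touches = (
                {other.coe_id} if other.status is Status.ASSIGNED else set(other.candidates)
            )
            if touches & a.candidates and (
                other.population.genetic_group == a.population.genetic_group
            ):
                unique = False
                break
        out.append(replace(a, unique_flag=unique))
    return out


def assign_all(
    s: StudySet,
    m: CoEMap,
    buffer_cells: int = 0,
    buffer_km: float = 0.0,
    mode: str = "rook",
) -> List[Assignment]:
    """Assign, flag and resolve every population of a study set."""
    assigned = [
        flag_uncertain(assign_population(p, m), m, buffer_cells, buffer_km, mode)
        for p in s.populations
    ]
    return resolve_uncertain(assigned, s)


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Export assignments as a table (candidates pipe-separated)."""
    rows = [
        {
            "study_id": a.population.study_id,
            "population_id": a.population.population_id,
            "qds_code": a.cell.text if a.cell else "",
            "status": a.status.value,
            "coe_id": a.coe_id or "",
            "candidates": "|".join(sorted(a.candidates)),
            "unique_flag": a.unique_flag,
        }
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "population_id",
            "qds_code",
            "status",
            "coe_id",
            "candidates",
            "unique_flag",
        ],
    )
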
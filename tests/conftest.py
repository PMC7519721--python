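import pandas as pd
import pytest

from coebreaks import CoEMap, GeoPoint, Population, StudySet, load_coe_map
from coebreaks.qds_grid import QDSCode, qds_bounds


def cell(row: int, col: int) -> QDSCode:
    return QDSCode.from_indices(row, col)


def centroid(c: QDSCode) -> GeoPoint:
    lat_min, lat_max, lon_min, lon_max = qds_bounds(c)
    return GeoPoint((lat_min + lat_max) / 2, (lon_min + lon_max) / 2)


def pop(study, species, pid, location, group, **meta) -> Population:
    return Population(study, species, pid, location, group, meta)


@pytest.fixture
def two_coe_map() -> CoEMap:
    """Two 2x2 centres sharing a vertical boundary: X (west) and Y (east)."""
    cells = {}
    for r in (132, 133):
        for k in (72, 73):
            cells[cell(r, k)] = "X"
        for k in (74, 75):
            cells[cell(r, k)] = "Y"
    return CoEMap(cells)


@pytest.fixture
def three_coe_map() -> CoEMap:
    """X and Y adjacent; Z isolated two rows south."""
    cells = {}
    for r in (132, 133):
        for k in (72, 73):
            cells[cell(r, k)] = "X"
        for k in (74, 75):
            cells[cell(r, k)] = "Y"
    for r in (136, 137):
        for k in (72, 73):
            cells[cell(r, k)] = "Z"
    return CoEMap(cells)
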
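"""Quarter Degree Square (QDS) grid codes for southern Africa.

A QDS code such as ``"3318CD"`` names a 0.25° × 0.25° cell of the South
African mapping grid: the leading four digits give the one-degree cell
(degrees south, degrees east of its north-west corner), and two quadrant
letters subdivide it twice, with ``A`` = NW, ``B`` = NE, ``C`` = SW and
``D`` = SE at each level.  Cape Town city centre (33.95°S, 18.42°E) lies
in 3318CD.

Cell intervals are half-open toward increasing south and increasing east,
so a locality lying exactly on a shared edge belongs to exactly one cell.
Latitudes are signed decimal degrees (negative = south); the code renders
degrees south as a positive integer, following the national convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet, Iterator, Tuple

__all__ = [
    "GeoPoint",
    "QDSCode",
    "QDSDomainError",
    "QDSParseError",
    "encode_qds",
    "qds_bounds",
    "qds_neighbors",
]

#: quadrant letters in (row, col) order within a parent cell; rows increase
#: southward, columns eastward, so A=NW, B=NE, C=SW, D=SE.
_LETTERS = "ABCD"

CELL_DEG = 0.25


class QDSDomainError(ValueError):
    """Coordinate outside the southern/eastern-hemisphere validity domain."""


class QDSParseError(ValueError):
    """Malformed QDS code string; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 locality in signed decimal degrees (negative = south)."""

    latitude: float
    longitude: float


def _letter_to_rc(letter: str, position: int) -> Tuple[int, int]:
    idx = _LETTERS.find(letter)
    if idx < 0:
        raise QDSParseError(f"invalid quadrant letter {letter!r}", position)
    return divmod(idx, 2)


def _rc_to_letter(row: int, col: int) -> str:
    return _LETTERS[2 * row + col]


@dataclass(frozen=True, order=True)
class QDSCode:
    """A parsed quarter-degree-square code."""

    deg_south: int
    deg_east: int
    half_quadrant: str
    quarter_quadrant: str

    @property
    def text(self) -> str:
        """Canonical string rendering, e.g. ``"3318CD"``."""
        return (
            f"{self.deg_south:02d}{self.deg_east:02d}"
            f"{self.half_quadrant}{self.quarter_quadrant}"
        )

    @classmethod
    def parse(cls, text: str) -> "QDSCode":
        """Parse a canonical code string (4 digits + 2 letters)."""
        if len(text) < 6:
            raise QDSParseError(f"code {text!r} too short", len(text))
        if len(text) > 6 and not text[4:-2].isdigit():
            raise QDSParseError(f"code {text!r} has trailing characters", 6)
        digits, letters = text[:-2], text[-2:]
        if not digits.isdigit():
            bad = next(i for i, ch in enumerate(digits) if not ch.isdigit())
            raise QDSParseError(f"expected digit, got {digits[bad]!r}", bad)
        if len(digits) != 4:
            raise QDSParseError(f"expected 4 digits, got {len(digits)}", 0)
        _letter_to_rc(letters[0], 4)
        _letter_to_rc(letters[1], 5)
        return cls(int(digits[:2]), int(digits[2:]), letters[0], letters[1])

    # ---- global quarter-degree indices -------------------------------------
    # row counts 0.25° steps southward from the equator, col eastward from the
    # prime meridian; they make neighbour arithmetic trivial.

    @property
    def row(self) -> int:
        hr, _ = _letter_to_rc(self.half_quadrant, 4)
        qr, _ = _letter_to_rc(self.quarter_quadrant, 5)
        return self.deg_south * 4 + 2 * hr + qr

    @property
    def col(self) -> int:
        _, hc = _letter_to_rc(self.half_quadrant, 4)
        _, qc = _letter_to_rc(self.quarter_quadrant, 5)
        return self.deg_east * 4 + 2 * hc + qc

    @classmethod
    def from_indices(cls, row: int, col: int) -> "QDSCode":
        if row < 0 or col < 0:
            raise QDSDomainError(f"indices out of domain: row={row}, col={col}")
        deg_s, sub_r = divmod(row, 4)
        deg_e, sub_c = divmod(col, 4)
        hr, qr = divmod(sub_r, 2)
        hc, qc = divmod(sub_c, 2)
        return cls(deg_s, deg_e, _rc_to_letter(hr, hc), _rc_to_letter(qr, qc))

    def __str__(self) -> str:
        return self.text


def _as_code(c: "QDSCode | str") -> QDSCode:
    return c if isinstance(c, QDSCode) else QDSCode.parse(c)


def encode_qds(p: "GeoPoint | Tuple[float, float]") -> QDSCode:
    """Return the code of the quarter-degree cell containing ``p``.

    Cells are half-open toward increasing south and east: a point on the
    northern or western edge of a cell belongs to that cell.

    Raises
    ------
    QDSDomainError
        If the latitude is not in [-90, 0) or the longitude not in (0, 180].
    """
    if not isinstance(p, GeoPoint):
        p = GeoPoint(*p)
    if not (-90.0 <= p.latitude < 0.0):
        raise QDSDomainError(
            f"latitude {p.latitude} outside [-90, 0): southern hemisphere only"
        )
    if not (0.0 < p.longitude <= 180.0):
        raise QDSDomainError(
            f"longitude {p.longitude} outside (0, 180]: eastern hemisphere only"
        )
    row = math.floor(-p.latitude / CELL_DEG)
    col = math.floor(p.longitude / CELL_DEG)
    return QDSCode.from_indices(row, col)


def qds_bounds(c: "QDSCode | str") -> Tuple[float, float, float, float]:
    """Bounding rectangle ``(lat_min, lat_max, lon_min, lon_max)`` of a cell.

    Signed decimal degrees; the rectangle spans exactly 0.25° × 0.25°.
    """
    c = _as_code(c)
    s0 = c.row * CELL_DEG
    e0 = c.col * CELL_DEG
    return (-(s0 + CELL_DEG), -s0, e0, e0 + CELL_DEG)


def qds_centroid(c: "QDSCode | str") -> GeoPoint:
    """Interior centroid of a cell."""
    lat_min, lat_max, lon_min, lon_max = qds_bounds(c)
    return GeoPoint((lat_min + lat_max) / 2.0, (lon_min + lon_max) / 2.0)


def qds_neighbors(c: "QDSCode | str", mode: str = "rook") -> FrozenSet[QDSCode]:
    """Neighbouring cells of ``c``.

    ``rook`` returns the 4 edge-sharing cells, ``queen`` the 8 edge-or-corner
    cells, correctly crossing one-degree-cell and quadrant-letter boundaries.
    Offsets that leave the southern/eastern hemisphere are dropped.
    """
    c = _as_code(c)
    if mode == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif mode == "queen":
        offsets = [
            (dr, dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
    else:
        raise ValueError(f"mode must be 'rook' or 'queen', got {mode!r}")
    out = set()
    for dr, dc in offsets:
        r, k = c.row + dr, c.col + dc
        if r >= 0 and k >= 0:
            out.add(QDSCode.from_indices(r, k))
    return frozenset(out)


def iter_window(
    lat_min: float, lat_max: float, lon_min: float, lon_max: float
) -> Iterator[QDSCode]:
    """Yield all cells whose centroid falls in the given lat/lon window."""
    row0 = math.floor(-lat_max / CELL_DEG)
    row1 = math.ceil(-lat_min / CELL_DEG)
    col0 = math.floor(lon_min / CELL_DEG)
    col1 = math.ceil(lon_max / CELL_DEG)
    for r in range(row0, row1):
        for k in range(col0, col1):
            c = QDSCode.from_indices(r, k)
            ctr = qds_centroid(c)
            if lat_min <= ctr.latitude <= lat_max and lon_min <= ctr.longitude <= lon_max:
                yield c
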
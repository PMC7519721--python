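"""Scoring population pairs across and within Centre-of-Endemism boundaries.

Pairs are formed within species within study, never between species or
studies: genetic groups are clade memberships within a species' phylogeny.
A pair straddling an adjacent-CoE boundary is a BREAK when its group
labels differ and HOMOGENEITY when they agree — unless an endpoint has
uncertain CoE membership and is not genetically unique, in which case the
pair is scored UNCERTAIN, a non-break (the null-promoting rule).  Pairs
within a single centre are BREAK or HOMOGENEITY only.

Pairs between non-adjacent centres are discarded: only adjacent-CoE
boundaries are under test.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .coe_map import BoundaryId, make_boundary
from .assignment import Assignment, Status
from .study_io import StudySet

__all__ = [
    "Category",
    "PairScore",
    "ScoreTally",
    "enumerate_across_pairs",
    "enumerate_within_pairs",
    "score_pair",
    "score_all",
    "tally",
    "study_summary",
    "write_pair_scores",
    "read_pair_scores",
]


class Category(enum.Enum):
    BREAK = "break"
    HOMOGENEITY = "homogeneity"
    UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class PairScore:
    """One scored population pair (unordered; canonical by population_id)."""

    study_id: str
    species_id: str
    pop_a: str
    pop_b: str
    relation: str  # "across" | "within"
    place: Union[BoundaryId, str]  # boundary for across, coe_id for within
    category: Category

    def __post_init__(self):
        assert self.pop_a != self.pop_b
        if self.category is Category.UNCERTAIN:
            assert self.relation == "across"


def _ordered(a: Assignment, b: Assignment) -> Tuple[Assignment, Assignment]:
    if a.population.population_id <= b.population.population_id:
        return a, b
    return b, a


def _pairable(assignments: Sequence[Assignment]) -> Dict[Tuple[str, str], List[Assignment]]:
    """Group non-OUTSIDE assignments by (study, species)."""
    groups: Dict[Tuple[str, str], List[Assignment]] = {}
    for a in assignments:
        if a.status is Status.OUTSIDE:
            continue
        key = (a.population.study_id, a.population.species_id)
        groups.setdefault(key, []).append(a)
    return groups


def enumerate_across_pairs(
    assignments: Sequence[Assignment], adjacency: FrozenSet[BoundaryId]
) -> List[Tuple[Assignment, Assignment]]:
    """All same-study same-species pairs straddling an adjacent-CoE boundary.

    Both ASSIGNED and UNCERTAIN populations participate via their
    (containing) ``coe_id``; pairs whose centres are not adjacent are
    excluded, and OUTSIDE populations never pair.
    """
    pairs = []
    for members in _pairable(assignments).values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if a.coe_id == b.coe_id:
                    continue
                if make_boundary(a.coe_id, b.coe_id) in adjacency:
                    pairs.append(_ordered(a, b))
    return pairs


def enumerate_within_pairs(
    assignments: Sequence[Assignment], include_uncertain: bool = False
) -> List[Tuple[Assignment, Assignment]]:
    """All same-study same-species pairs inside a single centre.

    By default only ASSIGNED populations pair (the membership of UNCERTAIN
    populations is by definition ambiguous); set ``include_uncertain`` to
    pair them under their containing centre.
    """
    ok = {Status.ASSIGNED} | ({Status.UNCERTAIN} if include_uncertain else set())
    pairs = []
    for members in _pairable(assignments).values():
        eligible = [a for a in members if a.status in ok]
        for i in range(len(eligible)):
            for j in range(i + 1, len(eligible)):
                a, b = eligible[i], eligible[j]
                if a.coe_id == b.coe_id:
                    pairs.append(_ordered(a, b))
    return pairs


def score_pair(a: Assignment, b: Assignment, relation: str) -> PairScore:
    """Score one enumerated pair.

    Across pairs with a non-unique UNCERTAIN endpoint are UNCERTAIN (a
    non-break); otherwise the pair is a BREAK iff the group labels differ.
    """
    a, b = _ordered(a, b)
    labels_differ = a.population.genetic_group != b.population.genetic_group
    if relation == "across":
        place: Union[BoundaryId, str] = make_boundary(a.coe_id, b.coe_id)
        non_unique_uncertain = any(
            x.status is Status.UNCERTAIN and not x.unique_flag for x in (a, b)
        )
        if non_unique_uncertain:
            cat = Category.UNCERTAIN
        else:
            cat = Category.BREAK if labels_differ else Category.HOMOGENEITY
    elif relation == "within":
        place = a.coe_id
        cat = Category.BREAK if labels_differ else Category.HOMOGENEITY
    else:
        raise ValueError(f"relation must be 'across' or 'within', got {relation!r}")
    return PairScore(
        study_id=a.population.study_id,
        species_id=a.population.species_id,
        pop_a=a.population.population_id,
        pop_b=b.population.population_id,
        relation=relation,
        place=place,
        category=cat,
    )


def score_all(
    assignments: Sequence[Assignment],
    adjacency: FrozenSet[BoundaryId],
    include_uncertain_within: bool = False,
) -> List[PairScore]:
    """Enumerate and score every across- and within-CoE pair."""
    scores = [
        score_pair(a, b, "across")
        for a, b in enumerate_across_pairs(assignments, adjacency)
    ]
    scores += [
        score_pair(a, b, "within")
        for a, b in enumerate_within_pairs(assignments, include_uncertain_within)
    ]
    return scores


@dataclass
class ScoreTally:
    """Per-boundary and per-CoE category counts with grand totals."""

    per_boundary: Dict[BoundaryId, Counter]
    per_coe: Dict[str, Counter]

    @property
    def across(self) -> Counter:
        total: Counter = Counter()
        for c in self.per_boundary.values():
            total.update(c)
        return total

    @property
    def within(self) -> Counter:
        total: Counter = Counter()
        for c in self.per_coe.values():
            total.update(c)
        return total

    @property
    def across_total(self) -> int:
        return sum(self.across.values())

    @property
    def within_total(self) -> int:
        return sum(self.within.values())

    @property
    def across_nonbreak_combined(self) -> int:
        """Uncertain pairs combined with inter-CoE homogeneity (non-breaks)."""
        c = self.across
        return c[Category.HOMOGENEITY] + c[Category.UNCERTAIN]


def tally(pairs: Sequence[PairScore]) -> ScoreTally:
    """Tally scored pairs per boundary and per centre."""
    per_boundary: Dict[BoundaryId, Counter] = {}
    per_coe: Dict[str, Counter] = {}
    for p in pairs:
        if p.relation == "across":
            per_boundary.setdefault(p.place, Counter())[p.category] += 1
        else:
            per_coe.setdefault(p.place, Counter())[p.category] += 1
    t = ScoreTally(per_boundary, per_coe)
    # conservation: per-place counts must sum to the grand totals
    assert sum(sum(c.values()) for c in per_boundary.values()) == t.across_total
    assert sum(sum(c.values()) for c in per_coe.values()) == t.within_total
    return t


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def study_summary(pairs: Sequence[PairScore], s: StudySet) -> pd.DataFrame:
    """Per-study summary with integer percentages.

    Columns: centres covered, boundaries compared, % across-pairs BREAK /
    UNCERTAIN / HOMOGENEITY, % within-pairs BREAK.  A study with no across
    (or within) pairs reports not-applicable (NA), not zero.
    """
    rows = []
    for study_id in sorted(s.studies):
        sp = [p for p in pairs if p.study_id == study_id]
        across = [p for p in sp if p.relation == "across"]
        within = [p for p in sp if p.relation == "within"]
        boundaries = {p.place for p in across}
        coes = set()
        for p in across:
            coes.update(p.place)
        coes.update(p.place for p in within)
        n_a, n_w = len(across), len(within)

        def pct(cat: Category, pool, n) -> Optional[int]:
            if n == 0:
                return None
            return _round_half_up(100.0 * sum(p.category is cat for p in pool) / n)

        rows.append(
            {
                "study_id": study_id,
                "n_coes": len(coes),
                "n_boundaries": len(boundaries),
                "pct_break_across": pct(Category.BREAK, across, n_a),
                "pct_uncertain": pct(Category.UNCERTAIN, across, n_a),
                "pct_homogeneity_across": pct(Category.HOMOGENEITY, across, n_a),
                "pct_break_within": pct(Category.BREAK, within, n_w),
                "n_across_pairs": n_a,
                "n_within_pairs": n_w,
            }
        )
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col.startswith("pct_"):
            df[col] = df[col].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# serialization

_PAIR_COLUMNS = [
    "study_id",
    "species_id",
    "pop_a",
    "pop_b",
    "relation",
    "place",
    "category",
]


def pair_scores_frame(pairs: Sequence[PairScore]) -> pd.DataFrame:
    rows = [
        {
            "study_id": p.study_id,
            "species_id": p.species_id,
            "pop_a": p.pop_a,
            "pop_b": p.pop_b,
            "relation": p.relation,
            "place": "|".join(p.place) if p.relation == "across" else p.place,
            "category": p.category.value,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def write_pair_scores(pairs: Sequence[PairScore], path) -> Path:
    """Write scored pairs to CSV; re-reading reproduces the tallies exactly."""
    path = Path(path)
    pair_scores_frame(pairs).to_csv(path, index=False)
    return path


def read_pair_scores(path) -> List[PairScore]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair-score table missing column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        if rec["relation"] == "across":
            place: Union[BoundaryId, str] = make_boundary(*rec["place"].split("|"))
        else:
            place = rec["place"]
        out.append(
            PairScore(
                study_id=rec["study_id"],
                species_id=rec["species_id"],
                pop_a=rec["pop_a"],
                pop_b=rec["pop_b"],
                relation=rec["relation"],
                place=place,
                category=Category(rec["category"]),
            )
        )
    return out


def tally_frames(t: ScoreTally) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Boundary and CoE tally tables for export."""
    b_rows = [
        {
            "boundary": "|".join(b),
            "break": c[Category.BREAK],
            "uncertain": c[Category.UNCERTAIN],
            "homogeneity": c[Category.HOMOGENEITY],
        }
        for b, c in sorted(t.per_boundary.items())
    ]
    c_rows = [
        {
            "coe": coe,
            "break": c[Category.BREAK],
            "homogeneity": c[Category.HOMOGENEITY],
        }
        for coe, c in sorted(t.per_coe.items())
    ]
    return (
        pd.DataFrame(b_rows, columns=["boundary", "break", "uncertain", "homogeneity"]),
        pd.DataFrame(c_rows, columns=["coe", "break", "homogeneity"]),
    )
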
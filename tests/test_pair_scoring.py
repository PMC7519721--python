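"""Pair enumeration, break/homogeneity/uncertain scoring and tallies."""

import itertools
import random

import numpy as np
import pytest

from coebreaks import StudySet
from coebreaks.assignment import Status, assign_all
from coebreaks.coe_map import coe_adjacency, make_boundary
from coebreaks.pair_scoring import (
    Category,
    enumerate_across_pairs,
    enumerate_within_pairs,
    read_pair_scores,
    score_all,
    score_pair,
    study_summary,
    tally,
    write_pair_scores,
)
from coebreaks.qds_grid import QDSCode

from conftest import cell, centroid, pop


def interior(coe):
    """An interior cell of each centre of the conftest three-CoE map."""
    return {"X": cell(132, 72), "Y": cell(133, 75), "Z": cell(136, 72)}[coe]


def make_pops(spec):
    """spec: list of (study, species, pid, coe, group) placed in interiors."""
    return [
        pop(st, sp, pid, centroid(interior(coe)), grp) for st, sp, pid, coe, grp in spec
    ]


class TestEnumeration:
    def test_k_times_m_across_pairs(self, three_coe_map):
        k, m = 3, 4
        pops = make_pops(
            [("S1", "sp", f"x{i}", "X", "gx") for i in range(k)]
            + [("S1", "sp", f"y{i}", "Y", "gy") for i in range(m)]
        )
        asn = assign_all(StudySet(pops), three_coe_map)
        pairs = enumerate_across_pairs(asn, coe_adjacency(three_coe_map))
        assert len(pairs) == k * m

    def test_non_adjacent_coes_never_pair(self, three_coe_map):
        pops = make_pops(
            [("S1", "sp", "x1", "X", "g1"), ("S1", "sp", "z1", "Z", "g2")]
        )
        asn = assign_all(StudySet(pops), three_coe_map)
        assert enumerate_across_pairs(asn, coe_adjacency(three_coe_map)) == []

    def test_different_species_or_studies_never_pair(self, three_coe_map):
        pops = make_pops(
            [
                ("S1", "spA", "x1", "X", "g1"),
                ("S1", "spB", "y1", "Y", "g2"),
                ("S2", "spA", "y2", "Y", "g3"),
            ]
        )
        asn = assign_all(StudySet(pops), three_coe_map)
        assert enumerate_across_pairs(asn, coe_adjacency(three_coe_map)) == []

    @pytest.mark.parametrize("n, expected", [(1, 0), (3, 3), (6, 15)])
    def test_within_pairs_are_combinations(self, three_coe_map, n, expected):
        pops = make_pops([("S1", "sp", f"p{i}", "Z", f"g{i}") for i in range(n)])
        asn = assign_all(StudySet(pops), three_coe_map)
        assert len(enumerate_within_pairs(asn)) == expected

    def test_uncertain_populations_excluded_from_within_by_default(self, two_coe_map):
        pops = [
            pop("S1", "sp", "b1", centroid(cell(132, 73)), "g1"),  # boundary cell
            pop("S1", "sp", "i1", centroid(cell(132, 72)), "g1"),
            pop("S1", "sp", "i2", centroid(cell(133, 72)), "g2"),
        ]
        asn = assign_all(StudySet(pops), two_coe_map, buffer_cells=1)
        assert len(enumerate_within_pairs(asn)) == 1
        assert len(enumerate_within_pairs(asn, include_uncertain=True)) == 3


class TestScoring:
    def score_single(self, m, pops, buffer_cells=0):
        asn = assign_all(StudySet(pops), m, buffer_cells=buffer_cells)
        return score_all(asn, coe_adjacency(m))

    def test_discordant_assigned_pair_is_break(self, three_coe_map):
        scores = self.score_single(
            three_coe_map,
            make_pops([("S1", "sp", "a", "X", "cladeA"), ("S1", "sp", "b", "Y", "cladeB")]),
        )
        assert [s.category for s in scores] == [Category.BREAK]

    def test_concordant_assigned_pair_is_homogeneity(self, three_coe_map):
        scores = self.score_single(
            three_coe_map,
            make_pops([("S1", "sp", "a", "X", "cladeA"), ("S1", "sp", "b", "Y", "cladeA")]),
        )
        assert [s.category for s in scores] == [Category.HOMOGENEITY]

    def test_non_unique_uncertain_endpoint_scores_uncertain(self, two_coe_map):
        # u sits in a boundary cell of Y and shares its group with x2 in X,
        # so it is not genetically unique and the pair is a non-break
        pops = [
            pop("S1", "sp", "a", centroid(cell(132, 72)), "cladeA"),
            pop("S1", "sp", "u", centroid(cell(132, 74)), "cladeB"),
            pop("S1", "sp", "x2", centroid(cell(133, 72)), "cladeB"),
        ]
        scores = self.score_single(two_coe_map, pops, buffer_cells=1)
        by_pair = {(s.pop_a, s.pop_b): s.category for s in scores if s.relation == "across"}
        assert by_pair[("a", "u")] == Category.UNCERTAIN
        # every across pair of a non-unique uncertain population is a non-break
        assert by_pair[("u", "x2")] == Category.UNCERTAIN

    def test_unique_uncertain_endpoint_stays_break_capable(self, two_coe_map):
        pops = [
            pop("S1", "sp", "a", centroid(cell(132, 72)), "cladeA"),
            pop("S1", "sp", "u", centroid(cell(132, 74)), "cladeB"),
        ]
        scores = self.score_single(two_coe_map, pops, buffer_cells=1)
        assert [s.category for s in scores] == [Category.BREAK]


class TestTally:
    def test_empty_input_gives_zero_tally(self):
        t = tally([])
        assert t.across_total == 0 and t.within_total == 0

    def test_permutation_invariance_and_round_trip(self, three_coe_map, tmp_path):
        rng = random.Random(5)
        pops = make_pops(
            [
                ("S1", "sp", f"x{i}", rng.choice(["X", "Y", "Z"]), f"g{rng.randrange(3)}")
                for i in range(20)
            ]
        )
        asn = assign_all(StudySet(pops), three_coe_map)
        scores = score_all(asn, coe_adjacency(three_coe_map))
        shuffled = scores[:]
        rng.shuffle(shuffled)
        t1, t2 = tally(scores), tally(shuffled)
        assert t1.per_boundary == t2.per_boundary and t1.per_coe == t2.per_coe

        path = write_pair_scores(scores, tmp_path / "pairs.csv")
        t3 = tally(read_pair_scores(path))
        assert t3.per_boundary == t1.per_boundary and t3.per_coe == t1.per_coe

    def test_conservation_of_counts(self, three_coe_map):
        pops = make_pops(
            [("S1", "sp", f"x{i}", c, f"g{i % 2}") for i, c in enumerate("XXYYZZZ")]
        )
        asn = assign_all(StudySet(pops), three_coe_map)
        t = tally(score_all(asn, coe_adjacency(three_coe_map)))
        assert sum(sum(c.values()) for c in t.per_boundary.values()) == t.across_total
        assert sum(sum(c.values()) for c in t.per_coe.values()) == t.within_total


class TestBruteForceOracle:
    """Full pipeline tally equals a nested-loop reference with no indexing."""

    @staticmethod
    def brute_force(pops, m, adjacency, assignments):
        status = {a.population.key: a for a in assignments}
        across, within = [], []
        for p, q in itertools.combinations(pops, 2):
            if p.study_id != q.study_id or p.species_id != q.species_id:
                continue
            ap, aq = status[p.key], status[q.key]
            if ap.status is Status.OUTSIDE or aq.status is Status.OUTSIDE:
                continue
            if ap.coe_id == aq.coe_id:
                if ap.status is Status.ASSIGNED and aq.status is Status.ASSIGNED:
                    within.append(
                        Category.BREAK if p.genetic_group != q.genetic_group else Category.HOMOGENEITY
                    )
            elif make_boundary(ap.coe_id, aq.coe_id) in adjacency:
                if (ap.status is Status.UNCERTAIN and not ap.unique_flag) or (
                    aq.status is Status.UNCERTAIN and not aq.unique_flag
                ):
                    across.append(Category.UNCERTAIN)
                else:
                    across.append(
                        Category.BREAK if p.genetic_group != q.genetic_group else Category.HOMOGENEITY
                    )
        return across, within

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_fixture_agreement(self, three_coe_map, seed):
        rng = random.Random(seed)
        cells_by_coe = {
            c: sorted(three_coe_map.cells_of(c), key=lambda x: x.text)
            for c in three_coe_map.coe_ids
        }
        pops = []
        for i in range(rng.randrange(20, 50)):
            coe = rng.choice(sorted(three_coe_map.coe_ids))
            c = rng.choice(cells_by_coe[coe])
            pops.append(
                pop(
                    f"S{rng.randrange(3)}",
                    f"sp{rng.randrange(2)}",
                    f"P{i}",
                    centroid(c),
                    f"g{rng.randrange(4)}",
                )
            )
        s = StudySet(pops)
        asn = assign_all(s, three_coe_map, buffer_cells=1)
        adjacency = coe_adjacency(three_coe_map)
        t = tally(score_all(asn, adjacency))
        across, within = self.brute_force(pops, three_coe_map, adjacency, asn)
        assert t.across_total == len(across) and t.within_total == len(within)
        for cat in Category:
            assert t.across[cat] == across.count(cat)
        for cat in (Category.BREAK, Category.HOMOGENEITY):
            assert t.within[cat] == within.count(cat)


class TestStudySummary:
    def test_all_break_study_gives_100_0_0(self, three_coe_map):
        pops = make_pops(
            [("A", "sp", "a1", "X", "g1"), ("A", "sp", "a2", "Y", "g2"), ("A", "sp", "a3", "Y", "g3")]
        )
        asn = assign_all(StudySet(pops), three_coe_map)
        pairs = score_all(asn, coe_adjacency(three_coe_map))
        df = study_summary(pairs, StudySet(pops)).set_index("study_id")
        assert df.loc["A", "pct_break_across"] == 100
        assert df.loc["A", "pct_uncertain"] == 0
        assert df.loc["A", "pct_homogeneity_across"] == 0

    def test_na_not_zero_when_no_pairs(self, three_coe_map):
        import pandas as pd

        pops = make_pops([("Lone", "sp", "p1", "Z", "g1")])
        df = study_summary([], StudySet(pops)).set_index("study_id")
        assert pd.isna(df.loc["Lone", "pct_break_across"])
        assert pd.isna(df.loc["Lone", "pct_break_within"])

    def test_integer_percentages_round_half_up(self, three_coe_map):
        # 1 break among 40 across pairs is 2.5%: half-up rounding prints 3
        spec = [("C", "sp", "x0", "X", "g_other")]
        spec += [("C", "sp", f"y{i}", "Y", "g_other" if i else "g_break") for i in range(40)]
        pops = make_pops(spec)
        asn = assign_all(StudySet(pops), three_coe_map)
        pairs = score_all(asn, coe_adjacency(three_coe_map))
        across = [p for p in pairs if p.relation == "across"]
        assert len(across) == 40
        assert sum(p.category is Category.BREAK for p in across) == 1
        df = study_summary(pairs, StudySet(pops)).set_index("study_id")
        assert df.loc["C", "pct_break_across"] == 3
        assert df.loc["C", "pct_homogeneity_across"] == 98
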
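"""Synthetic map and corpus generator: invariants and degenerate limits."""

import numpy as np
import pytest

from coebreaks import PipelineConfig, StudySet, run_analysis
from coebreaks.assignment import assign_all
from coebreaks.coe_map import coe_adjacency
from coebreaks.pair_scoring import Category, enumerate_across_pairs, enumerate_within_pairs
from coebreaks.qds_grid import qds_neighbors
from coebreaks.synthetic_data import (
    SyntheticConfig,
    make_coe_map,
    make_studies,
    paper_scale_fixture,
)

SMALL = dict(lat_min=-34.0, lat_max=-32.0, lon_min=18.0, lon_max=20.0)


def flood_fill_connected(cells):
    cells = set(cells)
    seen = {next(iter(cells))}
    stack = list(seen)
    while stack:
        c = stack.pop()
        for nb in qds_neighbors(c, "rook"):
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == cells


class TestMakeCoEMap:
    def test_partition_and_connectivity(self):
        cfg = SyntheticConfig(n_coes=5, seed=4, **SMALL)
        m = make_coe_map(cfg)
        assert m.coe_ids == {f"C{i:02d}" for i in range(1, 6)}
        assert sum(len(m.cells_of(c)) for c in m.coe_ids) == len(m.cells)
        for coe in m.coe_ids:
            assert flood_fill_connected(m.cells_of(coe))

    def test_two_coe_partition_covers_window(self):
        cfg = SyntheticConfig(
            n_coes=2, seed=0, lat_min=-33.0, lat_max=-32.0, lon_min=19.0, lon_max=20.0
        )
        m = make_coe_map(cfg)
        assert len(m.cells) == 16
        assert len(m.coe_ids) == 2

    def test_deterministic_for_fixed_seed(self):
        cfg = SyntheticConfig(n_coes=5, seed=99, **SMALL)
        assert make_coe_map(cfg).cells == make_coe_map(cfg).cells

    def test_too_many_coes_rejected(self):
        cfg = SyntheticConfig(
            n_coes=20, seed=0, lat_min=-32.5, lat_max=-32.0, lon_min=19.0, lon_max=19.5
        )
        with pytest.raises(ValueError, match="exceeds"):
            make_coe_map(cfg)

    @pytest.mark.parametrize("bad", [dict(p_div_across=1.5), dict(n_coes=1), dict(f_boundary=-0.1)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticConfig(**bad)


class TestMakeStudies:
    def run_tally(self, cfg):
        m = make_coe_map(cfg)
        s = make_studies(cfg, m)
        res = run_analysis(s, m, PipelineConfig(seed=1, replicates=200, buffer_cells=0))
        return res.tally

    def test_degenerate_full_divergence(self):
        t = self.run_tally(
            SyntheticConfig(n_coes=4, n_studies=6, p_div_across=1.0, p_div_within=0.0, seed=2, **SMALL)
        )
        assert t.across[Category.HOMOGENEITY] == 0 and t.across[Category.UNCERTAIN] == 0
        assert t.across[Category.BREAK] > 0
        assert t.within[Category.BREAK] == 0

    def test_degenerate_no_divergence(self):
        t = self.run_tally(
            SyntheticConfig(n_coes=4, n_studies=6, p_div_across=0.0, p_div_within=0.0, seed=2, **SMALL)
        )
        assert t.across[Category.BREAK] == 0 and t.within[Category.BREAK] == 0

    def test_determinism_and_studyset_invariants(self):
        cfg = SyntheticConfig(n_coes=4, n_studies=5, seed=8, **SMALL)
        m = make_coe_map(cfg)
        a, b = make_studies(cfg, m), make_studies(cfg, m)
        assert a.populations == b.populations
        assert all(len(v) >= 1 for v in a.studies.values())

    def test_realized_rates_match_closed_forms(self):
        """At scale, the observed across-break fraction matches
        1 - (1-d)(1-p_w)^2 with d the realized latent discordance, and the
        within-break fraction matches 1 - (1-p_w)^2."""
        p_w = 0.15
        cfg = SyntheticConfig(n_studies=120, p_div_across=0.9, p_div_within=p_w, seed=17)
        m = make_coe_map(cfg)
        s = make_studies(cfg, m)
        asn = assign_all(s, m, 0)
        across = enumerate_across_pairs(asn, coe_adjacency(m))
        within = enumerate_within_pairs(asn)
        obs_across = np.mean(
            [a.population.genetic_group != b.population.genetic_group for a, b in across]
        )
        d = np.mean(
            [a.population.meta["latent_group"] != b.population.meta["latent_group"] for a, b in across]
        )
        expected_across = 1 - (1 - d) * (1 - p_w) ** 2
        # pairs share populations, so allow generous sampling error
        assert obs_across == pytest.approx(expected_across, abs=0.03)
        obs_within = np.mean(
            [a.population.genetic_group != b.population.genetic_group for a, b in within]
        )
        assert obs_within == pytest.approx(1 - (1 - p_w) ** 2, abs=0.05)


class TestPaperScaleFixture:
    def test_headline_tallies(self):
        m, s = paper_scale_fixture()
        res = run_analysis(s, m, PipelineConfig(seed=0, replicates=100, buffer_cells=1))
        t = res.tally
        assert (
            t.across[Category.BREAK],
            t.across[Category.UNCERTAIN],
            t.across[Category.HOMOGENEITY],
        ) == (506, 8, 26)
        assert (t.within[Category.HOMOGENEITY], t.within[Category.BREAK]) == (525, 94)

    def test_end_to_end_determinism(self):
        m1, s1 = paper_scale_fixture()
        m2, s2 = paper_scale_fixture()
        assert m1.cells == m2.cells and s1.populations == s2.populations
        r1 = run_analysis(s1, m1, PipelineConfig(seed=5, replicates=300))
        r2 = run_analysis(s2, m2, PipelineConfig(seed=5, replicates=300))
        assert r1.gof_across == r2.gof_across and r1.gof_within == r2.gof_within
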
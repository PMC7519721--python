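# coebreaks

Do intraspecific genetic lineages of Cape Floristic Region (CFR) plants
respect the boundaries of Centres of Endemism (CoEs)?  `coebreaks` is a
pipeline for testing the spatial concordance of phylogeographic breaks
with a biogeographic regionalization mapped on the southern-African
Quarter Degree Square (QDS) grid.  It is aimed at comparative
phylogeographers and conservation planners who have (a) population
tables from published studies, each population labelled with a genetic
group (clade or sub-clade membership from the source study's phylogeny),
and (b) a CoE map as QDS-cell memberships or polygons.

## The analysis

1. **Geocoding.** Each population is dropped onto the 0.25° × 0.25° QDS
   grid (codes like `3318CD`; half-open cells, so edge localities belong
   to exactly one cell) and assigned to the CoE of its cell, or marked
   OUTSIDE if the cell belongs to no centre.
2. **Uncertainty.** Populations near a boundary between centres are
   flagged UNCERTAIN.  Unless such a population's genetic group is unique
   among all populations of either candidate centre (within its study),
   its across-boundary pairs are scored as non-breaks — a deliberately
   null-promoting rule.
3. **Pair scoring.** All same-study, same-species population pairs
   straddling an adjacent-CoE boundary are scored BREAK (labels differ),
   HOMOGENEITY (labels agree) or UNCERTAIN; pairs within a single centre
   are scored BREAK or HOMOGENEITY.
4. **Testing.** Category tallies are tested against equal category
   probabilities with Pearson's X² = Σ(Oᵢ−Eᵢ)²/Eᵢ, Eᵢ = N/k, using a
   Monte-Carlo simulated p-value: B multinomial(N, 1/k) replicates and
   p = (1 + #{T_b ≥ T_obs}) / (B + 1), with B = 10,000 by default.

A synthetic-data module generates CoE mosaics (seeded region growing)
and multi-study corpora with controllable across-boundary divergence,
within-centre divergence and boundary-cell placement, so the entire
pipeline is testable without any external data.

## Worked example

```python
import coebreaks as cb

coe_map, studies = cb.paper_scale_fixture()   # deterministic synthetic corpus
res = cb.run_analysis(studies, coe_map,
                      cb.PipelineConfig(seed=1, replicates=10_000))
t = res.tally
print(t.across_total, t.within_total)          # 540 619
print(f"{res.across_break_pct:.1f} {res.within_break_pct:.1f}")  # 93.7 15.2
print(f"{res.gof_across.statistic:.1f} {res.gof_across.p_mc:.2g}")
print(f"{res.gof_within.statistic:.1f} {res.gof_within.p_mc:.2g}")
```

prints

```
540 619
93.7 15.2
886.5 0.0001
300.1 0.0001
```

Of 540 population pairs compared across adjacent-CoE boundaries, 93.7%
show a phylogeographic break (X² = 886.5 against equal thirds of break /
uncertain / homogeneity, Monte-Carlo p = 1/10001), while only 15.2% of
619 within-centre pairs are divergent (X² = 300.1 against equal halves):
breaks concentrate on centre boundaries far beyond chance.

The same analysis runs from the shell:

```sh
coebreaks simulate -o data --seed 3          # synthetic corpus
coebreaks run -p data/populations.csv -m data/coe_cells.csv -o out --seed 3
cat out/report.md
```

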
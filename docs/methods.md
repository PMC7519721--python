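# Methods

## Spatial substrate

Centres of Endemism are represented as memberships of Quarter Degree
Square (QDS) cells, the 0.25° × 0.25° unit of the South African mapping
grid.  A code such as `3318CD` names the one-degree cell (degrees south,
degrees east of the NW corner) plus two quadrant letters (A=NW, B=NE,
C=SW, D=SE at each level); this is the standard national convention, the
only one under which Cape Town encodes to 3318CD.  Cells are half-open
toward increasing south and east, so a locality on a shared edge belongs
to exactly one cell and assignment is deterministic.  Input coordinates
are signed decimal degrees (WGS84); no projection is ever applied, and no
degree-minute-second parsing is attempted.

Two centres are adjacent — share a tested boundary — when a cell of one
neighbours a cell of the other.  The default neighbourhood is rook
(shared edge): a boundary between regions is naturally a shared edge, and
corner-touching centres share no boundary line.  Queen adjacency is
available for sensitivity analysis.  Polygon CoE input is rasterized by
cell-centroid containment, which makes the polygon and cell-table
representations provably interchangeable (tested).  Cells outside every
centre are allowed; populations falling there are excluded from all
pairing with a logged warning, since no membership exists to test.

## Assignment and the uncertainty rule

Each population takes the CoE of its cell.  Populations near a boundary
are flagged UNCERTAIN under either of two operationalizations, because
"near" has no single natural definition at mapping scale:

* `buffer_cells = 1` (default): the population's cell touches another
  centre.  This is the most conservative reading at quarter-degree scale.
* `buffer_km = d`: the population lies within great-circle distance *d*
  of a cell edge shared with another centre.  Distance to a constant-
  latitude or constant-longitude edge segment is computed by clamping the
  free coordinate and applying the haversine formula — exact for meridian
  edges and accurate to well under 1% over 0.25° parallel edges.

An UNCERTAIN population whose genetic group also occurs in another
population (same study) assigned to or uncertain-within any candidate
centre is *not* genetically unique; all its across-boundary pairs score
UNCERTAIN, which is counted as a non-break.  Genetically unique
populations remain break-capable.  Uniqueness is never compared across
studies — group labels from different studies are not commensurable.
This rule only ever converts breaks into non-breaks (a property test
asserts the monotonicity), biasing the analysis *against* detecting
boundary concordance.

With both buffers zero the pipeline reduces to a plain point-in-CoE
overlay.  Whether uncertain populations should also enter within-centre
pairing is genuinely open; the default excludes them (their membership is
ambiguous by construction), with `include_uncertain_within` to flip.

## Pair scoring

Pairs are enumerated within species within study only; multi-species
studies contribute pairs per species.  Genetic groups are categorical
labels: no distance thresholds or topology tests are applied, because the
upstream studies already summarize their phylogenies as clade membership.
Pairs between non-adjacent centres are discarded, not scored.  Per-study
summary percentages are rounded half-up to integers; corpus-level
percentages are printed with one decimal.

## Goodness-of-fit test

Observed category counts O (k = 3 across: break / uncertain /
homogeneity; k = 2 within: break / homogeneity) are tested against equal
probabilities p = 1/k with Pearson's X².  The three-category across
structure is adopted because it is the unique reading under which the
recomputed statistics match the published values (886.5 and 300.1 from
the tallies 506/8/26 and 94/525).  The null distribution is simulated: B
multinomial(N, p) replicates (default B = 10,000) and the add-one
estimator p = (1 + #{T_b ≥ T_obs}) / (B + 1), which is never zero and has
P(p ≤ α) ≤ α under the null.  An exact p-value by full multinomial
enumeration is provided for N ≤ 20 and k ≤ 3 as an independent oracle;
tests require MC/exact agreement within 4 Monte-Carlo standard errors and
a type-I error of 0.05 within binomial error over 2,000 simulated null
tallies (B = 999 per tally, N = 540 — the corpus-scale pair count).
Asymptotic χ² p-values are deliberately not the primary output; the
statistic itself is cross-checked against `scipy.stats.chisquare`.

## Synthetic data

The generator emulates the structure of a multi-study corpus:

* **Map**: a window of the grid is partitioned into `n_coes` contiguous
  centres by seeded multi-source region growing (round-robin frontier
  expansion, ties broken by centre order), guaranteeing rook-connected
  centres and determinism.
* **Genetic structure**: per (study, species) a latent group label per
  centre is sampled by walking a BFS spanning tree of the centre
  adjacency graph, flipping to a globally fresh label across each tree
  edge with probability `p_div_across`.  A spanning tree (not the full
  cyclic graph) gives a well-defined joint distribution; the price is
  that two non-tree-adjacent centres agree only if no flip occurred on
  the tree path between them, so realized adjacent-pair discordance
  *exceeds* the nominal parameter.  Recovery tests therefore measure the
  realized latent discordance d from the generator's own labels and
  check the pipeline's observed across-break rate against
  1 − (1 − d)(1 − p_div_within)².
* **Placement**: populations are placed uniformly in their centre's
  cells, a fraction `f_boundary` forced into boundary cells; coordinates
  are sampled in the interior 90% of the cell so the half-open edge
  convention is never exercised by chance.
* **Within-centre divergence**: with probability `p_div_within` a
  population's label is replaced by a globally unique private label,
  mirroring how source studies report divergent subclades; the pair-level
  within-break expectation is 1 − (1 − p_div_within)².

Defaults mirror a corpus of 12 studies, 1–3 species each, 3–12
populations per species (~180 populations) over 12 centres on a
3.5° × 8° window, with `p_div_across = 0.94` and `p_div_within = 0.08`
(pair-level ≈ 0.15) — the regime in which across-boundary divergence is
common and within-centre divergence rare — and `f_boundary = 0.1`.

What the generator does *not* emulate: realistic species ranges, spatial
autocorrelation of sampling, coalescent noise in clade assignment, or any
specific study's design.  Passing tests on synthetic data therefore
demonstrate the correctness of the bookkeeping and the statistics, not
the biological conclusion for any real corpus.

`paper_scale_fixture()` is a separate deterministic construction — a
synthetic stand-in for the deposited raw scoring table, which requires an
external download — whose pair totals (540 across, 619 within) and
category counts (506/8/26 and 94/525) are injected by construction: e.g.
the eight uncertain pairs come from populations placed in boundary cells
sharing a non-unique label.  It regression-tests the full pipeline
against the published aggregates; it carries no information about
per-boundary structure, which is why per-boundary counts are covered by
property-based tests instead.

## Numerical and problem-size choices

* Monte-Carlo replicates are drawn from a single `numpy` generator seeded
  from the run configuration; the within-test seed is offset by one so
  the two tests use independent streams.  Results are bit-reproducible.
* A replicate statistic counts as ≥ T_obs with 1e−9 absolute slack to
  guard against floating-point ties.
* Type-I calibration uses 2,000 simulated data sets with B = 999; the
  parameter-recovery grid runs (p_div_across, p_div_within) ∈
  {0.2, 0.5, 0.8}² at 60 replicate data sets per setting on a 2° × 2°,
  5-centre window — sizes chosen to keep the full suite in the
  tens-of-seconds range while leaving assertion bounds at 3–4 standard
  errors of the relevant Monte-Carlo estimate.

## Known limitations

* Which hierarchical level (centres vs sub-centres) a given map's
  boundaries represent is the caller's choice; the pipeline analyses
  whatever ids the input table provides (an optional parent mapping is
  carried through for bookkeeping).
* Studies reporting both nuclear and chloroplast groupings must be split
  into one study per marker system by the data preparer.
* Whether between-species pairs should ever be formed in multi-species
  studies is not decidable from published summaries; within-species
  pairing is the implemented (and conservative) choice.
* The km-distance uncertainty buffer measures distance to the shared
  edge of the population's own cell only, not to the nearest boundary
  anywhere on the map; at quarter-degree scale these coincide for all
  but pathological geometries.
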
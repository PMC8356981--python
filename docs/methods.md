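# Methods

`sbncomm` re-creates, on synthetic test–retest cohorts, a complete workflow
for asking how *repeatable* community detection and hub identification are
in weighted structural brain networks (SBNs), across choices of
graph-construction scheme and community-detection algorithm.  This note
documents the models, the numerical choices, and what the synthetic
experiments do and do not establish.

## The analysis problem

An SBN is a symmetric, non-negative, zero-diagonal matrix whose entries
summarise white-matter connectivity between atlas regions.  A cohort of N
participants is scanned twice; if a partition of an SBN into communities is
to mean anything biologically, the partition obtained from scan 1 should
agree with the partition from scan 2.  The workflow therefore evaluates
every pair (construction scheme, detection algorithm) on four axes:

1. **between-scan agreement** of community affiliations, quantified by
   normalised mutual information (NMI), with a resampling p-value;
2. **partition quality** against degree- and strength-preserving surrogate
   graphs (a permutation test on the quality index Q);
3. **consensus similarity**: how close each individual partition is to the
   cohort-level representative partition extracted from the co-clustering
   consensus matrix;
4. **nodal-metric reliability**: intra-class correlation of the
   participation coefficient P_i and within-module z-score z_i between
   sessions, plus the cross-cohort agreement of connector/provincial hub
   roles.

Pairs pass a selection gate (group NMI > 0.9, NMI p < .05, quality p < .05)
and the survivors are ranked by consensus similarity.  A two-way fixed-
effects ANOVA over the scheme × algorithm grid attributes variance in any
of these responses to the two factors and their interaction.

## Graph construction

**Edge metrics.** Nine per-edge metrics (FA, MD, RD, NS, PS, SLD, TV, TL,
ED) share one edge support.  MD and RD are diffusivities — large values
mean *weaker* connections — and are inverted (1 − min-max-rescaled value)
wherever metrics are combined.

**OMST filtering.**  The orthogonal-minimal-spanning-tree filter converts
weights to distances d = 1/w (w = 0 is "no edge", never distance 0),
extracts the minimum spanning tree, removes its edges, and repeats on the
remainder while it still spans the graph (at most `max_trees` = 10 rounds).
After each round the accumulated union is scored by the global
cost-efficiency J = E_glob − cost, where E_glob is the mean inverse
shortest-path length and cost is the fraction of total input weight
retained (dimensionless, so J is scale-invariant).  The union with maximal
J is returned together with the full (cost, J) curve so the selection can
be audited.  At desk scale (40-node cohorts with ~150 edges) a single tree
already captures a quarter of the total weight, so J typically peaks at
one or two trees and the filtered graphs are tree-like; on dense 90-node
empirical matrices the same rule keeps many more trees.  Consequences of
tree-like outputs are flagged below where they matter.

**Multi-metric integration.**  Selected metrics are min-max rescaled over
their edges and combined linearly with coefficients proportional to each
metric's mean dissimilarity (1 − |Pearson r| over shared edges) from the
other selected metrics, normalised to sum to one — redundant metrics are
down-weighted, complementary ones up-weighted.  When all pairwise
dissimilarities vanish (identical metrics) the weights fall back to
uniform.  The exact functional form of the original integration algorithm
is not published with formulas; this dissimilarity-proportional linear
combination is this package's declared realisation of that idea.

**Schemes.**  A: OMST on NS.  B: OMST on the NS+FA integration.  C: OMST on
all nine metrics.  D: keep the highest-NS edges at a matched sparsity.
E/F: D's topology re-weighted with FA/MD.  G: highest-FA edges re-weighted
with NS.  The sparsity anchor for D–G is either given or, with `"auto"`,
taken from scheme C's output on the same stack (the natural anchor would
be whichever OMST scheme proves most reproducible; C, the richest
integration, is the declared default).  All outputs are max-normalised to 1.  Thresholding
tie-breaks are lexicographic on (i, j), so every scheme is a deterministic
function of its input.

## Community detection

Five hard quality criteria share one greedy optimiser:

| criterion | objective | scale (default) |
|---|---|---|
| `newman` | Newman–Girvan modularity on weighted degrees | 1 |
| `rb` | Reichardt–Bornholdt: γ scales the degree-product null | γ = 1 |
| `rn` | Ronhovde–Nussinov Potts: γ penalises absent intra-community pairs | γ = 0.25 |
| `afg` | Arenas–Fernandez–Gomez: Newman Q with uniform self-loops r | r = 0 |
| `stability` | linearised Markov stability at time t | t = 1 |

Each default reduces to (or sits near) Newman modularity, matching
single-partition-per-algorithm usage; scales are exposed for resolution
scans.  The rn resolution deserves a note: γ trades edge weight against a
penalty per missing intra-community pair, so its natural scale depends on
the edge-weight distribution.  With the generator's uniform-[0.5, 1]
weights, γ ≥ 0.5 makes the criterion prefer splitting an extra
tightly-knit subgroup out of a planted module (verifiably: the optimum of
the objective is then finer than the planted partition), while γ in
[0.2, 0.3] recovers planted mesoscale structure essentially always;
γ = 0.25 is the package default.  Self-loops in `afg` follow the standard
weighted-graph convention (a loop of weight r adds 2r to its node's
strength); the implementation is checked against networkx modularity on
graphs with explicit self-loops.

The optimiser is a Louvain-style two-phase greedy scheme — seeded sweeps of
single-node moves to the best neighbouring community (ties to the lowest
community id), then aggregation of communities into supernodes, repeated
until stable — followed by a refinement stage at node level that
alternates greedy sweeps with deterministic Kernighan–Lin passes (each
node tentatively moved once, downhill moves allowed, best prefix kept).
The KL stage exists because pure Louvain is blind to improvements that
need two coordinated moves (e.g. the balanced split of a path graph); with
it, the optimiser reproduces the exhaustive-enumeration optimum on every
≤ 8-node fixture in the test suite, for all five criteria.  The all-in-one
and all-singleton partitions are always evaluated as baselines and the
returned partition never scores below either.  With a fixed seed the
result is deterministic.

**Soft covers** come from link communities: edges are items, the
similarity of two edges sharing a node is the Jaccard index of the
inclusive neighbourhoods of their far endpoints, single-linkage clustering
builds the dendrogram, and the cut maximising partition density is
projected back onto nodes (a node inherits every community of its
incident edges, hence possibly several).  This is the representative
soft method used to exercise the cover-comparison path; its construction
is deterministic.

## Partition similarity

Hard-partition NMI is 2I/(H₁+H₂) from the label contingency table
(arithmetic normalisation; `max` and other variants are available as an
option).  The degenerate case of two single-community partitions is
defined as 1 (identical information, all of it absent).  Cover agreement
uses the Lancichinetti–Fortunato–Kertész normalised conditional-entropy
construction over best-matching binary membership vectors; it coincides
with hard NMI to within a few hundredths for similar partitions but is a
different normalisation, and against a trivial one-community cover it
returns 1/2 rather than 0 — both facts are asserted in tests rather than
hidden.

Between-scan significance: the node-to-label assignment of the second
partition is permuted (preserving its community-size profile, destroying
node correspondence); p = (1 + #{null ≥ observed}) / (B + 1).  This
add-one convention never returns 0 and gives the test exact size on the
discrete null grid when rejection is declared at p ≤ α — the convention
used throughout the package's calibration checks.  Whether the original
study resampled subjects or node labels is not recoverable from the text;
node-label permutation is the declared choice, and a subject-level
variant would be a straightforward extension of
`group_agreement_pvalue`.

## Null models

Surrogates preserve the degree sequence exactly (double-edge swaps with a
connectivity check and revert; swap attempts = `n_swaps_per_edge` × |E|)
and node strengths to a declared tolerance: the original weight multiset
is placed on the rewired topology and symmetric Sinkhorn scaling
(W_ij ← W_ij √(f_i f_j), f = target/current strength) is iterated to
convergence.  Weight placement is a *random shuffle* by default.  The
alternative `weight_init="rank"` (largest weights onto the largest
strength-product pairs) converges faster but couples weights to strengths
more smoothly than an i.i.d.-weighted graph would, which biases the
quality permutation test anti-conservative (measured 17% null rejection at
α = .05 versus 6% with shuffling); shuffling keeps the surrogate ensemble
exchangeable with an equally random original.  On tree-like topologies the
strength system may admit no positive solution; the adjustment then warns
and records the achieved error (`.strength_error`) instead of failing.  On
the 40-node planted fixture the strengths match to ~10⁻⁸.

## Consensus clustering

The consensus matrix counts co-assignments of node pairs over all
subjects × sessions partitions and divides by the number of partitions;
the diagonal is reported as 1 and zeroed before filtering (self-loops mean
nothing to spanning trees).  One OMST + detection pass replaces iterative
threshold-and-recluster loops.  A perfectly consistent cohort produces a
block-diagonal probability matrix whose blocks are mutually disconnected;
the implementation therefore filters and partitions each connected
component separately and concatenates the labels, which makes the
procedure exactly idempotent (consensus over copies of one partition
returns that partition).  The detection algorithm applied to the consensus
matrix defaults to the one whose partitions built it.

## Hubs and reliability

P_i = 1 − Σ_s (κ_is/k_i)² and z_i standardise *strengths* (weighted
degrees), consistent with weighted SBNs; modules with zero within-module
strength variance assign z = 0, isolated nodes get P = 0.  Hubs are nodes
with z ≥ 2.5; connectors additionally have P > 0.30 (the classic
cartographic thresholds, exposed as configuration since published
role taxonomies vary).  The agreement index of a role is the per-node
fraction of subjects showing that role in both sessions; only index 1
marks a cohort-consistent hub.

ICC uses the two-way random-effects absolute-agreement single-measurement
model, ICC(2,1) = (MS_R − MS_E)/(MS_R + MS_E + 2(MS_C − MS_E)/n); an
all-constant table is defined as 0 (no between-subject variance to agree
about).  The implementation is five lines of mean squares and is
cross-checked against `pingouin.intraclass_corr` in the tests.  The
factorial comparison is a standard fixed-effects two-way ANOVA with
interaction (statsmodels), requiring a balanced design with ≥ 2 replicates
per cell; p-values are reported raw and Bonferroni-adjusted across the
three effects (the original correction method is unnamed; Bonferroni is
the declared default).  A constant response returns F = 0 for all effects
rather than 0/0.

## Synthetic cohorts: what they emulate, what they do not

A subject is a weighted planted-partition graph: 40 nodes in 4 equal
modules, within/between edge probabilities 0.8/0.05, edge weights uniform
on [0.5, 1]; disconnected draws are repaired with minimal weight-0.5
bridges.  The cohort default is 20 subjects — small enough for desk-scale
grids, large enough for stable NMI and ICC.  Session 2 applies
multiplicative log-normal weight noise on the log scale (weights stay
positive without clipping) and degree-preserving rewiring of a declared
fraction of edges (⌊f|E|/2⌋ double-edge swaps, so at most a fraction f of
edges change); weights travel with their edges.  Metric stacks mix the
z-scored NS matrix with independent Gaussian noise to hit a target edge
correlation per metric (MD/RD mixed against −NS), ED is the Euclidean
distance between random 3-D coordinates restricted to the edge support,
and a subject's two sessions share the stack seed so zero session noise
yields identical stacks.

No generative model of between-scan variability is claimed for real
test–retest data; the noise model is a declared stand-in.  The generator
has none of the features that make empirical SBNs hard: no heavy-tailed
streamline counts, no distance-dependent connection probability, no
hub-concentrated topology, no spatially correlated metric noise, and no
anatomical meaning in the node set.  Passing tests therefore certify the
*machinery* — recovery when structure is recoverable, calibration of the
permutation tests, exact conservation laws, idempotence and monotonicity —
not any empirical claim about brain networks.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data
at fixed problem sizes chosen for a single-CPU desk run: ≤ 8-node fixtures
for exhaustive enumeration (Bell(8) = 4140 partitions), 100 × 4 planted
recovery runs, 100 surrogates for conservation checks, 100 null inputs ×
99 surrogates for calibration, 20-subject zero-noise cohorts, a 3-point
noise grid with 12 subjects, and a 7 × 4 × 3 ANOVA design.  Every random
draw flows from an explicit seed (NumPy `SeedSequence` spawning); repeated
runs with the same seed are byte-identical, and the pipeline records all
derived seeds in its outputs.

## Known limitations

* OMST outputs at 40 nodes are near-trees, which makes scheme A–C
  partitions fragile under weight noise and depresses their consensus
  similarity relative to what dense 90-node empirical matrices show; the
  thresholded schemes D–G can conversely isolate nodes at matched
  sparsity, which the pipeline handles by per-component detection and a
  largest-component quality test.
* The rn default resolution is calibrated to the generator's weight scale;
  users applying it to differently scaled weights should rescale or scan γ.
* The soft-cover path implements one representative algorithm; the plug-in
  registry (`sbncomm.detection.ALGORITHMS`) is the intended extension
  point for further hard or soft methods.
* Eq.-style hub agreement uses a per-subject logical AND across sessions;
  alternative readings (OR, session-wise averaging) are not implemented.
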
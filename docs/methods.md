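# Methods

## Scope and data model

coexnet implements a coexpression-network workflow for multi-condition
expression surveys: filtering, pairwise association scoring, benchmark-driven
thresholding, Markov clustering, hub analysis, and term enrichment. The
in-memory substrate is a pandas DataFrame of log2 expression values with
unique gene identifiers as the index and stage labels as columns; all
downstream objects (score matrices, networks, partitions, hub sets) are
small typed containers over numpy arrays and networkx graphs.

## Low-information filter

A gene is removed iff BOTH hold: its between-sample expression difference
(max − min) is strictly below the median of all genes' differences, and its
mean signal is strictly below the median of all genes' means. Both medians
are computed once, on the full input, before any removal. Conventions:

* median of an even count = midpoint of the two central order statistics;
* strict inequalities — a gene exactly at a median is kept (so a matrix of
  identical rows keeps everything);
* the function is scale-agnostic; the pipeline applies it to the raw-scale
  matrix by default (`filter_on: raw|log2|none`) and log2-transforms the
  survivors, matching the original order of operations in which the
  between-sample "expression difference" is a property of the expression
  signal, not its logarithm.

Because both cut points are medians of the full gene population, the filter
removes at most ~half of the genes — those simultaneously flat and dim —
and the removed fraction depends on how range and mean co-vary.

## Association scores

**Correlations.** PCC is the product-moment correlation of the expression
rows; SCC is PCC of the average-ranked rows. Constant rows have undefined
variance; their correlations are set to 0 with a logged warning rather than
raising, since a filtered matrix can still contain near-flat genes.
Thresholding uses the signed coefficient by default (`absolute=True` is
available); the networks reported here never depend on negative edges
because module profiles are planted as positive associations.

**Mutual information.** The default estimator is the B-spline generalised
histogram: each gene's values are mapped affinely onto the knot domain of an
open-uniform B-spline basis (default 10 basis functions, spline order 3,
i.e. quadratic), giving every sample fractional membership in adjacent bins
that sums to one. Marginal and joint distributions are the sample means of
these weights and of their outer products, and MI is the plug-in entropy
combination H(X) + H(Y) − H(X,Y), clamped at 0 and reported in nats
(`unit="bits"` divides by ln 2). Spline order 1 degenerates exactly to hard
equal-width binning, which is kept as `estimator="equal_width_bins"` and
doubles as the brute-force test oracle. Pair computation is tiled
(`block_size` rows at a time) with results identical to the naive double
loop; 600 genes × 20 samples takes a few seconds.

**CLR.** For each gene i, μᵢ and σᵢ are the mean and *population* standard
deviation (divide by n) of its off-diagonal MI values — self-MI never enters
the background. zᵢ(j) = max(0, (I(i,j) − μᵢ)/σᵢ), combined symmetrically as
Z(i,j) = √(zᵢ(j)² + zⱼ(i)²). σᵢ = 0 yields zᵢ(·) = 0 with a warning. The
population-sd convention is fixed by the package's 3-gene worked example
(backgrounds (0.8, 0.2) → μ = 0.5, σ = 0.3, Z = √2) and recorded here
because the sample-sd alternative would rescale every Z. Confidence-level
calibrations of Z (as used for presentation in some studies) are not
computed; all cutoffs are raw Z values.

## Benchmark validation and cutoff selection

A reference protein complex is expanded into a clique of true edges; with
overlapping complexes, a pair is true if it co-occurs in any complex.
`validate_network` restricts inferred edges to pairs with both endpoints in
the benchmark universe — pairs with an endpoint outside it have no defined
truth and enter neither numerator nor denominator — then reports
p = correct/restricted, r = correct/true, F = 2pr/(p+r), with p = 0 for an
empty restricted set and F = 0 when p + r = 0.

`per_complex_curves` evaluates one curve per complex on a shared accuracy
baseline: p is global over the union universe (cross-complex pairs count as
incorrect) while r is that complex's own coverage. Judging a single complex
against only its own universe would make every restricted pair true by
construction (p ≡ 1) and push every optimum to the smallest cutoff, so the
union-universe baseline is the meaningful one whenever several complexes
are benchmarked together.

`select_cutoff` operationalises "the plateau of the F curve" as: per
complex, the smallest cutoff attaining that complex's maximal F; overall,
the minimum of the per-complex optima — the most permissive threshold that
is optimal for some complex. Ortholog transfer of complexes drops members
without a one-to-one ortholog and discards complexes shrinking below two
members, with a warning.

## Markov clustering

The MCL implementation is from scratch (no installed library provides it).
The flow matrix starts from the weighted adjacency (scores as capacities;
`weighted=False` binarises) plus a self-loop at each node's maximum incident
weight, column-normalised. Each round applies expansion (matrix power,
default 2), inflation (entry-wise power, default 1.8, then column
renormalisation), and pruning of entries below 1e-5 with renormalisation;
iteration stops when the largest entry change falls below 1e-6 or at 200
rounds (returned with `converged=False` and a warning). Clusters are the
connected components of the limit matrix's support (entries > tol), so
overlapping attractor systems merge deterministically; singletons are kept
as size-1 modules. The result is invariant to node relabelling, and columns
remain stochastic to 1e-9 after every round (exposed via the
`mcl_iterates` generator for verification). Inflation 1.8 follows the
established optimum for biological interaction and coexpression networks;
higher inflation never coarsens the partition on the test fixtures.

## Hubs

`select_hubs` ranks by degree, breaking boundary ties by lexicographic gene
id so the hub set is deterministic; the degree at rank k is recorded as
`min_degree`. Profile grouping is agglomerative clustering on Euclidean
distances with average linkage (UPGMA) — the distance metric is the
documented choice, the linkage is this package's declared convention — cut
into `n_groups` flat clusters (default 6, matching the six stage-specific
hub classes seen across the life cycle), with group ids renumbered by
descending size. The cross-tabulation of hub groups against modules counts
hubs missing from the partition under an `unassigned` column.

## Enrichment

One-sided hypergeometric tail P(X ≥ k) per term with ≥ 1 test-set hit
(scipy.stats.hypergeom), Benjamini–Hochberg adjustment across tested terms
(statsmodels), significance at FDR < alpha (default 0.05). Term universe
counts are taken within the supplied gene universe — by convention the
filtered gene set, though any universe can be passed. Terms are tested
exactly as given: no ontology-graph propagation, so pre-propagate real GO
annotations if ancestor semantics are wanted.

## Synthetic data generator

The generator emulates a 20-time-point life-cycle microarray survey: three
growth densities (L-l, L-m, L-h), seven starvation points (S-0…S-24), ten
conjugation points (C-0…C-18). Gene classes:

* **module genes** — latent per-module log2 profile plus i.i.d. Gaussian
  noise (default sd 0.5 log2 units, a typical microarray residual scale);
* **complex genes** — the first genes of their module with noise multiplied
  by an attenuation factor (default 0.5), making them the tightest cliques
  and hence the ground-truth "protein complexes";
* **background genes** — i.i.d. noise around a constant moderate level
  (default 10), expressed but unstructured;
* **low-information genes** — flat dim rows (level 4, noise sd 0.05) whose
  range and mean both fall below the global medians by construction.

The default design has 600 genes: six modules of 120/100/90/80/70/60 genes
carrying the six stage-profile shapes (conjugation-early, conjugation-late,
growth-specific, starvation-shared, mixed/oscillating, uniformly-high),
complexes of 19 and 13 genes (sizes echoing the 19S regulatory and 20S core
proteasome particles) inside the two conjugation modules, 30 background and
50 low-information genes. The conjugation modules carry the largest
amplitude (+6 log2 units over baseline 7) so that complex members — whose
attenuated noise narrows their observed range — remain clearly above the
median range and are never lost to the filter; the other profiles use
+3…+4 swings. Because the medians sit inside the structured-gene blocks,
the filter also removes the flattest, dimmest module genes (roughly a third
of the input at default noise), which mirrors how the filter behaves on
real surveys.

What the generator does **not** emulate: probe-level intensities, spatial
array artifacts, dye or batch effects, replicate structure, heavy-tailed
noise, and overlapping module membership. Passing the planted-truth tests
therefore demonstrates correctness of the algorithms under a clean additive
Gaussian model, not robustness to real microarray pathology.

## Problem sizes and determinism

Tests and the acceptance script run the default 600 × 20 design; scoring
and clustering at this size complete in seconds, and all stochastic checks
are seeded. Every random draw derives from a single integer seed
(numpy default_rng); identical seeds give bitwise-identical matrices,
partitions and artifacts. Module recovery is measured as the adjusted Rand
index between MCL modules and planted module labels over the network nodes
that belong to planted modules; hub-group recovery likewise against planted
module membership of network-connected module genes.

## Known limitations

* The accuracy denominator is universe-restricted; studies that divide by
  all network edges would report much smaller p at the same cutoff
  (recorded as a config-level convention, not a switch).
* MCL memory is O(n²) dense; networks beyond ~20k nodes need a sparse
  implementation.
* Hub grouping cuts the dendrogram at a fixed group count; the original
  heatmap-based grouping was visual, so group boundaries are an
  approximation by construction.
* The degree-histogram tail slope is a least-squares diagnostic over log2
  bins, not a maximum-likelihood power-law fit.
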
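# coexnet

Gene coexpression network inference and analysis for genome-wide expression
surveys, built around the workflow used to map the gene network of the
ciliate *Tetrahymena thermophila* across its life cycle (growth, starvation,
conjugation). The package takes a genes × samples expression matrix and

1. removes low-information genes with a combined range/mean median filter;
2. scores every gene pair by Pearson correlation (PCC), Spearman correlation
   (SCC), or mutual information transformed by the **context likelihood of
   relatedness** (CLR) algorithm;
3. chooses an operating score cutoff by benchmarking candidate networks
   against protein-complex cliques (accuracy / coverage / F-score);
4. partitions the thresholded network into modules with a from-scratch
   **Markov Cluster** (MCL) implementation;
5. ranks hub genes by degree and groups their expression profiles by
   Euclidean-distance clustering; and
6. tests any gene set (module, hub group, bait-neighbour set) for annotation
   term enrichment with hypergeometric tests under Benjamini–Hochberg FDR
   control.

A synthetic-data generator plants all of this structure — coexpression
modules with stage-specific profiles, tight complexes inside modules,
background and low-information genes — so that every stage can be tested
against known ground truth without downloading microarray data.

## The statistics

**Low-information filter.** A gene is removed iff both its between-sample
expression difference (max − min) and its mean signal are strictly below the
respective medians over all genes, with both medians computed once on the
full input.

**CLR.** Pairwise mutual information I(i,j) is estimated with a B-spline
generalised histogram (default 10 bins, spline order 3; a plain equal-width
binning estimator is also provided). Each gene's off-diagonal MI values give
a background mean μᵢ and population standard deviation σᵢ, and

    zᵢ(j) = max(0, (I(i,j) − μᵢ) / σᵢ),   Z(i,j) = √(zᵢ(j)² + zⱼ(i)²)

The symmetric Z-score is the edge weight and cutoff variable of the CLR
network.

**Benchmark validation.** Every within-complex gene pair of a reference
protein complex is a "true" edge. For a network thresholded at cutoff t,
restricted to pairs with both endpoints in the benchmark universe:
p = correct/inferred (accuracy), r = correct/true (coverage),
F = 2pr/(p+r). The operating cutoff is the smallest cutoff attaining each
complex's maximal F, minimised over complexes.

**MCL.** A column-stochastic flow matrix is alternately expanded (matrix
power) and inflated (entry-wise power, column renormalisation, pruning)
until convergence; modules are the connected components of the limit
matrix's support, named Module-1, Module-2, … by descending size.
Inflation defaults to 1.8.

**Enrichment.** One-sided hypergeometric tail per term,
BH-adjusted across tested terms, significant at FDR < 0.05.

## Worked example

Score the default 600-gene synthetic life-cycle dataset with CLR, pick the
cutoff from its planted complex benchmark, and cluster the network
(`examples/03_benchmark_cutoff.py` and `examples/04_modules_mcl.py`):

```
complex-19S-like: optimal Z cutoff 0.136 (best F = 1.000)
complex-20S-like: optimal Z cutoff 0.136 (best F = 1.000)
selected overall Z cutoff: 0.136
at that cutoff: p = 1.000, r = 1.000, F = 1.000

network: 513 nodes, 21996 edges at r >= 0.6
MCL found 23 modules (converged=True in 21 iterations)
  Module-1: 120 genes, planted labels ['M1']
  Module-2: 102 genes, planted labels ['M2', 'M6', 'background']
  Module-3: 93 genes, planted labels ['M3', 'M6', 'low-info']
```

p = r = F = 1 means the selected cutoff recovers the two planted complexes
in full with no cross-complex false edges; the largest MCL modules coincide
with the planted modules (Module-1 is exactly the 120-gene
conjugation-early module), with a few background genes absorbed where they
picked up stray edges.

Each script in `examples/` demonstrates one capability: filtering, the
three scorers and the size-vs-cutoff curves, benchmark-driven cutoff
selection, MCL modules, hub groups, enrichment, and the full pipeline.

## Command line

```bash
coexnet simulate --seed 1 --out-prefix data/toy
coexnet filter data/toy.expression.tsv --out data/filtered.tsv --no-log2
coexnet infer data/filtered.tsv --method clr --cutoff 2.0 --out data/edges.tsv
coexnet cluster data/edges.tsv --out data/modules.txt
coexnet run-all --config cfg.yaml --outdir runs/r1
```

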
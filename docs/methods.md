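# Methods

## The analysis model

The package treats a herbivory meta-analysis as operations on one central
object: a gene × experiment matrix of log2 fold changes (infested vs
control) whose rows are the union of genes called differentially expressed
(DE) in at least one experiment. Two boolean masks accompany it — DE status
per cell, and whether the gene was measurable on that experiment's platform
at all. Everything downstream (correlation, clustering, PCA, bootstraps,
set algebra) consumes this matrix; the PPI analytics consume a separate
score-filtered interaction graph.

### DEG calling

A gene is DE when its adjusted p-value is strictly below `padj_max`
(default 0.05) **and** |log2FC| is strictly above `abs_lfc_min` (default
1). The same strict cutoff is applied to down-regulation at −1; genes with
a missing adjusted p-value are never called. Duplicate rows in an input
table collapse to the row with the smallest padj, then the largest |log2FC|,
then first occurrence — input tables from public reanalyses often carry
duplicated identifiers and no convention exists, so the rule favors the
strongest evidence deterministically.

### Matrix assembly and fill policy

Cells that are measured but not DE are set to 0 by default
(`fill_policy="zero"`): published DEG lists usually omit non-significant
fold changes, and DEG-list heatmaps conventionally show those cells as
zero. `fill_policy="reported"` keeps the reported values for inputs that
carry full statistics; the variance-based analyses in the recovery
benchmarks use it together with `gene_universe="all"`. Unmeasured cells are
0 with the measured mask false; no imputation is attempted.

### Correlation module

Pearson correlations are computed between gene rows across all experiments
on the matrix as filled (a deliberate choice: the zero-filled matrix is
what the heatmap and clustering see). An edge requires r ≥ 0.95, signed by
default — co-expression modules of interest here are co-directional;
`signed=False` admits |r|. The reported module is the set of *clique
components*: connected components in which every pair is adjacent. A
component with even one missing pair is not a clique and contributes
nothing — this is the only reading of "fully connected subnetwork" that
distinguishes it from mere connectivity, and a flag falls back to plain
components. Zero-variance genes are reported separately instead of being
silently uncorrelated.

### Experiment clustering

Agglomerative clustering of experiment column vectors under Euclidean
distance with the Ward.D2 (variance-minimizing) update, cut to k = 4 by
default. Labels are renumbered by first appearance in experiment order so
the assignment is a pure function of the matrix.

### PCA contributions and dimension selection

PCA uses experiments as variables: columns are mean-centered (unscaled by
default, matching covariance-PCA conventions; a scale flag standardizes
them). With genes as observations, the contribution of gene g to dimension
d is 100·score²(g,d)/Σ_h score²(h,d), and analogously for experiments on
the loadings. The analysis depth D is the smallest depth whose cumulative
variance fraction strictly exceeds 0.70; the scree inflection — the argmax
of the second difference of the eigenvalue sequence, first index on ties —
is reported as a diagnostic and extends the selection when it is deeper.
Multi-dimension gene ranking uses the eigenvalue-weighted mean
contribution Σ_d ctr(g,d)·λ_d / Σ_d λ_d, the convention of contribution
biplot tooling; ties break lexicographically.

### BCa bootstrap and cluster specificity

`bca_interval` implements the bias-corrected and accelerated nonparametric
bootstrap: B resamples with replacement (default 10,000);
z0 = Φ⁻¹((#{θ* < θ̂} + ½#{θ* = θ̂})/B); acceleration from the leave-one-out
jackknife a = Σd³ᵢ /(6(Σd²ᵢ)^{3/2}); endpoints are the adjusted-percentile
empirical quantiles (type-7 interpolation). Degenerate inputs (constant
sample, zero jackknife variance) return the point interval; when all
bootstrap replicates fall on one side of the estimate the tie-share p is
clamped to (1/2B, 1−1/2B) to keep z0 finite.

A gene behaves *cluster-specifically* when the global mean log2FC (over
the analyzed genes × all experiments) lies outside the BCa interval of the
gene's log2FC across that cluster's experiments. The resampling unit is
the experiment within the cluster — the only exchangeable unit available.
Each (gene, cluster) pair draws from its own seed-sequence stream, so
results are independent of iteration order.

**Small-sample caveat.** BCa is known to undercover at small n; measured
here, nominal 95% intervals for a normal mean cover the truth ≈93% of the
time at n=20 and only ≈86% at n=6 (scipy's independent BCa reproduces
both). With clusters of ~6 experiments, roughly one null gene in seven is
falsely flagged at α = 0.05. This is a property of the prescribed interval
method at this cluster size, documented rather than patched; the recovery
benchmark reports it honestly (sensitivity ≈100%, specificity ≈86% under
planted effect 3, noise 0.5, cluster size 6).

### PPI analytics

The interactome keeps edges with combined score strictly above 900 and,
by default, non-zero experimental evidence ("evidence required" is encoded
as experimental subscore > 0; no subscore cutoff is published). Shortest
paths are unweighted: the score filter already binarizes confidence.

*Minimum connected network*: per component holding ≥2 mapped seeds, the
metric-closure Steiner approximation — seed-to-seed BFS distances
(neighbors visited lexicographically), Kruskal MST of the closure with
(distance, u, v) ordering, closure edges expanded to graph paths, a
spanning tree re-extracted, non-seed leaves pruned. This is the published
2-approximation; the original platform's exact algorithm is not public, so
a testable stand-in with fully deterministic tie-breaking is used, and the
brute-force bound (≤2× the exhaustive optimum on small graphs) is part of
the test suite. By default the returned subnetwork restores all original
edges among retained nodes; a flag keeps only tree edges.

*Hubs*: exact unnormalized Brandes betweenness over unordered pairs
(matching the large raw values of published hub tables; a normalization is
one division away), top-15 per network with ties broken by degree then
name, and an order-free intersection across per-time-point rankings for
recurrent connectors.

*Expansion*: each round scores every non-member neighbor by the summed
combined scores of its edges into the current members and admits the top
`per_round` (default 5 — the published account gives the number of rounds,
six in the text and eight in a figure legend, but not nodes per round;
both are configuration). Growth is monotone and deterministic.

*Enrichment*: hypergeometric upper-tail test per term against a
user-supplied annotation, Holm (Bonferroni step-down) correction across
tested terms. No term database ships with the package.

### Integration

The final seed set is (specific ∩ basal) ∪ (basal ∩ cluster-contributing)
∪ (cluster-contributing \ correlated), where *basal* is the node set of
the minimum network around the recurrent hubs, *correlated* defaults to
the clique-component genes (flag to use the any-correlation set),
*cluster-contributing* is the top-contribution genes flagged above the
global mean in the cluster holding the target species (a strict flag
additionally requires no flag in any other cluster), and *specific* is the
species-specific DEG set.

## The synthetic generator

`simulate_meta_experiments` draws log2FC = μ(g,e) + N(0, sd) with μ the
planted module effect when gene g's module is active in experiment e's
cluster/species, else 0. Adjusted p-values are *assigned* (0.001 for
planted cells, 0.5 otherwise) rather than computed from a count model: the
pipeline consumes only the thresholded decision, and a fake read-count
model would add nothing testable. Microarray experiments drop a fraction
of genes uniformly at random (real probe dropout is structured, but no
stage depends on that structure). All draws come from per-experiment
seed-sequence spawns, so output is a pure function of (spec, seed).

The default scenario mirrors the shape of a published 28-experiment
compilation: 17 microarray + 11 RNA-seq experiments across aphids,
whiteflies, thrips, lepidopterans, mites and leafminers in four planted
clusters; a 120-gene core module silent in the aphid-like cluster;
cluster modules of 15–30 genes (effects 2–3 log2 units); a 20-gene
mite-specific module split early/persistent/late across the four mite
time points; gene-level noise sd 0.5; 10% microarray dropout. Two
refinements are deliberate: the core module carries a shared
per-experiment amplitude (U(1.5, 4)) and a tighter per-gene noise (0.15),
because a co-regulated module can only clear a pairwise r ≥ 0.95 threshold
if the shared signal variance exceeds ~19× the per-gene noise variance —
with one global noise level the correlation stage would be vacuous.
Species modules of a species with ≥3 time points are split into thirds
(early-only / persistent / late-only) so per-time-point DEG sets differ,
which is what makes hub recurrence across time points informative.

What the generator does **not** emulate: correlated noise between
experiments sharing a platform or lab, structured probe dropout,
compositional or normalization artifacts, and identifier mismatches.
Recovery results on synthetic data therefore show the pipeline's
correctness and calibration under its own model assumptions, not
robustness to those real-data pathologies.

The planted PPI (`simulate_ppi`) is a Barabási–Albert background graph;
seed genes attach to `attach_m` background nodes with pairwise-disjoint
neighborhoods, and each planted hub links directly to its assigned seed
genes — making it their unique length-2 connector, hence high-betweenness
by construction. In the default pipeline scenario each of three hubs
serves 40 core genes. High-centrality background nodes can legitimately
recur in top-15 tables alongside the planted hubs, so end-to-end recovery
is asserted as "planted ⊆ recurrent, recurrent small", while exact
recovery is asserted in constructions that guarantee it.

## Problem sizes and numerical choices

Benchmarks run at desk scale by design: 28 experiments, 200–2,000 genes,
B = 2,000 for coverage/recovery sweeps (B = 10,000 in the pipeline default
and endpoint checks), 50 seeds for clustering recovery, 10 for
contribution and specificity recovery, 200/100 random graphs for the
betweenness/Steiner oracles. Determinism everywhere comes from explicit
seed-sequence derivation (stage name CRC ⊕ root seed), lexicographic
tie-breaking in graph algorithms, and sign-fixing of SVD components
(largest-|loading| entry positive). Degenerate inputs are handled
explicitly: zero-variance genes (diagnostics list), constant bootstrap
samples (point intervals), empty seed sets and sub-minimal clusters
(errors naming the offender).

## Known limitations

* BCa undercoverage at small cluster sizes (above) — flags from clusters
  of ≤6 experiments are anticonservative.
* The minimum-connected-network heuristic guarantees only a factor-2 bound
  relative to the optimal Steiner tree.
* Species specificity is defined against all non-target experiments
  regardless of time point; a gene shared with a single other experiment
  disqualifies it.
* Identifiers are opaque strings: no ortholog/probe mapping, so inputs
  must already share a gene namespace.
* The correlation threshold applies to the zero-filled matrix; with
  `fill_policy="reported"` the same genes can correlate differently.
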
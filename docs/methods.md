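# Methods

## Data model

An OTU table is a `p × n` matrix of non-negative integer counts (OTUs as
rows, samples as columns) with unique string identifiers on both axes;
every sample must contain at least one read. Relative abundances divide
each column by its total, preserving the zero pattern exactly. The
phylogeny is a rooted tree (multifurcations allowed) with non-negative
branch lengths whose leaves are keyed by OTU id; a Newick string without an
explicit root is treated as rooted at its outermost node and is never
re-rooted. When a table and tree disagree, `harmonize` either rejects the
pair (`strict`) or restricts both to the shared OTU set (`prune`),
collapsing the unary nodes left behind by shearing so the retained taxa
keep their summed root-to-leaf path lengths; a single internal child left
dangling at the root is promoted, since a branch shared by every sample
cancels from every pairwise UniFrac comparison.

## Beta-diversity metrics

**Bray-Curtis** is computed on the raw counts, `Σ|n_Ai − n_Bi| / Σ(n_Ai +
n_Bi)`; no rarefaction or relative-abundance conversion is applied by
default (a relative-abundance mode exists but is not the default). This
makes BC sensitive to sequencing-depth differences — deliberately so, as
that is the behaviour being studied.

**UniFrac family.** All three variants are computed from one branch
decomposition: for every non-root branch `b` with length `ℓ_b` we
accumulate, per sample, a presence flag (any descendant leaf has a nonzero
count) and an abundance share `p_b` (fraction of the sample's reads on
descendant leaves). The root branch is excluded. Then

- unweighted: `Σ ℓ_b [present in exactly one] / Σ ℓ_b [present in ≥ 1]`,
- weighted (normalized): `Σ ℓ_b |p_Ab − p_Bb| / Σ ℓ_b (p_Ab + p_Bb)`,
- generalized with exponent `γ ∈ [0, 1]`:
  `Σ ℓ_b (p_Ab+p_Bb)^γ |p_Ab−p_Bb|/(p_Ab+p_Bb) / Σ ℓ_b (p_Ab+p_Bb)^γ`,
  summed over branches with `p_Ab + p_Bb > 0`.

The normalized weighted variant is used (rather than the raw-sum variant)
so every metric in the panel lives on a common [0, 1] scale; it coincides
with the generalized form at `γ = 1`, which the tests assert to 1e−12. The
whole family is verified to 1e−10 against a naive oracle that enumerates
every branch and recomputes its descendant set from scratch, and
cross-checked against scikit-bio's independent implementation.

**Aitchison** adds a pseudocount (default 1) to every count, closes the
composition, applies the centered log-ratio transform and takes Euclidean
distances. A pseudocount of 0 is accepted only for strictly positive
tables, where CLR scale invariance holds exactly.

**Combined metric.** Each of the UU and BC matrices is divided by its own
largest entry, then mixed convexly with weight `α` on UU (default 0.5).
Because the scaling is per-matrix, the combined metric is dataset-relative:
adding samples changes the normalization, so matrices from different
datasets are not comparable. At `α ∈ {0, 1}` the metric equals the
normalized component exactly; since per-matrix scaling is monotone, PAM and
complete-linkage partitions at the endpoints coincide with those of the raw
component.

## Diagnostics

Per-sample Shannon diversity is `−Σ p_ij ln p_ij` over nonzero abundances
(natural log; a `base` argument converts units). "Total Shannon" is the sum
over samples. The "high-abundance mass" is the sum of per-OTU mean relative
abundances over OTUs whose mean is **strictly** greater than the threshold
(default 0.001); the mean is the unweighted average of per-sample relative
abundances (a pooled-counts mode is available). Magnitudes of the total
Shannon statistic depend on the log base and on whether counts were
rarefied; this package fixes natural log and unrarefied counts.

## Clustering

**PAM** follows the classical BUILD + SWAP scheme: BUILD greedily adds the
medoid that most reduces total assignment cost; SWAP repeatedly applies the
single best strictly-improving medoid/non-medoid exchange until none
exists. All ties break toward the lowest sample index, making the result
deterministic. Known limitation: single-run BUILD + SWAP is a local search
— on unstructured (e.g. i.i.d. uniform) dissimilarity matrices it can stop
in a single-swap local optimum above the global medoid optimum. On
block-structured dissimilarities of the kind produced by clustered data it
matched exhaustive medoid search on every fixture tried (1200/1200 at
n ≤ 10, k ≤ 3).

**Hierarchical complete linkage** delegates to
`scipy.cluster.hierarchy.linkage`, which accepts arbitrary non-Euclidean,
non-metric dissimilarities; trees are cut at `k` clusters. Complete linkage
is monotone, so merge heights never decrease.

**Dirichlet-multinomial mixture.** Each component is a multinomial whose
composition parameter is Dirichlet-distributed — the standard model for
overdispersed microbiome counts. Fitting is EM: the E-step computes
responsibilities from the DM log-likelihood (log-gamma sums; the
multinomial coefficient is constant across components and omitted); the
M-step re-estimates weights and updates each component's Dirichlet
parameters by a responsibility-weighted fixed-point iteration (three steps
per M-step). The fixed point is the standard monotone lower-bound update
for the Polya likelihood, so the observed log-likelihood is non-decreasing
across EM iterations (asserted to 1e−6 in tests). Initialization draws
responsibilities from a flat Dirichlet per start; the best of `n_starts`
runs by final log-likelihood is kept. Convergence is declared when the
log-likelihood changes by less than `tol` (default 1e−6) within `max_iter`
iterations; otherwise the best iterate is returned with `converged=False`.
Because the DM likelihood is dimension-hungry, OTUs present in fewer than
20% of samples are conventionally summed into a single `RARE_BIN` row
first (`bin_rare_otus`; the threshold comparison is strict, and binning is
the caller's choice). The number of components `k` is fixed by the caller;
model selection is out of scope.

## Evaluation

The adjusted Rand index is the chance-corrected pair-counting agreement
(computed via scikit-learn after aligning partitions by sample id): 1 iff
the partitions are identical up to label renaming, 0 in expectation for
independent random labelings. PCoA is classical metric scaling: eigendecompose
`−½ J D² J`, sort eigenvalues descending, scale eigenvectors by the square
root of positive eigenvalues. No Cailliez or Lingoes correction is applied;
negative eigenvalues are reported so non-Euclidean distortion is visible,
and `proportion_explained` divides by the sum of the positive eigenvalues
only. Distance histograms bin the `n(n−1)/2` upper-triangle entries —
clean two-group structure shows up as bimodality.

## Perturbations

All four procedures operate on fresh copies; the sweep harness never
mutates its inputs.

- **Tree trimming.** Depth is the edge count from the root, and the
  frontier is fixed by the *original* tree: with maximal leaf depth `Dmax`
  and trimming level `L`, every maximal subtree whose root lies at depth
  `≥ Dmax − L` collapses into a single leaf carrying the summed counts of
  its descendants and the subtree root's original branch length. Using the
  original depth frontier (rather than recomputing it after each merge)
  keeps levels integral, monotone and reproducible. `L = 0` is the
  identity. Column sums are conserved; total Shannon is non-increasing in
  `L` (entropy under coarsening) and high-abundance mass non-decreasing
  (means of merged OTUs add).
- **Branch growing.** Each generation replaces every leaf by two daughters
  (daughter branch length defaults to the parent leaf's own terminal
  length). In the default `per_sample_whole_count` mode, each sample's
  whole count moves to one daughter by a fair coin — per-sample Shannon is
  exactly invariant and zeros stay zero, i.e. branches grow without adding
  information. The alternative `per_sequence_split` mode assigns each read
  independently (binomial ½), which does raise per-sample entropy; both
  modes conserve column sums.
- **Count thresholding** zeroes entries `≤ t`; zeroed sets are nested in
  `t`. Errors if a sample would be emptied.
- **Zero filling** flips each zero entry to a count of 1 independently with
  probability `q`; any flip strictly increases total Shannon.

`run_sweep` applies one perturbation over a grid, computes the requested
metrics, clusters each matrix (PAM or complete linkage) and scores against
the true partition, recording per-step ARI medians with 2.5/97.5 percentile
intervals plus the two diagnostics. Deterministic kinds (trim, threshold)
run once per step and thus have zero-width intervals; stochastic kinds
(grow, zerofill) default to 200 replicates. Tests and examples use 8–25
replicates to keep the default suite fast; the estimator is unchanged.

## Synthetic regimes

Each cluster is a Dirichlet-multinomial: a base composition over the
tree's leaves (taken in tip order so index blocks are phylogenetically
adjacent), per-sample compositions `Dirichlet(c · base)`, read depth
`Poisson(depth_mean)` (minimum 1), counts multinomial. Regime presets:

- `separated` (200 OTUs, 20+20 samples, depth 10 000, concentration 200):
  each cluster puts ~90% of its mass on its own 40%-block of taxa, the rest
  on a shared block. Every metric and clusterer should recover the clusters
  perfectly; this is the sanity floor.
- `schnorr_like` (2500 OTUs, 20+20 samples, depth 5000, concentration
  400): 95% of each cluster's mass is spread over a shared block of 2000
  taxa (mean abundance ≈ 0.0005, below the 0.001 threshold, so the
  high-abundance mass stays under the 0.1 target), and ~4.8% sits on a
  cluster-specific block of 250 phylogenetically adjacent taxa. The
  cluster-specific mass is deliberately small: Bray-Curtis' between-cluster
  count signal then sits inside its own compositional sampling noise
  (individual Dirichlet draws at these tiny parameters are highly
  dispersed), while the specific blocks' presence pattern still marks whole
  clades, so unweighted UniFrac separates the clusters cleanly.
- `smits_like` (600 OTUs, 30+30 samples, depth 10 000, concentration 300):
  both clusters share a core block (~60% of mass) with identical expected
  composition; each cluster additionally holds ~40% of its mass on its own
  40-taxon contrast block, which the *other* cluster carries at fixed
  low "carriage" counts (tiers 1–8 reads, present with probability 0.97).
  On top, a `shared_rare_fraction` of taxa is sporadic single-read noise in
  all samples (presence probability 0.3, count exactly 1). Zero patterns
  therefore overlap almost completely and UU sees mostly noise, while the
  abundance shift drives BC. Raising a count threshold first deletes the
  single-read noise, then strips the carriage tiers one by one, so the UU
  Rand index recovers sharply and monotonically — the thresholding
  mechanism in its cleanest form.

Regime targets (high-abundance mass below/above `ha_mass_target`) are
enforced by construction, verified after generation, and regenerated from a
derived seed up to five times before an "infeasible regime" error. All
randomness flows from the single spec seed.

What the generator does **not** emulate: real taxonomies, longitudinal
within-subject correlation, variable library-size artefacts beyond Poisson
depth, or the exact summary statistics of any published cohort. Passing
the mechanism tests shows the metrics respond to the intended dataset
properties, not that any particular real dataset will cluster well.

## Numerical choices and degenerate inputs

Distance matrices are validated as symmetric, finite, non-negative with
zero diagonal (tolerance 1e−12) and symmetrized before use. Branches with
zero combined share are skipped in generalized UniFrac; samples with no
present taxa are rejected by name in the UniFrac family, as are all-zero
samples in BC and `relative_abundance`. `normalize_by_max` refuses an
all-zero matrix (so the combined metric is undefined when all samples have
identical presence patterns). Newick serialization emits branch lengths to
10 significant digits and round-trips bit-comparable topologies; internal
nodes without labels receive deterministic preorder names `N1, N2, …`.
Dirichlet draws use gamma sampling with parameters clipped at 1e−12;
Dirichlet-mixture parameters are clipped to [1e−8, 1e8] inside the fixed
point.

## Problem sizes

Default test and example sizes are chosen for interactive turnaround: the
mechanism checks run 50 generator seeds per regime at the preset sizes
above; sweep examples use grids of ≤ 11 steps and ≤ 25 replicates for
stochastic kinds; oracle comparisons use trees of ≤ 12 leaves where
brute-force enumeration is exact. All sizes scale up through the public
APIs without code changes.
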
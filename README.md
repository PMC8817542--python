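# microclust

Beta-diversity metrics, unsupervised clustering and perturbation
diagnostics for microbiome OTU tables.

## The problem

Unsupervised clustering of microbiome samples is notoriously sensitive to
the choice of beta-diversity metric. The count-driven Bray-Curtis (BC)
dissimilarity,

    d_BC = Σᵢ |n_Ai − n_Bi| / Σᵢ (n_Ai + n_Bi),

is dominated by high-abundance OTUs and fails on communities where almost
no OTU has a mean relative abundance above ~0.001. The presence/absence
phylogenetic metric, unweighted UniFrac (UU) — the fraction of observed
branch length unique to one of the two samples — ignores counts entirely
and fails when the two groups share most taxa and differ mainly in
abundance, so that low-count presence noise swamps the signal.

`microclust` implements a combined metric that hedges both failure modes.
After scaling each pairwise matrix by its largest value,

    d_combined = α · d_UU / max(d_UU) + (1 − α) · d_BC / max(d_BC),

with α = 0.5 by default. Around it the package provides:

- **Metrics**: Bray-Curtis, unweighted / weighted (normalized) /
  generalized UniFrac, Aitchison (CLR + Euclidean), and the combined metric.
- **Clusterers**: PAM (BUILD + SWAP), hierarchical complete linkage, and a
  Dirichlet-multinomial mixture (EM) with rare-OTU binning.
- **Evaluation**: adjusted Rand index, principal coordinates analysis,
  pairwise-distance histograms.
- **Diagnostics**: total Shannon diversity and "high-abundance mass" (the
  summed mean abundance of OTUs with mean abundance > 0.001) — two
  dataset-level numbers that predict which metric will struggle.
- **Perturbations**: tree trimming, branch growing, count thresholding and
  zero filling, plus a sweep harness that traces the ARI of each
  metric/clusterer combination along a perturbation grid with replicate
  percentile intervals.
- **Synthetic data**: a two-cluster Dirichlet-multinomial generator with
  regimes that emulate the dataset properties above (`separated`,
  `schnorr_like`, `smits_like`).

## Worked example

Generate a community with almost no high-abundance OTUs (the regime where
Bray-Curtis collapses), then cluster it with three metrics:

```python
from microclust import (
    generate_dataset, summarize_dataset, compute_metric, pam,
    adjusted_rand_index,
)

table, tree, truth = generate_dataset("schnorr_like", seed=1)
s = summarize_dataset(table)
print(f"OTUs: {s.n_otus}, samples: {s.n_samples}, mean depth: {s.mean_depth:.0f}")
print(f"total Shannon: {s.total_shannon:.2f} nats")
print(f"high-abundance mass (>0.001): {s.high_abundance_mass:.3f}")
for metric in ("bc", "uu", "combined"):
    D = compute_metric(table, tree, metric)
    ari = adjusted_rand_index(truth, pam(D, k=2))
    print(f"{metric:>8}: ARI = {ari:.3f}")
```

Output:

```
OTUs: 2500, samples: 40, mean depth: 5006
total Shannon: 246.03 nats
high-abundance mass (>0.001): 0.065
      bc: ARI = -0.023
      uu: ARI = 1.000
combined: ARI = 1.000
```

Only 6.5% of the community's mass sits in OTUs above the 0.001 abundance
threshold, and Bray-Curtis clustering is no better than chance (ARI ≈ 0)
while unweighted UniFrac and the combined metric recover the two groups
perfectly. On a `smits_like` dataset (shared taxa, abundance-shift signal,
heavy low-count presence noise) the roles flip: BC scores 1.0, UU scores
≈ 0 — and the combined metric again scores 1.0.

The same pipeline is available from the shell:

```sh
microclust simulate --regime schnorr_like --seed 1 \
    --out-table T.tsv --out-tree X.nwk --out-labels L.csv
microclust summarize --table T.tsv
microclust beta --table T.tsv --tree X.nwk --metric combined --out D.tsv
microclust cluster --dist D.tsv --method pam --k 2 --out P.csv
microclust evaluate ari --pred P.csv --truth L.csv
microclust sweep --kind threshold --table T.tsv --tree X.nwk --truth L.csv \
    --grid 0:10 --metrics bc,uu --out trace.csv --plot trace.png
```

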
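"""Pairwise beta-diversity metrics.

Implements the count-based Bray-Curtis dissimilarity, the UniFrac family
(unweighted, weighted-normalized, generalized), the Aitchison distance, and
a combined Bray-Curtis/unweighted-UniFrac metric

    d_combined = alpha * d_UU / max(d_UU)  +  (1 - alpha) * d_BC / max(d_BC)

which mixes a presence/absence phylogenetic signal with a count-driven
signal after scaling each matrix by its own largest value. ``alpha = 0.5``
is the default. Because of the per-matrix normalization the combined metric
is dataset-relative: adding samples changes the scaling.

The UniFrac family is computed from a branch decomposition of the rooted
tree: for every non-root branch we accumulate, per sample, whether any
descendant leaf is present and what fraction of the sample's reads descend
through the branch. The root branch is excluded; multifurcations are
supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import (
    DistanceMatrix,
    FormatError,
    OTUTable,
    PhyloTree,
    relative_abundance,
)


@dataclass
class CombinedConfig:
    """Mixing weight for the combined metric (share given to unweighted UniFrac)."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass
class BranchWeights:
    """Per-branch lengths plus per-sample descendant presence and abundance share.

    Branches are the non-root nodes of the tree in postorder. ``presence[b, j]``
    is True when any leaf below branch ``b`` has a nonzero count in sample
    ``j``; ``share[b, j]`` is the fraction of sample ``j``'s reads that fall on
    leaves below ``b`` (leaf-level shares sum to 1 per sample, and a branch's
    share equals the sum of its children's shares).
    """

    lengths: np.ndarray  # (B,)
    presence: np.ndarray  # (B, n) bool
    share: np.ndarray  # (B, n) float
    branch_names: list[str]
    sample_ids: list[str]


def branch_weights(table: OTUTable, tree: PhyloTree) -> BranchWeights:
    """Decompose a harmonized table/tree pair into per-branch sample weights."""
    leaf_set = set(tree.leaf_names)
    if set(table.otu_ids) != leaf_set:
        missing = sorted(set(table.otu_ids) ^ leaf_set)
        raise FormatError(
            f"table and tree must be harmonized before UniFrac; mismatched ids: {missing[:10]}"
        )
    row = {o: i for i, o in enumerate(table.otu_ids)}
    ab = relative_abundance(table).abundances
    pres_leaf = table.counts > 0

    lengths: list[float] = []
    names: list[str] = []
    pres_rows: list[np.ndarray] = []
    share_rows: list[np.ndarray] = []
    # postorder accumulation: each node's vectors are sums/ORs of its children's
    node_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.root.postorder():
        if node.is_tip():
            i = row[node.name]
            p = pres_leaf[i]
            s = ab[i]
        else:
            p = np.zeros(table.n_samples, dtype=bool)
            s = np.zeros(table.n_samples, dtype=float)
            for child in node.children:
                cp, cs = node_cache.pop(id(child))
                p = p | cp
                s = s + cs
        node_cache[id(node)] = (p, s)
        if node is not tree.root:
            lengths.append(float(node.length or 0.0))
            names.append(node.name)
            pres_rows.append(p)
            share_rows.append(s)
    return BranchWeights(
        lengths=np.array(lengths, dtype=float),
        presence=np.array(pres_rows, dtype=bool),
        share=np.array(share_rows, dtype=float),
        branch_names=names,
        sample_ids=list(table.sample_ids),
    )


def bray_curtis(table: OTUTable, use_relative: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|nA - nB| / sum(nA + nB) on raw counts.

    The default operates on the actual counts; ``use_relative=True`` converts
    to relative abundances first.
    """
    if (table.counts.sum(axis=0) == 0).any():
        raise FormatError("Bray-Curtis undefined for an all-zero sample")
    data = (
        relative_abundance(table).abundances if use_relative else table.counts.astype(float)
    )
    vals = squareform(pdist(data.T, metric="braycurtis"))
    return DistanceMatrix(
        vals, list(table.sample_ids), "bray_curtis", {"use_relative": use_relative}
    )


def _check_present(bw: BranchWeights) -> None:
    empty = ~bw.presence.any(axis=0)
    if empty.any():
        j = int(np.flatnonzero(empty)[0])
        raise FormatError(f"sample {bw.sample_ids[j]!r} has no present taxa")


def unweighted_unifrac(table: OTUTable, tree: PhyloTree) -> DistanceMatrix:
    """Unshared branch length over union branch length (presence/absence only)."""
    bw = branch_weights(table, tree)
    _check_present(bw)
    P = bw.presence.astype(float)
    wl = bw.lengths[:, np.newaxis] * P
    both = wl.T @ P  # length on branches present in both samples
    tot = bw.lengths @ P  # length on branches present in each sample
    union = tot[:, np.newaxis] + tot[np.newaxis, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(union > 0, (union - both) / union, 0.0)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(vals, list(table.sample_ids), "unweighted_unifrac")


def weighted_unifrac(table: OTUTable, tree: PhyloTree) -> DistanceMatrix:
    """Normalized weighted UniFrac: sum l|pA - pB| / sum l(pA + pB).

    Equal to generalized UniFrac at exponent 1.
    """
    bw = branch_weights(table, tree)
    _check_present(bw)
    n = len(bw.sample_ids)
    S = bw.share
    l = bw.lengths
    vals = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(S - S[:, j : j + 1])
        ssum = S + S[:, j : j + 1]
        num = l @ diff
        den = l @ ssum
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[j] = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(vals, list(table.sample_ids), "weighted_unifrac")


def generalized_unifrac(table: OTUTable, tree: PhyloTree, gamma: float = 0.5) -> DistanceMatrix:
    """Generalized UniFrac with exponent ``gamma`` in [0, 1].

    d = sum_b l_b (pA+pB)^gamma |pA-pB|/(pA+pB) / sum_b l_b (pA+pB)^gamma,
    summed over branches with pA + pB > 0. gamma = 1 recovers the normalized
    weighted UniFrac; smaller gamma down-weights abundant lineages.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    bw = branch_weights(table, tree)
    _check_present(bw)
    n = len(bw.sample_ids)
    S = bw.share
    l = bw.lengths
    vals = np.zeros((n, n))
    for j in range(n):
        ssum = S + S[:, j : j + 1]
        diff = np.abs(S - S[:, j : j + 1])
        mask = ssum > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(mask, ssum**gamma, 0.0)
            ratio = np.where(mask, diff / np.where(mask, ssum, 1.0), 0.0)
        num = l @ (w * ratio)
        den = l @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[j] = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(
        vals, list(table.sample_ids), "generalized_unifrac", {"gamma": gamma}
    )


def aitchison(table: OTUTable, pseudocount: float = 1.0) -> DistanceMatrix:
    """Euclidean distance after centered log-ratio transform.

    A positive ``pseudocount`` is added to every count before closure to
    handle zeros; ``pseudocount=0`` is allowed only when all counts are
    strictly positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = table.counts.astype(float)
    if pseudocount == 0 and (counts <= 0).any():
        raise ValueError("pseudocount 0 requires strictly positive counts")
    x = counts + pseudocount
    x = x / x.sum(axis=0, keepdims=True)
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    vals = squareform(pdist(clr.T, metric="euclidean"))
    return DistanceMatrix(
        vals, list(table.sample_ids), "aitchison", {"pseudocount": pseudocount}
    )


def normalize_by_max(dm: DistanceMatrix) -> DistanceMatrix:
    """Scale all entries by the matrix's largest value so the max becomes 1."""
    m = dm.values.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero distance matrix")
    return DistanceMatrix(
        dm.values / m,
        list(dm.sample_ids),
        dm.metric_name + "_normalized",
        {**dm.params, "normalized_by": m},
    )


def combined_metric(
    table: OTUTable,
    tree: PhyloTree,
    config: CombinedConfig | None = None,
    alpha: float | None = None,
) -> DistanceMatrix:
    """Convex combination of max-normalized unweighted UniFrac and Bray-Curtis."""
    if config is None:
        config = CombinedConfig(alpha if alpha is not None else 0.5)
    uu = normalize_by_max(unweighted_unifrac(table, tree))
    bc = normalize_by_max(bray_curtis(table))
    vals = config.alpha * uu.values + (1.0 - config.alpha) * bc.values
    return DistanceMatrix(
        vals, list(table.sample_ids), "combined", {"alpha": config.alpha}
    )


METRIC_NAMES = ("bc", "uu", "wu", "gu", "aitchison", "combined")


def compute_metric(
    table: OTUTable,
    tree: PhyloTree | None,
    metric: str,
    alpha: float = 0.5,
    gamma: float = 0.5,
    pseudocount: float = 1.0,
) -> DistanceMatrix:
    """Dispatch a metric by short name (``bc, uu, wu, gu, aitchison, combined``)."""
    if metric in ("uu", "wu", "gu", "combined") and tree is None:
        raise ValueError(f"metric {metric!r} requires a tree")
    if metric == "bc":
        return bray_curtis(table)
    if metric == "uu":
        return unweighted_unifrac(table, tree)
    if metric == "wu":
        return weighted_unifrac(table, tree)
    if metric == "gu":
        return generalized_unifrac(table, tree, gamma=gamma)
    if metric == "aitchison":
        return aitchison(table, pseudocount=pseudocount)
    if metric == "combined":
        return combined_metric(table, tree, CombinedConfig(alpha))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
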
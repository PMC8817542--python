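"""Dataset perturbations that probe when a beta-diversity metric fails.

Four procedures modify an OTU table (and, where relevant, its tree), each
targeting one mechanism:

* :func:`trim_tree` — merge the most distal OTUs into proximal composite
  OTUs by summing counts ("trimming" levels off the tree). Raises the mean
  abundance of the surviving taxa, so a count-driven metric (Bray-Curtis)
  gains signal; total Shannon diversity can only decrease (entropy under
  coarsening).
* :func:`grow_descendants` — the converse: split every OTU into daughter
  OTUs, scattering counts across new tips without adding information. In the
  default whole-count mode each sample's entire count moves to one daughter,
  leaving every per-sample Shannon exactly unchanged while the
  high-abundance mass falls.
* :func:`threshold_to_zero` — zero out entries at or below a count
  threshold, i.e. tighten the criterion for calling an OTU "present".
  Removes low-count presence noise, which is what unweighted UniFrac sees.
* :func:`zeros_to_ones` — flip zero entries to a count of one with some
  probability: a minimal change to counts that floods the presence pattern
  with noise, degrading unweighted UniFrac while leaving count-driven
  metrics essentially untouched.

:func:`run_sweep` runs any of these over a parameter grid, recomputing the
requested metrics, clustering each distance matrix, and scoring against the
true partition (adjusted Rand index) with replicate percentile intervals for
the stochastic perturbations, alongside the two dataset diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beta
from .cluster import hierarchical_complete, pam
from .diversity import high_abundance_mass, total_shannon
from .evaluate import adjusted_rand_index
from .io import OTUTable, Partition, PhyloTree

DETERMINISTIC_KINDS = ("trim", "threshold")
STOCHASTIC_KINDS = ("grow", "zerofill")


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def trim_tree(
    table: OTUTable, tree: PhyloTree, levels: int
) -> tuple[OTUTable, PhyloTree]:
    """Merge every maximal subtree rooted within ``levels`` of the deepest leaf.

    Depth is counted in edges from the root and the frontier is fixed by the
    *original* tree: with maximum leaf depth ``Dmax``, every maximal subtree
    whose root sits at depth >= ``Dmax - levels`` collapses to a single leaf
    whose counts are the sum of its descendants' rows and whose branch length
    is the subtree root's original length. ``levels=0`` is the identity.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    dmax = max(tree.leaf_depths().values())
    if levels >= dmax:
        raise ValueError(f"levels must be < max leaf depth ({dmax})")
    cutoff = dmax - levels
    new_tree = tree.copy()
    row = {o: i for i, o in enumerate(table.otu_ids)}

    merged_rows: dict[str, np.ndarray] = {}
    stack = [(new_tree.root, 0)]
    while stack:
        node, depth = stack.pop()
        if depth >= cutoff and not node.is_tip():
            tips = [t.name for t in node.tips()]
            merged_rows[node.name] = table.counts[[row[t] for t in tips]].sum(axis=0)
            node.children = []  # collapse to a leaf keeping name and length
        elif not node.is_tip():
            stack.extend((c, depth + 1) for c in node.children)

    new_tree = PhyloTree(new_tree.root)  # re-validate
    ids, rows = [], []
    for name in new_tree.leaf_names:
        ids.append(name)
        rows.append(merged_rows[name] if name in merged_rows else table.counts[row[name]])
    new_table = OTUTable(np.array(rows), ids, list(table.sample_ids))
    return new_table, new_tree


def grow_descendants(
    table: OTUTable,
    tree: PhyloTree,
    generations: int = 1,
    mode: str = "per_sample_whole_count",
    branch_length: float | None = None,
    seed: int = 0,
) -> tuple[OTUTable, PhyloTree]:
    """Split every leaf into two daughters for each generation.

    ``per_sample_whole_count`` (default) moves each sample's entire count to
    one daughter chosen by a fair coin, so no per-sample Shannon changes and
    no new presence arises from zeros. ``per_sequence_split`` assigns each
    sequence independently (binomial 1/2), which spreads counts across both
    daughters and does raise per-sample entropy. Daughter branch lengths
    default to the parent leaf's own terminal length.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if mode not in ("per_sample_whole_count", "per_sequence_split"):
        raise ValueError(f"unknown mode {mode!r}")
    if branch_length is not None and branch_length <= 0:
        raise ValueError("branch_length must be positive")
    rng = np.random.default_rng(seed)

    new_tree = tree.copy()
    rows = {o: table.counts[i].copy() for i, o in enumerate(table.otu_ids)}
    for _ in range(generations):
        for tip in list(new_tree.root.tips()) or [new_tree.root]:
            counts = rows.pop(tip.name)
            length = branch_length if branch_length is not None else float(tip.length or 1.0)
            names = (f"{tip.name}/0", f"{tip.name}/1")
            if mode == "per_sample_whole_count":
                to_second = rng.integers(0, 2, size=counts.shape).astype(bool)
                c0 = np.where(to_second, 0, counts)
                c1 = np.where(to_second, counts, 0)
            else:
                c1 = rng.binomial(counts, 0.5)
                c0 = counts - c1
            rows[names[0]] = c0
            rows[names[1]] = c1
            tip.extend(
                [
                    type(tip)(name=names[0], length=length),
                    type(tip)(name=names[1], length=length),
                ]
            )
    new_tree = PhyloTree(new_tree.root)
    ids = new_tree.leaf_names
    new_table = OTUTable(np.array([rows[o] for o in ids]), ids, list(table.sample_ids))
    return new_table, new_tree


def threshold_to_zero(table: OTUTable, threshold: int) -> OTUTable:
    """Set every count <= ``threshold`` to zero.

    Errors if any sample would lose all of its reads.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    counts = np.where(table.counts <= threshold, 0, table.counts)
    empty = np.flatnonzero(counts.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(
            f"threshold {threshold} leaves sample "
            f"{table.sample_ids[empty[0]]!r} with no counts"
        )
    return OTUTable(counts, list(table.otu_ids), list(table.sample_ids))


def zeros_to_ones(table: OTUTable, prob: float, seed: int = 0) -> OTUTable:
    """Independently flip each zero entry to a count of 1 with probability ``prob``."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    zeros = table.counts == 0
    flips = zeros & (rng.random(table.counts.shape) < prob)
    counts = np.where(flips, 1, table.counts)
    return OTUTable(counts, list(table.otu_ids), list(table.sample_ids))


# ---------------------------------------------------------------------------
# sweep harness
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    """One grid point of a sweep: diagnostics plus per-metric ARI summaries."""

    param: float
    ari_median: dict[str, float]
    ari_lo: dict[str, float]  # 2.5th percentile over replicates
    ari_hi: dict[str, float]  # 97.5th percentile over replicates
    total_shannon: float
    high_abundance_mass: float


@dataclass
class PerturbationTrace:
    kind: str
    steps: list[StepRecord]
    n_replicates: int
    seed: int
    metrics: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {
                "param": s.param,
                "total_shannon": s.total_shannon,
                "high_abundance_mass": s.high_abundance_mass,
            }
            for m in self.ari_metrics():
                row[f"ari_{m}_median"] = s.ari_median[m]
                row[f"ari_{m}_lo"] = s.ari_lo[m]
                row[f"ari_{m}_hi"] = s.ari_hi[m]
            rows.append(row)
        return pd.DataFrame(rows)

    def ari_metrics(self) -> list[str]:
        return self.metrics or sorted(self.steps[0].ari_median)


def _apply(kind, table, tree, param, seed):
    if kind == "trim":
        return trim_tree(table, tree, int(param))
    if kind == "grow":
        return grow_descendants(table, tree, generations=int(param), seed=seed)
    if kind == "threshold":
        return threshold_to_zero(table, int(param)), tree
    if kind == "zerofill":
        return zeros_to_ones(table, float(param), seed=seed), tree
    raise ValueError(f"unknown perturbation kind {kind!r}")


def run_sweep(
    table: OTUTable,
    tree: PhyloTree,
    truth: Partition,
    kind: str,
    grid,
    metrics=("bc", "uu", "combined"),
    clusterer: str = "pam",
    k: int = 2,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.5,
    gamma: float = 0.5,
) -> PerturbationTrace:
    """Sweep a perturbation over ``grid``, scoring each metric+clusterer by ARI.

    Deterministic kinds (``trim``, ``threshold``) run once per grid value;
    stochastic kinds (``grow``, ``zerofill``) run ``n_replicates`` times and
    report the median with the 2.5/97.5 percentile interval. ``grow``'s grid
    values are generation counts; ``grid=[0]``-style identity steps are
    handled for every kind (a ``grow`` step of 0 leaves the data unchanged).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid values must be strictly increasing")
    if kind not in DETERMINISTIC_KINDS + STOCHASTIC_KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if clusterer not in ("pam", "hclust"):
        raise ValueError("clusterer must be 'pam' or 'hclust'")
    metrics = list(metrics)
    rng = np.random.default_rng(seed)

    steps: list[StepRecord] = []
    for param in grid:
        reps = 1 if kind in DETERMINISTIC_KINDS or param == 0 else n_replicates
        aris: dict[str, list[float]] = {m: [] for m in metrics}
        shannons, masses = [], []
        for _ in range(reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            if param == 0:
                pt, ptree = table, tree
            else:
                pt, ptree = _apply(kind, table, tree, param, rep_seed)
            shannons.append(total_shannon(pt))
            masses.append(high_abundance_mass(pt))
            for m in metrics:
                D = beta.compute_metric(pt, ptree, m, alpha=alpha, gamma=gamma)
                part = (
                    pam(D, k, seed=rep_seed)
                    if clusterer == "pam"
                    else hierarchical_complete(D, k)
                )
                aris[m].append(adjusted_rand_index(truth, part))
        steps.append(
            StepRecord(
                param=float(param),
                ari_median={m: float(np.median(v)) for m, v in aris.items()},
                ari_lo={m: float(np.percentile(v, 2.5)) for m, v in aris.items()},
                ari_hi={m: float(np.percentile(v, 97.5)) for m, v in aris.items()},
                total_shannon=float(np.median(shannons)),
                high_abundance_mass=float(np.median(masses)),
            )
        )
    return PerturbationTrace(
        kind=kind, steps=steps, n_replicates=n_replicates, seed=seed, metrics=metrics
    )
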
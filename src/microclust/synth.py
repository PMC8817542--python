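"""Synthetic two-cluster OTU tables and random phylogenies.

The generator emulates, at desk scale, the dataset properties that decide
which beta-diversity metric succeeds:

* ``separated`` — each cluster's reads are dominated by its own block of
  taxa (disjoint dominant clades, modest shared background). Every metric
  separates the clusters; this is the sanity floor.
* ``schnorr_like`` — a community with almost no high-abundance OTUs: most
  reads are spread over a large shared block of taxa whose mean abundances
  sit below the 0.001 high-abundance threshold, while the cluster signal is
  carried by blocks of phylogenetically adjacent low-abundance taxa present
  only in their own cluster. Presence/absence phylogenetic metrics
  (unweighted UniFrac) separate the clusters; count-driven metrics
  (Bray-Curtis, Aitchison) drown in compositional sampling noise.
* ``smits_like`` — clusters that share almost all taxa: the signal is an
  abundance shift of common taxa (abundant in one cluster, carried at a few
  reads per sample in the other), on top of a large pool of low-count noise
  taxa sporadically present in both clusters. Count-driven metrics separate
  the clusters; unweighted UniFrac sees mostly the shared presence noise.

Statistically each cluster is a Dirichlet-multinomial: a per-cluster base
composition, per-sample compositions drawn from a Dirichlet around it, and
multinomial counts at Poisson-distributed depth — the same generative family
the DMM clusterer assumes. The ``smits_like`` low-count carriage and noise
are injected as small fixed counts on top of the sampled table so their
removal by count thresholding is predictable.

All randomness flows from ``SyntheticSpec.seed`` through a single
``numpy.random.Generator``, so a spec reproduces its table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import skbio

from .diversity import high_abundance_mass
from .io import OTUTable, Partition, PhyloTree

REGIMES = ("separated", "schnorr_like", "smits_like")


@dataclass
class SyntheticSpec:
    """Parameters of a two-cluster synthetic dataset."""

    n_otus: int = 200
    samples_per_cluster: tuple[int, int] = (20, 20)
    depth_mean: int = 10000
    regime: str = "separated"
    ha_mass_target: float = 0.5
    shared_rare_fraction: float = 0.1
    dirichlet_concentration: float = 200.0
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 4:
            raise ValueError("n_otus must be >= 4")
        if min(self.samples_per_cluster) < 1 or self.depth_mean < 1:
            raise ValueError("samples_per_cluster and depth_mean must be positive")
        if not 0 <= self.ha_mass_target <= 1 or not 0 <= self.shared_rare_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.dirichlet_concentration <= 0 or self.effect_size <= 0:
            raise ValueError("concentration and effect_size must be positive")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")


def make_regime(name: str) -> SyntheticSpec:
    """Documented default spec for a named regime."""
    if name == "separated":
        return SyntheticSpec(
            n_otus=200,
            samples_per_cluster=(20, 20),
            depth_mean=10000,
            regime="separated",
            ha_mass_target=0.5,
            shared_rare_fraction=0.1,
            dirichlet_concentration=200.0,
        )
    if name == "schnorr_like":
        return SyntheticSpec(
            n_otus=2500,
            samples_per_cluster=(20, 20),
            depth_mean=5000,
            regime="schnorr_like",
            ha_mass_target=0.1,
            shared_rare_fraction=0.0,
            dirichlet_concentration=400.0,
        )
    if name == "smits_like":
        return SyntheticSpec(
            n_otus=600,
            samples_per_cluster=(30, 30),
            depth_mean=10000,
            regime="smits_like",
            ha_mass_target=0.5,
            shared_rare_fraction=0.65,
            dirichlet_concentration=300.0,
        )
    raise ValueError(f"unknown regime {name!r}; choose from {REGIMES}")


def generate_tree(n_leaves: int, seed: int = 0) -> PhyloTree:
    """Random binary tree by sequential random joins, exponential branch lengths."""
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [
        skbio.TreeNode(name=f"OTU_{i + 1}", length=float(rng.exponential(0.1)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.exponential(0.1)))
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# regime construction
# ---------------------------------------------------------------------------

def _jittered_block(rng: np.random.Generator, size: int, mass: float, conc: float) -> np.ndarray:
    """A composition over ``size`` taxa summing to ``mass`` with mild heterogeneity."""
    return rng.dirichlet(np.full(size, conc)) * mass


@dataclass
class _Blueprint:
    base1: np.ndarray
    base2: np.ndarray
    noise_idx: np.ndarray  # sporadic low-count taxa (both clusters)
    noise_prob: float
    noise_count: int
    carriage_idx: tuple[np.ndarray, np.ndarray]  # injected into cluster 1, cluster 2
    carriage_counts: tuple[np.ndarray, np.ndarray]
    carriage_prob: float


def _blueprint(spec: SyntheticSpec, rng: np.random.Generator) -> _Blueprint:
    p = spec.n_otus
    e = spec.effect_size
    empty = np.array([], dtype=int)
    none = (empty, empty)
    nocounts = (np.array([]), np.array([]))

    if spec.regime == "separated":
        n_block = int(round(0.4 * p))
        base1 = np.zeros(p)
        base2 = np.zeros(p)
        m_spec = 9.0 * e / (9.0 * e + 1.0)  # 0.9 at effect_size 1
        shared = _jittered_block(rng, p - 2 * n_block, 1.0 - m_spec, 5.0)
        base1[:n_block] = _jittered_block(rng, n_block, m_spec, 2.0)
        base2[p - n_block :] = _jittered_block(rng, n_block, m_spec, 2.0)
        base1[n_block : p - n_block] = shared
        base2[n_block : p - n_block] = shared
        return _Blueprint(base1, base2, empty, 0.0, 0, none, nocounts, 0.0)

    if spec.regime == "schnorr_like":
        n_spec = int(round(0.1 * p))
        n_shared = p - 2 * n_spec
        # mass on a cluster's own rare block: small enough that Bray-Curtis'
        # between-cluster count signal sits inside its compositional noise,
        # while the block's presence pattern still carries a clear clade signal
        m_spec = 0.048 * e / (0.048 * e + 0.952)
        shared = _jittered_block(rng, n_shared, 1.0 - m_spec, 10.0)
        base1 = np.zeros(p)
        base2 = np.zeros(p)
        base1[n_spec : p - n_spec] = shared
        base2[n_spec : p - n_spec] = shared
        base1[:n_spec] = _jittered_block(rng, n_spec, m_spec, 10.0)
        base2[p - n_spec :] = _jittered_block(rng, n_spec, m_spec, 10.0)
        return _Blueprint(base1, base2, empty, 0.0, 0, none, nocounts, 0.0)

    # smits_like
    n_contrast = min(40, max(5, p // 15))
    n_noise = int(round(spec.shared_rare_fraction * p))
    n_core = p - 2 * n_contrast - n_noise
    if n_core < 10:
        raise ValueError(
            "infeasible smits_like regime: shared_rare_fraction leaves "
            f"{n_core} core taxa (need >= 10); lower it or raise n_otus"
        )
    m_contrast = 0.4 * e / (0.4 * e + 0.6)
    idxA = np.arange(n_contrast)
    idxB = np.arange(n_contrast, 2 * n_contrast)
    idx_core = np.arange(2 * n_contrast, 2 * n_contrast + n_core)
    idx_noise = np.arange(2 * n_contrast + n_core, p)
    core = _jittered_block(rng, n_core, 1.0 - m_contrast, 20.0)
    base1 = np.zeros(p)
    base2 = np.zeros(p)
    base1[idx_core] = core
    base2[idx_core] = core
    base1[idxA] = _jittered_block(rng, n_contrast, m_contrast, 20.0)
    base2[idxB] = _jittered_block(rng, n_contrast, m_contrast, 20.0)
    # low-count carriage of the other cluster's contrast taxa: tiered fixed
    # counts 1..8 so a count threshold removes them tier by tier
    tiers = (np.arange(n_contrast) % 8) + 1
    return _Blueprint(
        base1,
        base2,
        idx_noise,
        0.3,
        1,
        (idxB, idxA),
        (tiers, tiers),
        0.97,
    )


def _sample_cluster(
    rng: np.random.Generator,
    base: np.ndarray,
    n_samples: int,
    conc: float,
    depth_mean: int,
) -> np.ndarray:
    p = base.shape[0]
    out = np.zeros((p, n_samples), dtype=np.int64)
    support = base > 0
    alpha = conc * base[support]
    for j in range(n_samples):
        g = rng.gamma(np.clip(alpha, 1e-12, None))
        s = g.sum()
        theta = g / s if s > 0 else np.full(alpha.shape, 1.0 / alpha.size)
        depth = max(1, int(rng.poisson(depth_mean)))
        out[support, j] = rng.multinomial(depth, theta / theta.sum())
    return out


def generate_two_cluster_table(
    spec: SyntheticSpec, tree: PhyloTree
) -> tuple[OTUTable, Partition]:
    """Draw a two-cluster count table over the leaves of ``tree``.

    Leaves are taken in the tree's tip (postorder) order, so blocks of
    consecutive indices in the blueprint correspond to phylogenetically
    adjacent taxa. Regime diagnostics are enforced by construction and then
    verified, with a bounded number of regenerations before giving up.
    """
    leaves = [t.name for t in tree.root.tips()] or [tree.root.name]
    if len(leaves) != spec.n_otus:
        raise ValueError(
            f"tree has {len(leaves)} leaves but spec.n_otus = {spec.n_otus}"
        )
    last_err: str | None = None
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, attempt)))
        bp = _blueprint(spec, rng)
        n1, n2 = spec.samples_per_cluster
        c1 = _sample_cluster(rng, bp.base1, n1, spec.dirichlet_concentration, spec.depth_mean)
        c2 = _sample_cluster(rng, bp.base2, n2, spec.dirichlet_concentration, spec.depth_mean)
        counts = np.hstack([c1, c2])
        n = n1 + n2
        # sporadic shared low-count noise
        if bp.noise_idx.size:
            hits = rng.random((bp.noise_idx.size, n)) < bp.noise_prob
            block = counts[bp.noise_idx]
            counts[bp.noise_idx] = np.where(hits & (block == 0), bp.noise_count, block)
        # tiered carriage counts of the opposite cluster's contrast taxa
        cols = (np.arange(0, n1), np.arange(n1, n))
        for idx, vals, js in zip(bp.carriage_idx, bp.carriage_counts, cols):
            if idx.size == 0:
                continue
            hits = rng.random((idx.size, js.size)) < bp.carriage_prob
            block = counts[np.ix_(idx, js)]
            counts[np.ix_(idx, js)] = np.where(
                hits & (block == 0), vals[:, np.newaxis].astype(np.int64), block
            )
        sample_ids = [f"S{i + 1}" for i in range(n)]
        table = OTUTable(counts, list(leaves), sample_ids)
        truth = Partition(np.array([1] * n1 + [2] * n2), sample_ids)

        ha = high_abundance_mass(table)
        if spec.regime == "schnorr_like" and ha >= spec.ha_mass_target:
            last_err = (
                f"high_abundance_mass {ha:.3f} >= target {spec.ha_mass_target}"
            )
            continue
        if spec.regime == "smits_like" and ha <= spec.ha_mass_target:
            last_err = (
                f"high_abundance_mass {ha:.3f} <= target {spec.ha_mass_target}"
            )
            continue
        return table, truth
    raise ValueError(
        f"infeasible regime target for {spec.regime!r} after 5 attempts: {last_err}"
    )


def generate_dataset(
    regime: str, seed: int = 0, **overrides
) -> tuple[OTUTable, PhyloTree, Partition]:
    """Convenience wrapper: regime preset -> tree + table + true partition."""
    spec = replace(make_regime(regime), seed=seed, **overrides)
    tree = generate_tree(spec.n_otus, seed=seed)
    table, truth = generate_two_cluster_table(spec, tree)
    return table, tree, truth
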
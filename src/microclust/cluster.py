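"""Unsupervised clustering of samples.

Three clusterers are provided:

* **PAM** (partition around medoids): classic BUILD + SWAP search minimizing
  the sum of distances from every sample to its assigned medoid. Works on any
  dissimilarity matrix. Deterministic; ties break toward the lowest sample
  index.
* **Hierarchical complete linkage**: agglomerative merging by the largest
  between-cluster pairwise distance, cut at ``k`` clusters. Accepts arbitrary
  (possibly non-metric) dissimilarities; delegated to
  :func:`scipy.cluster.hierarchy.linkage`.
* **Dirichlet-multinomial mixture (DMM)**: model-based clustering of raw
  count vectors. Each cluster is a Dirichlet-multinomial (multinomial whose
  composition parameter is Dirichlet-distributed), which captures the
  overdispersion of microbiome counts. Fitted by EM: responsibilities from
  the DM log-likelihood in the E-step, mixture weights plus a fixed-point
  update of each component's Dirichlet parameters in the M-step. Because the
  model likelihood is dimension-hungry, rare OTUs are conventionally summed
  into a single bin first (:func:`bin_rare_otus`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln, logsumexp, psi

from .io import DistanceMatrix, OTUTable, Partition

RARE_BIN_ID = "RARE_BIN"


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def _assignment_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[medoids].min(axis=0).sum())


def pam(D: DistanceMatrix, k: int, seed: int = 0) -> Partition:
    """Partition around medoids via BUILD then best-improvement SWAP.

    The search is deterministic (``seed`` is accepted for interface symmetry
    with the stochastic clusterers but is not used): BUILD greedily adds the
    medoid that most reduces the total assignment cost, SWAP repeatedly
    applies the single best strictly-improving medoid/non-medoid exchange.
    All ties break toward the lowest sample index.
    """
    n = D.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = D.values

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[medoids].min(axis=0)
        best_j, best_cost = -1, np.inf
        for j in range(n):
            if j in medoids:
                continue
            cost = np.minimum(current, d[j]).sum()
            if cost < best_cost - 1e-15:
                best_j, best_cost = j, cost
        medoids.append(best_j)

    # SWAP
    cost = _assignment_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best_delta, best_pair = -1e-12, None
        for mi, m in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1 :]
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = _assignment_cost(d, others + [h])
                delta = cost - new_cost
                if delta > best_delta + 1e-15:
                    best_delta, best_pair = delta, (mi, h)
        if best_pair is not None and best_delta > 1e-12:
            mi, h = best_pair
            medoids[mi] = h
            cost = _assignment_cost(d, medoids)
            improved = True

    medoids = sorted(medoids)
    nearest = np.argmin(d[medoids], axis=0)  # ties -> lowest medoid index
    labels = nearest + 1
    return Partition(labels, list(D.sample_ids))


# ---------------------------------------------------------------------------
# Hierarchical complete linkage
# ---------------------------------------------------------------------------

def hierarchical_complete(D: DistanceMatrix, k: int) -> Partition:
    """Agglomerative clustering with complete linkage, cut at ``k`` clusters."""
    n = D.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return Partition(np.arange(1, n + 1), list(D.sample_ids))
    Z = linkage(D.condensed(), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Partition(labels, list(D.sample_ids))


# ---------------------------------------------------------------------------
# DMM
# ---------------------------------------------------------------------------

def bin_rare_otus(table: OTUTable, prevalence: float = 0.2) -> OTUTable:
    """Sum OTUs present in fewer than ``prevalence`` of samples into one bin.

    The bin row is named ``RARE_BIN`` and appended last; column sums are
    preserved. If nothing is rare the table is returned unchanged.
    """
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    frac = (table.counts > 0).mean(axis=1)
    rare = frac < prevalence
    if not rare.any():
        return table
    keep = ~rare
    rows = table.counts[keep]
    bin_row = table.counts[rare].sum(axis=0, keepdims=True)
    counts = np.vstack([rows, bin_row])
    ids = [o for o, m in zip(table.otu_ids, keep) if m] + [RARE_BIN_ID]
    return OTUTable(counts, ids, list(table.sample_ids))


@dataclass
class DMMModel:
    """Fitted Dirichlet-multinomial mixture."""

    k: int
    mixing_weights: np.ndarray  # (k,)
    dirichlet_params: np.ndarray  # (k, p)
    log_likelihood: float
    responsibilities: np.ndarray  # (n, k)
    converged: bool
    n_iter: int
    log_likelihood_trace: np.ndarray


def _dm_loglik(X: np.ndarray, totals: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log-likelihood of each sample under params ``a``.

    The multinomial coefficient is omitted (constant across components).
    """
    A = a.sum()
    return (
        gammaln(A)
        - gammaln(totals + A)
        + (gammaln(X + a[np.newaxis, :]) - gammaln(a)[np.newaxis, :]).sum(axis=1)
    )


def _fixed_point_update(
    X: np.ndarray, totals: np.ndarray, a: np.ndarray, r: np.ndarray, n_steps: int = 3
) -> np.ndarray:
    """Responsibility-weighted fixed-point iteration for DM parameters.

    Each step multiplies a_i by the ratio of weighted digamma sums; this is
    the standard monotone lower-bound update for the Polya (DM) likelihood,
    so the EM objective cannot decrease.
    """
    a = a.copy()
    w = r.sum()
    if w <= 0:
        return a
    for _ in range(n_steps):
        A = a.sum()
        num = (r[:, np.newaxis] * (psi(X + a[np.newaxis, :]) - psi(a)[np.newaxis, :])).sum(
            axis=0
        )
        den = (r * (psi(totals + A) - psi(A))).sum()
        if den <= 0:
            break
        a = np.clip(a * num / den, 1e-8, 1e8)
    return a


def dmm_fit(
    table: OTUTable,
    k: int,
    n_starts: int = 4,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[DMMModel, Partition]:
    """Fit a k-component Dirichlet-multinomial mixture by EM.

    Runs ``n_starts`` randomized initializations (responsibilities drawn from
    a flat Dirichlet) and keeps the fit with the highest final log-likelihood.
    Binning of rare OTUs is the caller's choice (see :func:`bin_rare_otus`).
    Returns the model and the maximum-responsibility partition.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = table.counts.T.astype(float)  # (n, p)
    n, p = X.shape
    totals = X.sum(axis=1)
    rng = np.random.default_rng(seed)

    best: DMMModel | None = None
    for _ in range(max(1, n_starts)):
        r = rng.dirichlet(np.ones(k), size=n)  # (n, k)
        # moment-style init: weighted mean composition, moderate precision
        a = np.empty((k, p))
        for c in range(k):
            w = r[:, c]
            comp = (w[:, np.newaxis] * (X / totals[:, np.newaxis])).sum(axis=0) / w.sum()
            a[c] = np.clip(comp, 1e-8, None) * p
        weights = r.mean(axis=0)

        trace = []
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            log_comp = np.stack(
                [np.log(weights[c] + 1e-300) + _dm_loglik(X, totals, a[c]) for c in range(k)],
                axis=1,
            )  # (n, k)
            ll = float(logsumexp(log_comp, axis=1).sum())
            trace.append(ll)
            r = np.exp(log_comp - logsumexp(log_comp, axis=1, keepdims=True))
            weights = np.clip(r.mean(axis=0), 1e-12, None)
            weights = weights / weights.sum()
            for c in range(k):
                a[c] = _fixed_point_update(X, totals, a[c], r[:, c])
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        model = DMMModel(
            k=k,
            mixing_weights=weights,
            dirichlet_params=a,
            log_likelihood=trace[-1],
            responsibilities=r,
            converged=converged,
            n_iter=it,
            log_likelihood_trace=np.array(trace),
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model

    labels = best.responsibilities.argmax(axis=1) + 1
    return best, Partition(labels, list(table.sample_ids))
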
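"""Clustering agreement, ordination and distance diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.metrics import adjusted_rand_score

from .io import DistanceMatrix, Partition


def adjusted_rand_index(a: Partition, b: Partition) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    1 means identical up to label renaming; 0 is the expectation under
    random labeling. The two partitions must cover the same samples (order
    may differ; labels are aligned by sample id).
    """
    if set(a.sample_ids) != set(b.sample_ids):
        raise ValueError("partitions cover different sample sets")
    order = {s: i for i, s in enumerate(a.sample_ids)}
    b_aligned = np.empty_like(b.labels)
    for s, lab in zip(b.sample_ids, b.labels):
        b_aligned[order[s]] = lab
    return float(adjusted_rand_score(a.labels, b_aligned))


@dataclass
class Ordination:
    """Principal-coordinates embedding of a distance matrix.

    ``eigenvalues`` holds the full descending spectrum of the double-centered
    Gower matrix (negative values flag non-Euclidean distortion and are
    excluded from the coordinates); ``proportion_explained`` divides each
    eigenvalue by the sum of the positive ones.
    """

    coordinates: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (n,) descending
    proportion_explained: np.ndarray  # (n,)
    sample_ids: list[str]


def pcoa(D: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical metric scaling: eigendecompose -1/2 J D^2 J.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only; no Cailliez/Lingoes correction is applied.
    """
    n = D.n_samples
    if n_axes > max(n - 1, 1):
        raise ValueError(f"n_axes must be <= n - 1 = {n - 1}")
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    G = (G + G.T) / 2.0
    evals, evecs = eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos_sum = evals[evals > 0].sum()
    prop = evals / pos_sum if pos_sum > 0 else np.zeros_like(evals)
    m = min(n_axes, int((evals > 1e-12).sum()))
    if m == 0:
        coords = np.zeros((n, n_axes))
    else:
        coords = evecs[:, :m] * np.sqrt(evals[:m])
        if m < n_axes:
            coords = np.hstack([coords, np.zeros((n, n_axes - m))])
    return Ordination(coords, evals, prop, list(D.sample_ids))


def distance_histogram(D: DistanceMatrix, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the n(n-1)/2 pairwise distances (upper triangle).

    A dataset that splits cleanly into two groups typically shows a bimodal
    histogram: a within-cluster mode and a between-cluster mode.
    Returns ``(bin_edges, counts)``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vals = D.condensed()
    counts, edges = np.histogram(vals, bins=n_bins)
    return edges, counts
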
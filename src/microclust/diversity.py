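"""Alpha-diversity and dataset-level diagnostics.

Two dataset-level statistics are used throughout as predictors of metric
behaviour:

* the **total Shannon diversity**, the sum over samples of the per-sample
  entropies ``-sum_i p_ij ln p_ij`` (natural log), which quantifies how much
  of the table's information lives in low-abundance entries; and
* the **high-abundance mass**, the summed mean relative abundance of OTUs
  whose mean abundance exceeds a threshold (0.001 by default), which
  quantifies how much of the community is carried by dominant taxa.

Datasets with little high-abundance mass tend to defeat count-driven metrics
such as Bray-Curtis, while datasets whose information is concentrated in
low-abundance presence noise (high total Shannon relative to their size)
tend to defeat presence/absence metrics such as unweighted UniFrac.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import OTUTable, relative_abundance


@dataclass
class DatasetSummary:
    """Table-level summary statistics."""

    n_otus: int
    n_samples: int
    mean_depth: float
    total_shannon: float
    high_abundance_mass: float
    ha_threshold: float = 0.001

    def to_dict(self) -> dict:
        return {
            "n_otus": self.n_otus,
            "n_samples": self.n_samples,
            "mean_depth": self.mean_depth,
            "total_shannon": self.total_shannon,
            "high_abundance_mass": self.high_abundance_mass,
            "ha_threshold": self.ha_threshold,
        }


def shannon_per_sample(table: OTUTable, base: float | None = None) -> np.ndarray:
    """Shannon entropy of each sample's relative-abundance column.

    Zero-count taxa contribute nothing. Natural log by default; pass ``base``
    to change units (e.g. 2 for bits).
    """
    ab = relative_abundance(table).abundances
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ab > 0, -ab * np.log(ab), 0.0)
    h = terms.sum(axis=0)
    if base is not None:
        h = h / math.log(base)
    return h


def total_shannon(table: OTUTable, base: float | None = None) -> float:
    """Sum of per-sample Shannon diversities over the whole dataset."""
    return float(shannon_per_sample(table, base=base).sum())


def mean_abundance(table: OTUTable, mode: str = "sample_mean") -> np.ndarray:
    """Per-OTU mean relative abundance.

    ``sample_mean`` (default) averages each OTU's per-sample relative
    abundances; ``pooled`` divides pooled counts by the pooled total.
    """
    if mode == "sample_mean":
        return relative_abundance(table).abundances.mean(axis=1)
    if mode == "pooled":
        tot = table.counts.sum()
        return table.counts.sum(axis=1) / tot
    raise ValueError(f"unknown mean mode {mode!r}")


def high_abundance_mass(
    table: OTUTable, threshold: float = 0.001, mode: str = "sample_mean"
) -> float:
    """Summed mean abundance of OTUs with mean abundance strictly > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    means = mean_abundance(table, mode=mode)
    return float(means[means > threshold].sum())


def summarize_dataset(table: OTUTable, threshold: float = 0.001) -> DatasetSummary:
    """Compute the standard dataset summary used for metric-failure diagnosis."""
    return DatasetSummary(
        n_otus=table.n_otus,
        n_samples=table.n_samples,
        mean_depth=float(table.counts.sum(axis=0).mean()),
        total_shannon=total_shannon(table),
        high_abundance_mass=high_abundance_mass(table, threshold=threshold),
        ha_threshold=threshold,
    )
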
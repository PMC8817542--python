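"""Minimal matplotlib helpers for PCoA and sweep traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluate import Ordination
from .io import Partition
from .perturb import PerturbationTrace


def plot_pcoa(ord_: Ordination, path: str, labels: Partition | None = None) -> None:
    """Scatter the first two principal coordinates, optionally colored by label."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x, y = ord_.coordinates[:, 0], ord_.coordinates[:, 1]
    if labels is not None:
        order = {s: i for i, s in enumerate(labels.sample_ids)}
        c = [labels.labels[order[s]] for s in ord_.sample_ids]
    else:
        c = None
    ax.scatter(x, y, c=c, cmap="coolwarm", s=25, edgecolor="k", linewidth=0.3)
    ax.set_xlabel(f"PCo1 ({100 * ord_.proportion_explained[0]:.1f}%)")
    ax.set_ylabel(f"PCo2 ({100 * ord_.proportion_explained[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trace(trace: PerturbationTrace, path: str) -> None:
    """ARI (with percentile band) and diagnostics along a perturbation sweep."""
    df = trace.to_dataframe()
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    for m in trace.ari_metrics():
        ax1.plot(df["param"], df[f"ari_{m}_median"], marker="o", label=m)
        ax1.fill_between(df["param"], df[f"ari_{m}_lo"], df[f"ari_{m}_hi"], alpha=0.2)
    ax1.set_ylabel("adjusted Rand index")
    ax1.legend()
    ax2.plot(df["param"], df["total_shannon"], color="tab:green", label="total Shannon")
    ax2b = ax2.twinx()
    ax2b.plot(
        df["param"], df["high_abundance_mass"], color="tab:purple",
        label="high-abundance mass",
    )
    ax2.set_xlabel(f"{trace.kind} parameter")
    ax2.set_ylabel("total Shannon (nats)")
    ax2b.set_ylabel("high-abundance mass")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
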
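"""Plot helpers for noise curves and MDS scatters (matplotlib, Agg-safe)."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .robustness import MDSEmbedding, NoiseExperiment

__all__ = ["plot_noise_curve", "plot_mds"]


def plot_noise_curve(experiment: NoiseExperiment, path=None, ax=None):
    """Mean classification-error curve over τ with its 95% band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    taus = experiment.config.tau_grid
    ax.fill_between(taus, experiment.band_low, experiment.band_high, alpha=0.3, label="95% band")
    ax.plot(taus, experiment.mean_curve, color="k", label="mean error")
    ax.set_xlabel("noise sd τ (Å)")
    ax.set_ylabel("classification error")
    ax.set_ylim(0, 1)
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_mds(
    embedding: MDSEmbedding,
    labels: Optional[Sequence[str]] = None,
    path=None,
    ax=None,
):
    """2-D MDS scatter, colour-coded by ligand group when labels are given."""
    if embedding.coordinates.shape[1] < 2:
        raise ValueError("need a 2-D or 3-D embedding")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    xy = embedding.coordinates[:, :2]
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=18)
    else:
        for lab in dict.fromkeys(labels):
            mask = [l == lab for l in labels]
            ax.scatter(xy[mask, 0], xy[mask, 1], s=18, label=lab)
        ax.legend(fontsize=8)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
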
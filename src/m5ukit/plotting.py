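"""Figure helpers (matplotlib, Agg-safe): embedding scatters, effect heatmaps,
logo-style attribution bars and training curves.  All functions return the
Axes and optionally save to file; nothing here is required by the numerical
pipeline."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .seqdata import ALPHABET, CENTER_POSITION

__all__ = ["plot_embedding", "plot_effect_heatmap", "plot_attribution_logo",
           "plot_history", "plot_curves"]

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def plot_embedding(embedding, labels: Sequence[int] | None = None, path=None, ax=None):
    """Scatter of a 2-D layer embedding, coloured by class."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    coords = embedding.coords
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=4, alpha=0.6)
    else:
        labels = np.asarray(labels)
        for lab, color, name in ((0, "#7f7f7f", "negative"), (1, "#d62728", "positive")):
            sel = labels == lab
            ax.scatter(coords[sel, 0], coords[sel, 1], s=4, alpha=0.6,
                       color=color, label=name)
        ax.legend(markerscale=3, frameon=False)
    ax.set_title(f"UMAP: {embedding.layer_name}")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    _finish(fig, path)
    return ax


def plot_effect_heatmap(mem, path=None, ax=None):
    """4x41 mutation-effect heatmap with wild-type cells marked."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(12, 2.2))
    else:
        fig = ax.figure
    vmax = max(np.abs(mem.delta).max(), 1e-12)
    im = ax.imshow(mem.delta.T, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    for i, base in enumerate(mem.seq):
        ax.plot(i, ALPHABET.index(base), marker="s", ms=3, color="black")
    ax.set_yticks(range(4), list(ALPHABET))
    ax.set_xticks(range(0, mem.delta.shape[0], 5), range(1, mem.delta.shape[0] + 1, 5))
    ax.set_xlabel("position")
    ax.set_title(f"{mem.seq_id} (wild-type p = {mem.wt_prob:.3f})")
    fig.colorbar(im, ax=ax, label="Δp")
    _finish(fig, path)
    return ax


def plot_attribution_logo(matrix: np.ndarray, path=None, ax=None, title=""):
    """Logo-style stacked bars of a (L, 4) attribution or composition matrix.

    Per position, positive values stack upward and negative downward, coloured
    by base; the centre position is marked.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(12, 2.5))
    else:
        fig = ax.figure
    L = matrix.shape[0]
    for i in range(L):
        up = down = 0.0
        order = np.argsort(-np.abs(matrix[i]))
        for j in order:
            v = matrix[i, j]
            if v == 0:
                continue
            base = ALPHABET[j]
            if v > 0:
                ax.bar(i + 1, v, bottom=up, color=_BASE_COLORS[base], width=0.8)
                up += v
            else:
                ax.bar(i + 1, v, bottom=down, color=_BASE_COLORS[base], width=0.8)
                down += v
    ax.axvline(CENTER_POSITION, color="black", lw=0.5, ls="--")
    ax.axhline(0, color="black", lw=0.5)
    handles = [plt.Rectangle((0, 0), 1, 1, color=_BASE_COLORS[b]) for b in ALPHABET]
    ax.legend(handles, list(ALPHABET), ncol=4, frameon=False, fontsize=8)
    ax.set_xlabel("position")
    ax.set_title(title)
    _finish(fig, path)
    return ax


def plot_history(histories, path=None, ax=None):
    """Per-member training/validation loss curves."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    for i, h in enumerate(histories):
        epochs = np.arange(1, len(h.train_loss) + 1)
        ax.plot(epochs, h.train_loss, color="C0", alpha=0.6,
                label="train" if i == 0 else None)
        if h.val_loss:
            ax.plot(epochs, h.val_loss, color="C1", alpha=0.6,
                    label="validation" if i == 0 else None)
    ax.set_xlabel("epoch")
    ax.set_ylabel("binary cross-entropy")
    ax.legend(frameon=False)
    _finish(fig, path)
    return ax


def plot_curves(roc, pr, path=None):
    """Side-by-side ROC and PR curves."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(roc.x, roc.y)
    ax1.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax1.set_xlabel("false positive rate")
    ax1.set_ylabel("true positive rate")
    ax1.set_title("ROC")
    ax2.plot(pr.x, pr.y)
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.set_title("PR")
    _finish(fig, path)
    return fig
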
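"""Plotting helpers: PCA embeddings, ROC curves, emergence heatmaps."""

from __future__ import annotations

import numpy as np


def plot_embedding(pca_result, groups, ax=None):
    """2-D scatter of PCA scores colored by group label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scores = pca_result.scores
    for g in dict.fromkeys(groups):
        sel = np.array([x == g for x in groups])
        ax.scatter(scores[sel, 0], scores[sel, 1], label=g, s=25)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    return ax


def plot_roc(roc_points, auc=None, ax=None):
    """ROC curve with the chance diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = np.asarray(roc_points)
    label = f"AUC = {auc:.3f}" if auc is not None else None
    ax.plot(pts[:, 0], pts[:, 1], label=label)
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    if label:
        ax.legend()
    return ax


def plot_emergence_heatmap(traj, reference_power: float = 1.0, ax=None,
                           fmax: float = 50.0):
    """Per-bin spectra over the 0-100% arousal axis on a fixed dB scale."""
    import matplotlib.pyplot as plt

    from .eegsignal import trajectory_heatmap

    if ax is None:
        _, ax = plt.subplots()
    freqs, arousal, db = trajectory_heatmap(traj, reference_power)
    sel = freqs <= fmax
    im = ax.pcolormesh(arousal, freqs[sel], db[sel], vmin=-20, vmax=20,
                       shading="nearest", cmap="viridis")
    ax.set_xlabel("Arousal progression (%)")
    ax.set_ylabel("Frequency (Hz)")
    plt.colorbar(im, ax=ax, label="Power (dB)")
    return ax
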
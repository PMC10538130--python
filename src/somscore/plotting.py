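"""Line/bar plot conveniences for DS trajectories and index scans.

Plots are diagnostics only; every number they show is available from the
CSV/JSON outputs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .discriminant import DSMatrix
from .indices import IndexReport, SilhouetteResult


def plot_ds_trajectory(ds: DSMatrix, path, title: str | None = None) -> None:
    """One line per cluster of DS over frames, transitions as vertical rules."""
    fig, ax = plt.subplots(figsize=(10, 4))
    t = np.arange(ds.n_frames)
    for m in range(ds.n_clusters):
        ax.plot(t, ds.scores[:, m], lw=1.0, label=f"cluster {m}")
    for fr in ds.transitions:
        ax.axvline(fr, color="0.6", lw=0.6, ls="--")
    ax.set_xlabel("frame")
    ax.set_ylabel("discriminant score")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="upper right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_index_bars(reports: list[IndexReport], path) -> None:
    """Per-k bar charts of the four indices plus QE."""
    ks = [r.k for r in reports]
    panels = [
        ("mean silhouette", [r.silhouette_mean for r in reports]),
        ("Dunn (centroid)", [r.dunn for r in reports]),
        ("Davies-Bouldin", [r.davies_bouldin for r in reports]),
        ("Calinski-Harabasz", [r.calinski_harabasz for r in reports]),
        ("quantization error", [r.quantization_error for r in reports]),
    ]
    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3))
    for ax, (name, vals) in zip(axes, panels):
        ax.bar([str(k) for k in ks], vals, color="tab:blue")
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("k")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_silhouette_panel(sil: SilhouetteResult, assignments, path, k: int | None = None) -> None:
    """Sorted per-cluster silhouette bars with the mean as a reference line."""
    labels = np.asarray(assignments)
    fig, ax = plt.subplots(figsize=(5, 4))
    y = 0
    for m in np.unique(labels):
        vals = np.sort(sil.sc[labels == m])
        ax.barh(np.arange(y, y + vals.size), vals, height=1.0, label=f"cluster {m}")
        y += vals.size + 2
    ax.axvline(sil.mean_sc, color="red", lw=1.0)
    ax.set_xlabel("silhouette value")
    ax.set_yticks([])
    if k is not None:
        ax.set_title(f"k = {k}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
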
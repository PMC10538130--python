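"""Cluster bookkeeping: assignments, per-cluster centroids and sizes.

A :class:`ClusterModel` is the common currency between the SOM engine, the
validity indices and the discriminant score.  Centroids come either from the
per-cluster data means (the default used by all scores) or directly from the
SOM neuron weights.  Empty clusters are *kept* — a trained map routinely
leaves dead neurons — with size 0 and an undefined (NaN) centroid; consumers
flag or reject them explicitly rather than silently renumbering clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CENTROID_SOURCES = ("data_means", "neuron_weights")


@dataclass
class ClusterModel:
    n_clusters: int
    assignments: np.ndarray          # (N,) int, values in [0, n_clusters)
    centroids: np.ndarray            # (M, D); NaN rows mark undefined centroids
    sizes: np.ndarray                # (M,) int, sums to N
    global_centroid: np.ndarray      # (D,) mean of all rows
    source: str = "data_means"
    data: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return int(self.assignments.size)

    @property
    def empty(self) -> np.ndarray:
        """Boolean mask of clusters with no assigned samples."""
        return self.sizes == 0

    @property
    def singletons(self) -> np.ndarray:
        return self.sizes == 1

    def members(self, m: int) -> np.ndarray:
        """Row indices assigned to cluster ``m``."""
        return np.flatnonzero(self.assignments == m)


def build_cluster_model(
    data,
    assignments,
    n_clusters: int | None = None,
    source: str = "data_means",
    weights=None,
) -> ClusterModel:
    """Assemble a :class:`ClusterModel` from data rows and cluster labels.

    Parameters
    ----------
    data
        (N, D) matrix of feature vectors (flattened skeleton frames).
    assignments
        Length-N integer labels in ``[0, n_clusters)``.
    n_clusters
        Number of clusters M; defaults to ``max(assignments) + 1``.
    source
        ``"data_means"`` computes each centroid as the arithmetic mean of its
        assigned rows (empty clusters get NaN centroids); ``"neuron_weights"``
        uses the supplied ``weights`` rows verbatim.
    weights
        (M, D) neuron weight matrix, required when ``source="neuron_weights"``.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    labels = np.asarray(assignments, dtype=int)
    if labels.ndim != 1 or labels.size != X.shape[0]:
        raise ValueError(
            f"assignments must be one label per row: {labels.shape} vs N={X.shape[0]}"
        )
    if labels.size and labels.min() < 0:
        raise ValueError("negative cluster index")
    if source not in CENTROID_SOURCES:
        raise ValueError(f"source must be one of {CENTROID_SOURCES}, got {source!r}")

    M = int(n_clusters) if n_clusters is not None else int(labels.max()) + 1
    if labels.size and labels.max() >= M:
        raise ValueError(
            f"assignment index {labels.max()} >= n_clusters={M}"
        )

    sizes = np.bincount(labels, minlength=M)

    if source == "neuron_weights":
        if weights is None:
            raise ValueError("source='neuron_weights' requires weights")
        W = np.atleast_2d(np.asarray(weights, dtype=float))
        if W.shape != (M, X.shape[1]):
            raise ValueError(
                f"weights shape {W.shape} != (M={M}, D={X.shape[1]})"
            )
        centroids = W.copy()
    else:
        centroids = np.full((M, X.shape[1]), np.nan)
        for m in range(M):
            if sizes[m] > 0:
                centroids[m] = X[labels == m].mean(axis=0)

    return ClusterModel(
        n_clusters=M,
        assignments=labels,
        centroids=centroids,
        sizes=sizes,
        global_centroid=X.mean(axis=0),
        source=source,
        data=X,
    )
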
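"""Classical cluster-validity indices, in the exact forms used for posture scoring.

Four internal indices plus the SOM quantization error are aggregated into one
:class:`IndexReport` per candidate cluster count:

* silhouette coefficient — per-sample (b_min - a) / max(a, b_min), in [-1, 1];
* Dunn index, *centroid variant* — the numerator is the minimum distance
  between cluster centroids (not the classical point-wise minimum), the
  denominator the largest intra-cluster pairwise distance;
* Davies-Bouldin index, *sum form* — the per-cluster maxima of
  (av(m) + av(m1)) / d(cc_m, cc_m1) are summed over clusters (no 1/M); the
  classical mean form is available as a variant (the two differ by the factor
  M and rank identically at fixed M);
* Calinski-Harabasz index — between/within dispersion ratio, always Euclidean.

Degenerate situations (empty clusters, all-singleton clusterings, coincident
centroids) are reported through flags rather than silently patched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterModel
from .metrics import Metric, pairwise_distances

DB_VARIANTS = ("paper_sum", "mean")


@dataclass
class SilhouetteResult:
    """Per-sample silhouette decomposition."""

    a_bar: np.ndarray      # mean distance to co-members (0 for singletons)
    b_min: np.ndarray      # min mean distance to another cluster
    sc: np.ndarray         # per-sample silhouette in [-1, 1]
    mean_sc: float


@dataclass
class IndexReport:
    """All scores for one cluster count k, with degeneracy flags."""

    k: int
    silhouette_mean: float
    dunn: float
    davies_bouldin: float
    dbi_variant: str
    calinski_harabasz: float
    quantization_error: float
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "k": self.k,
            "sc_mean": self.silhouette_mean,
            "dunn": self.dunn,
            "dbi": self.davies_bouldin,
            "dbi_variant": self.dbi_variant,
            "ch": self.calinski_harabasz,
            "qe": self.quantization_error,
            "flags": ";".join(self.flags),
        }


def _check_data(clusters: ClusterModel, data) -> np.ndarray:
    if data is not None:
        return np.atleast_2d(np.asarray(data, dtype=float))
    if clusters.data is None:
        raise ValueError("no data: pass data explicitly or build the model with data")
    return clusters.data


def silhouette_values(
    data, clusters: ClusterModel, metric: Metric | str = Metric.EUCLIDEAN
) -> SilhouetteResult:
    """Per-sample silhouette coefficients.

    a is the mean distance from a sample to the other members of its own
    cluster; b_min the smallest mean distance to the members of any other
    (non-empty) cluster; sc = (b_min - a)/max(a, b_min).  Samples in
    singleton clusters get sc = 0 by convention.
    """
    X = _check_data(clusters, data)
    metric = Metric.coerce(metric)
    labels, sizes = clusters.assignments, clusters.sizes
    nonempty = np.flatnonzero(sizes > 0)
    if nonempty.size < 2:
        raise ValueError("silhouette undefined for fewer than 2 non-empty clusters")

    D = pairwise_distances(X, X, metric)
    N = X.shape[0]
    # sum of distances from each sample to every cluster, via one-hot grouping
    onehot = np.zeros((N, clusters.n_clusters))
    onehot[np.arange(N), labels] = 1.0
    cluster_sums = D @ onehot                      # (N, M)

    own_size = sizes[labels].astype(float)
    a_bar = np.zeros(N)
    non_single = own_size > 1
    a_bar[non_single] = (
        cluster_sums[np.arange(N), labels][non_single] / (own_size[non_single] - 1)
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        means = cluster_sums / sizes[None, :].astype(float)   # NaN for empty clusters
    means[np.arange(N), labels] = np.inf                      # exclude own cluster
    means[:, sizes == 0] = np.inf
    b_min = means.min(axis=1)

    sc = np.zeros(N)
    denom = np.maximum(a_bar, b_min)
    valid = non_single & (denom > 0)
    sc[valid] = (b_min[valid] - a_bar[valid]) / denom[valid]
    return SilhouetteResult(a_bar=a_bar, b_min=b_min, sc=sc, mean_sc=float(sc.mean()))


def dunn_index(
    data, clusters: ClusterModel, metric: Metric | str = Metric.EUCLIDEAN
) -> float:
    """Centroid-variant Dunn index.

    Numerator: minimum distance between (defined) cluster centroids.
    Denominator: maximum intra-cluster pairwise distance over all clusters
    (singletons contribute 0).  All-singleton clusterings make the
    denominator 0: returns +inf as the degenerate sentinel.
    """
    X = _check_data(clusters, data)
    metric = Metric.coerce(metric)
    nonempty = np.flatnonzero(clusters.sizes > 0)
    if nonempty.size < 2:
        raise ValueError("Dunn index needs >= 2 non-empty clusters")
    C = clusters.centroids[nonempty]
    dc = pairwise_distances(C, C, metric)
    np.fill_diagonal(dc, np.inf)
    d_cmin = float(dc.min())

    d_max = 0.0
    for m in nonempty:
        members = X[clusters.assignments == m]
        if members.shape[0] >= 2:
            d_max = max(d_max, float(pairwise_distances(members, members, metric).max()))
    if d_max == 0.0:
        return float("inf")
    return d_cmin / d_max


def davies_bouldin(
    data, clusters: ClusterModel, metric: Metric | str = Metric.EUCLIDEAN,
    variant: str = "paper_sum",
) -> float:
    """Davies-Bouldin index over the non-empty clusters.

    ``variant="paper_sum"`` (default) sums the per-cluster maxima of the
    pairwise similarity ratio; ``"mean"`` divides that sum by the number of
    clusters (the classical form, matching reference implementations).
    Coincident centroids return +inf (degenerate).
    """
    if variant not in DB_VARIANTS:
        raise ValueError(f"variant must be one of {DB_VARIANTS}, got {variant!r}")
    X = _check_data(clusters, data)
    metric = Metric.coerce(metric)
    nonempty = np.flatnonzero(clusters.sizes > 0)
    if nonempty.size < 2:
        raise ValueError("Davies-Bouldin needs >= 2 non-empty clusters")

    av = np.array([
        pairwise_distances(
            X[clusters.assignments == m], clusters.centroids[m][None, :], metric
        ).mean()
        for m in nonempty
    ])
    C = clusters.centroids[nonempty]
    dcc = pairwise_distances(C, C, metric)
    if np.any(dcc[~np.eye(len(nonempty), dtype=bool)] == 0.0):
        return float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (av[:, None] + av[None, :]) / dcc
    np.fill_diagonal(ratio, -np.inf)
    davmax = ratio.max(axis=1)
    total = float(davmax.sum())
    return total / len(nonempty) if variant == "mean" else total


def calinski_harabasz(data, clusters: ClusterModel) -> float:
    """Calinski-Harabasz variance-ratio criterion (Euclidean by definition).

    CH = [sum_m K_m |cc_m - c|^2 / (M-1)] / [sum_m sum_j |f_j - cc_m|^2 / (N-M)]
    over the non-empty clusters.  Zero within-cluster dispersion returns +inf.
    """
    X = _check_data(clusters, data)
    nonempty = np.flatnonzero(clusters.sizes > 0)
    M, N = nonempty.size, X.shape[0]
    if M < 2:
        raise ValueError("Calinski-Harabasz needs >= 2 non-empty clusters")
    if N <= M:
        raise ValueError(f"Calinski-Harabasz requires N > M (N={N}, M={M})")
    c = clusters.global_centroid
    between = sum(
        clusters.sizes[m] * float(np.sum((clusters.centroids[m] - c) ** 2))
        for m in nonempty
    )
    within = sum(
        float(np.sum((X[clusters.assignments == m] - clusters.centroids[m]) ** 2))
        for m in nonempty
    )
    if within == 0.0:
        return float("inf")
    return (between / (M - 1)) / (within / (N - M))


def compute_report(
    data, clusters: ClusterModel, som=None,
    metric: Metric | str | None = None, db_variant: str = "paper_sum",
) -> IndexReport:
    """Assemble all five scores into one record with degeneracy flags.

    ``metric`` drives silhouette, Dunn and Davies-Bouldin (defaulting to the
    SOM's training metric when a model is given, else Euclidean); CH is
    always Euclidean, and QE follows the SOM model's own metric.  Index
    failures become flags — no score is silently dropped.
    """
    from .som import quantization_error  # local import to avoid cycle

    X = _check_data(clusters, data)
    if metric is None:
        metric = som.metric if som is not None else Metric.EUCLIDEAN
    metric = Metric.coerce(metric)
    flags: list[str] = []
    if np.any(clusters.empty):
        flags.append("empty_cluster")
    if np.any(clusters.singletons):
        flags.append("singleton_cluster")

    def safe(name, fn):
        try:
            v = fn()
        except ValueError as exc:
            flags.append(f"{name}_error:{exc}")
            return float("nan")
        if not np.isfinite(v):
            flags.append(f"{name}_degenerate")
        return float(v)

    sc = safe("silhouette", lambda: silhouette_values(X, clusters, metric).mean_sc)
    di = safe("dunn", lambda: dunn_index(X, clusters, metric))
    db = safe("davies_bouldin", lambda: davies_bouldin(X, clusters, metric, db_variant))
    ch = safe("calinski_harabasz", lambda: calinski_harabasz(X, clusters))
    qe = (
        safe("quantization_error", lambda: quantization_error(X, som))
        if som is not None
        else float("nan")
    )
    return IndexReport(
        k=clusters.n_clusters,
        silhouette_mean=sc,
        dunn=di,
        davies_bouldin=db,
        dbi_variant=db_variant,
        calinski_harabasz=ch,
        quantization_error=qe,
        flags=flags,
    )
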
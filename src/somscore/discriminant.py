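"""Discriminant score (DS): per-frame, per-cluster membership trajectories.

For a frame f and cluster centroids cc_1..cc_M with distances
d_m = d(f, cc_m) under the chosen metric, the discriminant score of
cluster m is the *normalized inverse distance*

    DS_m = (1 / d_m) / sum_m' (1 / d_m'),

with the limit branch DS_m = 1 (others 0) when f coincides with cc_m.
Scores lie in [0, 1] and sum to 1 over clusters, so each frame carries a
full membership profile rather than a single hard label.  Tracked over a
recording, the M trajectories expose posture structure directly:

* the per-frame argmax is the *winning* cluster;
* frames where the winner changes are posture *transitions* (a steep drop
  of the outgoing trajectory against a steep rise of the incoming one);
* a cluster's *peak* (its maximum DS over the frames it wins) says how
  decisively it ever represents a posture, and its *dwell fraction* (share
  of frames won) says whether that posture persists or is transient.

Low peaks and tiny dwell fractions are the signature of superfluous
clusters, which is what the k-selection rule exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterModel
from .metrics import Metric, pairwise_distances
from .skeleton import PostureSequence


@dataclass
class DSMatrix:
    """T x M discriminant scores plus derived winner/transition statistics."""

    scores: np.ndarray                 # (T, M), rows sum to 1
    metric: Metric
    winner: np.ndarray                 # (T,) smoothed winning-cluster index
    raw_winner: np.ndarray             # (T,) unsmoothed per-frame argmax
    transitions: np.ndarray            # strictly increasing frame indices
    peak: np.ndarray                   # (M,) max DS over frames the cluster wins
    peak_all_frames: np.ndarray        # (M,) max DS over all frames
    dwell: np.ndarray                  # (M,) fraction of frames won, sums to 1
    smooth_window: int = 1
    fps: float | None = None

    @property
    def n_frames(self) -> int:
        return int(self.scores.shape[0])

    @property
    def n_clusters(self) -> int:
        return int(self.scores.shape[1])


# Distances below this are rounding noise (cosine self-distance is ~1e-16,
# never exactly 0); treated as exact coincidence with the centroid.
ZERO_TOL = 1e-12


def _ds_from_distances(d: np.ndarray) -> np.ndarray:
    """Rows of normalized inverse distances; (near-)zero rows become one-hot."""
    T, M = d.shape
    out = np.empty((T, M))
    zero = d <= ZERO_TOL
    nz_rows = ~zero.any(axis=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[nz_rows]
    out[nz_rows] = inv / inv.sum(axis=1, keepdims=True)
    for k in np.flatnonzero(zero.any(axis=1)):
        hits = np.flatnonzero(zero[k])
        if hits.size > 1:
            raise ValueError(
                f"frame {k}: coincident centroids (distance 0 to clusters {hits.tolist()})"
            )
        row = np.zeros(M)
        row[hits[0]] = 1.0
        out[k] = row
    return out


def ds_vector(f, clusters: ClusterModel, metric: Metric | str = Metric.COSINE) -> np.ndarray:
    """Discriminant scores of one frame against all M cluster centroids.

    Requires every centroid to be defined (no empty data-mean clusters);
    substitute prototypes first if the model has dead clusters.
    """
    fv = np.asarray(f, dtype=float).ravel()
    if np.any(~np.isfinite(clusters.centroids)):
        raise ValueError(
            "undefined (NaN) centroid: empty cluster under data_means; "
            "substitute a prototype before scoring"
        )
    d = pairwise_distances(fv[None, :], clusters.centroids, Metric.coerce(metric))
    return _ds_from_distances(d)[0]


def winner_sequence(scores, smooth_window: int = 1) -> np.ndarray:
    """Per-frame argmax (ties to the lowest index), then centered mode filter.

    The mode filter uses an odd window with edge replication; ties in the
    window mode also break to the lowest cluster index.  ``smooth_window=1``
    means no smoothing.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    T = S.shape[0]
    if smooth_window > T:
        raise ValueError(f"smooth_window {smooth_window} exceeds sequence length {T}")
    raw = np.argmax(S, axis=1)
    if smooth_window == 1:
        return raw
    half = smooth_window // 2
    padded = np.concatenate([np.full(half, raw[0]), raw, np.full(half, raw[-1])])
    out = np.empty(T, dtype=int)
    for t in range(T):
        out[t] = np.argmax(np.bincount(padded[t : t + smooth_window]))
    return out


def detect_transitions(winner) -> np.ndarray:
    """Frame indices t >= 1 where the winning cluster changes."""
    w = np.asarray(winner, dtype=int)
    if w.size == 0:
        raise ValueError("empty winner sequence")
    return np.flatnonzero(np.diff(w) != 0) + 1


def peak_dwell_stats(scores, winner, n_clusters: int | None = None):
    """Per-cluster (peak over winning frames, all-frames peak, dwell fraction).

    The peak of a cluster that never wins is 0 — the all-frames maximum is
    reported alongside for transparency.  Dwell fractions partition the
    frames, so they sum to 1.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    w = np.asarray(winner, dtype=int)
    M = int(n_clusters) if n_clusters is not None else S.shape[1]
    T = S.shape[0]
    peak = np.zeros(M)
    dwell = np.zeros(M)
    for m in range(M):
        wins = w == m
        dwell[m] = wins.sum() / T
        if wins.any():
            peak[m] = S[wins, m].max()
    peak_all = S[:, :M].max(axis=0) if S.size else np.zeros(M)
    return peak, peak_all, dwell


def ds_trajectory(
    seq: PostureSequence | np.ndarray,
    clusters: ClusterModel,
    metric: Metric | str = Metric.COSINE,
    smooth_window: int = 5,
) -> DSMatrix:
    """Full DS analysis of a sequence: scores, winners, transitions, peaks.

    Default winner smoothing is a 5-frame mode filter (~0.33 s at 15 fps),
    suppressing single-frame winner chatter without masking real
    transitions; pass ``smooth_window=1`` for unordered data.
    """
    metric = Metric.coerce(metric)
    if isinstance(seq, PostureSequence):
        X, fps = seq.frames, seq.fps
    else:
        X, fps = np.atleast_2d(np.asarray(seq, dtype=float)), None
    if X.shape[0] == 0:
        raise ValueError("empty sequence")
    if np.any(~np.isfinite(clusters.centroids)):
        raise ValueError("undefined centroid (empty cluster); substitute a prototype")
    d = pairwise_distances(X, clusters.centroids, metric)
    scores = _ds_from_distances(d)
    raw = winner_sequence(scores, 1)
    T = X.shape[0]
    eff_window = min(smooth_window, T if T % 2 else T - 1) if T > 1 else 1
    win = winner_sequence(scores, eff_window)
    peak, peak_all, dwell = peak_dwell_stats(scores, win, clusters.n_clusters)
    return DSMatrix(
        scores=scores,
        metric=metric,
        winner=win,
        raw_winner=raw,
        transitions=detect_transitions(win),
        peak=peak,
        peak_all_frames=peak_all,
        dwell=dwell,
        smooth_window=smooth_window,
        fps=fps,
    )
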
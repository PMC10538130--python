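"""Cluster-count selection: scan candidate k, score each, apply the peak rule.

The selection rule formalizes how a posture analyst reads a family of
discriminant-score trajectories: a candidate k is *acceptable* when every
cluster both (a) reaches a decisive peak — its maximum DS over the frames it
wins is at least ``theta_peak`` — and (b) persists — its dwell fraction is at
least ``theta_dwell``.  Superfluous clusters betray themselves by flat, low
trajectories or vanishing dwell ("unknown" neurons); among the acceptable
candidates the default rule keeps the *largest* k, i.e. the richest posture
vocabulary that remains well discriminated, so no key posture is dropped.

The default ``theta_peak = 0.5`` is the smallest round threshold that
separates decisive posture peaks from the flat trajectories of superfluous
clusters in worked examples of this kind; both thresholds are configuration,
not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterModel, build_cluster_model
from .discriminant import DSMatrix, ds_trajectory
from .indices import IndexReport, compute_report
from .metrics import Metric
from .skeleton import PostureSequence
from .som import SOMModel, TrainingConfig, train_som, assign_clusters, quantization_error

RULES = ("largest_passing_k", "best_min_peak")


@dataclass
class SelectionCriteria:
    theta_peak: float = 0.5
    theta_dwell: float = 0.05
    rule: str = "largest_passing_k"

    def validate(self) -> None:
        if not (0.0 < self.theta_peak < 1.0):
            raise ValueError("theta_peak must lie in (0, 1)")
        if not (0.0 < self.theta_dwell < 1.0):
            raise ValueError("theta_dwell must lie in (0, 1)")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")


@dataclass
class KVerdict:
    """Audit record for one candidate k."""

    k: int
    passed: bool
    min_peak: float
    min_dwell: float | None
    failing_clusters: list[int]
    reasons: list[str]


@dataclass
class Recommendation:
    chosen_k: int | None
    criteria: SelectionCriteria
    per_k: list[KVerdict]
    ch_argmax: int | None = None
    ch_disagrees: bool = False

    def verdict(self, k: int) -> KVerdict:
        for v in self.per_k:
            if v.k == k:
                return v
        raise KeyError(k)

    def as_dict(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "criteria": {
                "theta_peak": self.criteria.theta_peak,
                "theta_dwell": self.criteria.theta_dwell,
                "rule": self.criteria.rule,
            },
            "ch_argmax": self.ch_argmax,
            "ch_disagrees": self.ch_disagrees,
            "per_k": [
                {
                    "k": v.k,
                    "pass": v.passed,
                    "min_peak": v.min_peak,
                    "min_dwell": v.min_dwell,
                    "failing_clusters": v.failing_clusters,
                    "reasons": v.reasons,
                }
                for v in self.per_k
            ],
        }


@dataclass
class KScanRecord:
    """Everything computed for one candidate k during a scan."""

    k: int
    som: SOMModel
    clusters: ClusterModel
    report: IndexReport
    ds: DSMatrix


def recommend_k(peaks_dwells: dict, criteria: SelectionCriteria | None = None) -> Recommendation:
    """Apply the peak/dwell acceptance rule to per-k per-cluster statistics.

    ``peaks_dwells`` maps each candidate k to either ``(peaks, dwells)`` or
    just ``peaks`` (dwell check skipped — e.g. when scoring a printed peak
    table).  A k passes iff min(peaks) >= theta_peak and, when dwell data is
    present, min(dwells) >= theta_dwell.  ``largest_passing_k`` returns the
    maximum passing candidate; ``best_min_peak`` the passing candidate whose
    minimum peak is largest.  With no passing candidate, ``chosen_k`` is
    None and the per-k audit explains each failure.
    """
    criteria = criteria or SelectionCriteria()
    criteria.validate()
    if not peaks_dwells:
        raise ValueError("no candidate cluster counts supplied")

    verdicts: list[KVerdict] = []
    for k in sorted(peaks_dwells):
        entry = peaks_dwells[k]
        if isinstance(entry, tuple):
            peaks, dwells = entry
        else:
            peaks, dwells = entry, None
        peaks = np.asarray(peaks, dtype=float)
        if peaks.size != k:
            raise ValueError(f"k={k}: expected {k} per-cluster peaks, got {peaks.size}")
        failing: list[int] = []
        reasons: list[str] = []
        min_peak = float(peaks.min())
        for m in np.flatnonzero(peaks < criteria.theta_peak):
            failing.append(int(m))
            reasons.append(
                f"cluster {m}: peak DS {peaks[m]:.3g} < theta_peak {criteria.theta_peak}"
            )
        min_dwell = None
        if dwells is not None:
            dw = np.asarray(dwells, dtype=float)
            min_dwell = float(dw.min())
            for m in np.flatnonzero(dw < criteria.theta_dwell):
                if int(m) not in failing:
                    failing.append(int(m))
                reasons.append(
                    f"cluster {m}: dwell {dw[m]:.3g} < theta_dwell {criteria.theta_dwell}"
                )
        verdicts.append(
            KVerdict(
                k=int(k),
                passed=not reasons,
                min_peak=min_peak,
                min_dwell=min_dwell,
                failing_clusters=sorted(set(failing)),
                reasons=reasons,
            )
        )

    passing = [v for v in verdicts if v.passed]
    if not passing:
        chosen = None
    elif criteria.rule == "largest_passing_k":
        chosen = max(v.k for v in passing)
    else:  # best_min_peak
        chosen = max(passing, key=lambda v: (v.min_peak, v.k)).k
    return Recommendation(chosen_k=chosen, criteria=criteria, per_k=verdicts)


def scan_k(
    data,
    seq: PostureSequence | None = None,
    k_candidates=(3, 4, 5, 6),
    metric: Metric | str = Metric.COSINE,
    som_config: TrainingConfig | None = None,
    base_seed: int = 0,
    smooth_window: int = 1,
    centroid_source: str = "data_means",
    n_restarts: int = 1,
) -> dict[int, KScanRecord]:
    """Train one map per candidate k and compute all scores for each.

    Each k trains independently with seed ``base_seed + k`` (restarts, if
    requested, add 1000*r and keep the lowest-QE run).  DS centroids are the
    per-cluster data means; a cluster left empty by the map falls back to
    its neuron weight — the only prototype a dead neuron has.  Winner
    smoothing defaults to off because a scan may run on unordered frames;
    pass an odd window > 1 for temporal sequences.
    """
    metric = Metric.coerce(metric)
    X = np.atleast_2d(np.asarray(data, dtype=float))
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks:
        raise ValueError("no candidate cluster counts")
    if min(ks) < 2:
        raise ValueError("candidates must be >= 2")
    if max(ks) >= X.shape[0]:
        raise ValueError(f"candidate k={max(ks)} >= N={X.shape[0]}")
    frames = seq.frames if seq is not None else X
    if seq is not None and seq.frames.shape != X.shape:
        raise ValueError("seq and data disagree in shape")

    base_config = som_config or TrainingConfig()
    records: dict[int, KScanRecord] = {}
    for k in ks:
        best = None
        for r in range(max(1, n_restarts)):
            cfg = TrainingConfig(**{**base_config.__dict__, "seed": base_seed + k + 1000 * r})
            som = train_som(X, k, metric=metric, config=cfg)
            qe = quantization_error(X, som)
            if best is None or qe < best[0]:
                best = (qe, som)
        som = best[1]
        labels = assign_clusters(X, som)
        clusters = build_cluster_model(X, labels, n_clusters=k, source=centroid_source,
                                       weights=som.weights if centroid_source == "neuron_weights" else None)
        ds_clusters = clusters
        if centroid_source == "data_means" and np.any(clusters.empty):
            # dead neurons have no data mean; score them by their weight vector
            centroids = clusters.centroids.copy()
            centroids[clusters.empty] = som.weights[clusters.empty]
            ds_clusters = ClusterModel(
                n_clusters=k, assignments=labels, centroids=centroids,
                sizes=clusters.sizes, global_centroid=clusters.global_centroid,
                source="data_means", data=X,
            )
        report = compute_report(X, clusters, som=som, metric=metric)
        ds = ds_trajectory(frames, ds_clusters, metric=metric, smooth_window=smooth_window)
        records[k] = KScanRecord(k=k, som=som, clusters=clusters, report=report, ds=ds)
    return records


def recommend_from_scan(
    records: dict[int, KScanRecord], criteria: SelectionCriteria | None = None
) -> Recommendation:
    """Run :func:`recommend_k` on a scan and cross-check against CH's argmax.

    The variance-ratio (Calinski-Harabasz) argmax over the same candidates is
    attached; when it disagrees with the DS recommendation the disagreement
    is flagged, not resolved — the two criteria weigh different evidence.
    """
    stats = {k: (rec.ds.peak, rec.ds.dwell) for k, rec in records.items()}
    rec = recommend_k(stats, criteria)
    ch = {k: r.report.calinski_harabasz for k, r in records.items()
          if np.isfinite(r.report.calinski_harabasz)}
    if ch:
        rec.ch_argmax = max(ch, key=ch.get)
        rec.ch_disagrees = rec.chosen_k is not None and rec.ch_argmax != rec.chosen_k
    return rec
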
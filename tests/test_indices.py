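import numpy as np
import pytest

from somscore import (
    Metric,
    SOMModel,
    build_cluster_model,
    calinski_harabasz,
    compute_report,
    davies_bouldin,
    dunn_index,
    silhouette_values,
)
from _oracles import (
    brute_calinski_harabasz,
    brute_davies_bouldin,
    brute_silhouette,
    random_labeled_dataset,
)


def test_toy_silhouette_hand_value(toy_ab):
    X, _, cm = toy_ab
    res = silhouette_values(X, cm, Metric.EUCLIDEAN)
    # a = 1, b = (10 + sqrt(101))/2 for every point
    b = (10 + np.sqrt(101)) / 2
    expected = (b - 1) / b
    np.testing.assert_allclose(res.sc, expected, atol=1e-12)
    assert res.mean_sc == pytest.approx(0.9002, abs=1e-4)


def test_silhouette_perfect_cohesion_duplicate_point():
    X = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0], [9.5, 9.0]])
    cm = build_cluster_model(X, [0, 0, 1, 1])
    res = silhouette_values(X, cm, Metric.EUCLIDEAN)
    assert res.sc[0] == pytest.approx(1.0)  # a = 0 -> sc = 1


def test_silhouette_singletons_zero_by_convention():
    X = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
    cm = build_cluster_model(X, [0, 1, 2])
    res = silhouette_values(X, cm, Metric.EUCLIDEAN)
    np.testing.assert_array_equal(res.sc, np.zeros(3))


def test_silhouette_requires_two_clusters():
    X = np.eye(3)
    with pytest.raises(ValueError):
        silhouette_values(X, build_cluster_model(X, [0, 0, 0]), Metric.EUCLIDEAN)


def test_toy_dunn_hand_value(toy_ab):
    X, _, cm = toy_ab
    assert dunn_index(X, cm, Metric.EUCLIDEAN) == pytest.approx(10.0)


def test_dunn_monotone_in_cluster_separation(toy_ab):
    X, labels, cm = toy_ab
    X2 = X.copy()
    X2[labels == 1, 0] += 15.0
    cm2 = build_cluster_model(X2, labels)
    assert dunn_index(X2, cm2, Metric.EUCLIDEAN) > dunn_index(X, cm, Metric.EUCLIDEAN)


def test_dunn_zero_for_identical_centroids():
    X = np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 0.5], [0.0, 1.5]])
    cm = build_cluster_model(X, [0, 0, 1, 1])  # both centroids at (0, 1)
    assert dunn_index(X, cm, Metric.EUCLIDEAN) == 0.0


def test_dunn_all_singletons_degenerate():
    X = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
    cm = build_cluster_model(X, [0, 1, 2])
    assert dunn_index(X, cm, Metric.EUCLIDEAN) == np.inf


def test_toy_davies_bouldin_sum_and_mean(toy_ab):
    X, _, cm = toy_ab
    assert davies_bouldin(X, cm, Metric.EUCLIDEAN, "paper_sum") == pytest.approx(0.2)
    assert davies_bouldin(X, cm, Metric.EUCLIDEAN, "mean") == pytest.approx(0.1)


def test_db_sum_equals_m_times_mean(rng):
    for _ in range(20):
        X, labels = random_labeled_dataset(rng)
        cm = build_cluster_model(X, labels)
        M = len(set(labels.tolist()))
        s = davies_bouldin(X, cm, Metric.EUCLIDEAN, "paper_sum")
        m = davies_bouldin(X, cm, Metric.EUCLIDEAN, "mean")
        assert s == pytest.approx(M * m, rel=1e-12)


def test_db_coincident_centroids_degenerate():
    X = np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 0.5], [0.0, 1.5]])
    cm = build_cluster_model(X, [0, 0, 1, 1])
    assert davies_bouldin(X, cm, Metric.EUCLIDEAN) == np.inf


def test_toy_calinski_harabasz_hand_value(toy_ab):
    X, _, cm = toy_ab
    assert calinski_harabasz(X, cm) == pytest.approx(200.0)


def test_ch_requires_n_greater_than_m():
    X = np.eye(3)
    with pytest.raises(ValueError):
        calinski_harabasz(X, build_cluster_model(X, [0, 1, 2]))


def test_ch_invariant_under_rigid_rotation(rng):
    X, labels = random_labeled_dataset(rng)
    theta = 0.7
    D = X.shape[1]
    R = np.eye(D)
    R[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    ch1 = calinski_harabasz(X, build_cluster_model(X, labels))
    ch2 = calinski_harabasz(X @ R.T, build_cluster_model(X @ R.T, labels))
    assert ch2 == pytest.approx(ch1, rel=1e-9)


def test_oracle_equivalence_brute_force_and_sklearn(rng):
    """SC / CH / DB(mean) match a brute-force loop and sklearn on 200 datasets."""
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_samples,
    )

    for _ in range(200):
        X, labels = random_labeled_dataset(rng)
        cm = build_cluster_model(X, labels)

        sc = silhouette_values(X, cm, Metric.EUCLIDEAN).sc
        np.testing.assert_allclose(sc, brute_silhouette(X, labels), atol=1e-8)
        np.testing.assert_allclose(sc, silhouette_samples(X, labels), atol=1e-8)

        ch = calinski_harabasz(X, cm)
        assert ch == pytest.approx(brute_calinski_harabasz(X, labels), rel=1e-6)
        assert ch == pytest.approx(calinski_harabasz_score(X, labels), rel=1e-6)

        db = davies_bouldin(X, cm, Metric.EUCLIDEAN, "mean")
        assert db == pytest.approx(brute_davies_bouldin(X, labels), rel=1e-8)
        assert db == pytest.approx(davies_bouldin_score(X, labels), rel=1e-6)


def test_silhouette_range_and_cosine_scale_invariance(rng):
    for _ in range(50):
        X, labels = random_labeled_dataset(rng)
        X = np.abs(X) + 0.5  # keep norms positive for cosine
        cm = build_cluster_model(X, labels)
        res = silhouette_values(X, cm, Metric.COSINE)
        assert np.all(res.sc >= -1 - 1e-12) and np.all(res.sc <= 1 + 1e-12)
        scale = rng.uniform(0.5, 3.0, size=(X.shape[0], 1))
        res2 = silhouette_values(X * scale, build_cluster_model(X * scale, labels,
                                 n_clusters=cm.n_clusters), Metric.COSINE)
        # per-point rescaling leaves cosine pairwise distances unchanged,
        # hence identical silhouette values up to centroid recomputation noise
        np.testing.assert_allclose(res2.sc, res.sc, atol=1e-9)


def test_compute_report_toy_assembly(toy_ab):
    X, _, cm = toy_ab
    som = SOMModel(2, cm.centroids.copy(), Metric.EUCLIDEAN)
    rep = compute_report(X, cm, som=som, metric=Metric.EUCLIDEAN)
    assert rep.silhouette_mean == pytest.approx(0.9002, abs=1e-4)
    assert rep.dunn == pytest.approx(10.0)
    assert rep.davies_bouldin == pytest.approx(0.2)
    assert rep.calinski_harabasz == pytest.approx(200.0)
    assert rep.quantization_error == pytest.approx(0.25)
    assert rep.flags == []


def test_compute_report_flags_empty_cluster(toy_ab):
    X, labels, _ = toy_ab
    cm = build_cluster_model(X, labels, n_clusters=3)
    som = SOMModel(3, np.vstack([cm.centroids[:2], [[5.0, 5.0]]]), Metric.EUCLIDEAN)
    rep = compute_report(X, cm, som=som, metric=Metric.EUCLIDEAN)
    assert "empty_cluster" in rep.flags
    assert np.isfinite(rep.calinski_harabasz)


def test_compute_report_deterministic(toy_ab):
    X, _, cm = toy_ab
    som = SOMModel(2, cm.centroids.copy(), Metric.EUCLIDEAN)
    r1 = compute_report(X, cm, som=som)
    r2 = compute_report(X, cm, som=som)
    assert r1 == r2
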
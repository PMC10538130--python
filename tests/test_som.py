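import numpy as np
import pytest

from somscore import (
    Metric,
    SOMModel,
    TrainingConfig,
    assign_clusters,
    find_bmu,
    init_som,
    quantization_error,
    train_som,
)


def _blobs(rng, centers, n=50, sd=0.5):
    centers = np.asarray(centers, float)
    X = np.vstack([c + rng.normal(0, sd, size=(n, centers.shape[1])) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n)
    return X, labels


def test_init_deterministic_by_seed(rng):
    data = rng.normal(size=(20, 6))
    cfg = TrainingConfig(seed=7)
    w1 = init_som(3, 6, cfg, data=data).weights
    w2 = init_som(3, 6, TrainingConfig(seed=7), data=data).weights
    np.testing.assert_array_equal(w1, w2)


def test_sample_init_is_row_permutation(rng):
    data = rng.normal(size=(4, 5))
    model = init_som(4, 5, TrainingConfig(init_scheme="sample", seed=3), data=data)
    got = {tuple(w) for w in model.weights}
    want = {tuple(r) for r in data}
    assert got == want


def test_sample_init_requires_enough_rows(rng):
    with pytest.raises(ValueError):
        init_som(5, 3, TrainingConfig(init_scheme="sample"), data=rng.normal(size=(3, 3)))


def test_uniform_init_within_data_bounding_box(rng):
    data = rng.uniform(-5, 7, size=(30, 4))
    model = init_som(6, 4, TrainingConfig(seed=1), data=data)
    assert np.all(model.weights >= data.min(axis=0) - 1e-12)
    assert np.all(model.weights <= data.max(axis=0) + 1e-12)


def test_find_bmu_cosine_closed_form():
    # d(f, w0) = 1, d(f, w1) = 1 - 1/sqrt(2) ~ 0.2929 -> neuron 1
    model = SOMModel(2, np.array([[0.0, 1.0], [1.0, 1.0]]), Metric.COSINE)
    assert find_bmu([1.0, 0.0], model) == 1


def test_find_bmu_exact_match_and_tie_rule():
    W = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0], [3.0, 7.0]])
    model = SOMModel(4, W, Metric.EUCLIDEAN)
    assert find_bmu([3.0, 7.0], model) == 3
    tie = SOMModel(2, np.array([[1.0, 0.0], [0.0, 1.0]]), Metric.EUCLIDEAN)
    assert find_bmu([0.5, 0.5], tie) == 0  # equidistant -> lowest index


def test_zero_epochs_keeps_init_weights(rng):
    data = rng.normal(size=(10, 3)) + 5
    cfg = TrainingConfig(epochs=0, seed=2)
    trained = train_som(data, 3, Metric.EUCLIDEAN, cfg)
    np.testing.assert_array_equal(
        trained.weights, init_som(3, 3, cfg, data=data).weights
    )


def test_training_deterministic_by_seed(rng):
    data = rng.normal(size=(30, 5)) + 3
    cfg = dict(epochs=5, seed=11)
    w1 = train_som(data, 3, Metric.COSINE, TrainingConfig(**cfg)).weights
    w2 = train_som(data, 3, Metric.COSINE, TrainingConfig(**cfg)).weights
    np.testing.assert_array_equal(w1, w2)


def test_two_blob_purity(rng):
    """2 well-separated blobs, M=2, Euclidean: purity 1.0 in >= 18/20 seeds."""
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        X, labels = _blobs(r, [np.zeros(5), np.full(5, 10.0)], n=50, sd=0.5)
        model = train_som(X, 2, Metric.EUCLIDEAN, TrainingConfig(epochs=10, seed=seed))
        assign = assign_clusters(X, model)
        purity = max(
            np.mean(assign == labels), np.mean(assign == 1 - labels)
        )
        hits += purity == 1.0
    assert hits >= 18


def test_training_reduces_quantization_error():
    """Mean final QE < mean initial QE over 20 seeds on blob data."""
    init_qe, final_qe = [], []
    for seed in range(20):
        r = np.random.default_rng(100 + seed)
        X, _ = _blobs(r, [np.zeros(4) + 1, np.full(4, 8.0)], n=40, sd=0.8)
        cfg = TrainingConfig(epochs=10, seed=seed)
        init_qe.append(
            quantization_error(X, init_som(3, 4, cfg, metric=Metric.EUCLIDEAN, data=X))
        )
        final_qe.append(quantization_error(X, train_som(X, 3, Metric.EUCLIDEAN, cfg)))
    assert np.mean(final_qe) < np.mean(init_qe)


def test_single_neuron_converges_into_hull(rng):
    X = rng.normal(size=(40, 3)) + 10
    model = train_som(X, 1, Metric.EUCLIDEAN, TrainingConfig(epochs=20, seed=5))
    w = model.weights[0]
    assert np.all(w >= X.min(axis=0)) and np.all(w <= X.max(axis=0))


def test_separated_blobs_capture_distinct_bmus():
    """M neurons on M well-separated blobs -> purity 1 in >= 18/20 seeds."""
    hits = 0
    centers = np.eye(4) * 20.0 + 5.0
    for seed in range(20):
        r = np.random.default_rng(seed)
        X, labels = _blobs(r, centers, n=30, sd=0.5)
        model = train_som(X, 4, Metric.EUCLIDEAN, TrainingConfig(epochs=15, seed=seed))
        assign = assign_clusters(X, model)
        # purity under best permutation: each blob maps to one distinct BMU
        from itertools import permutations
        best = max(
            np.mean(np.array(perm)[labels] == assign)
            for perm in permutations(range(4))
        )
        hits += best == 1.0
    assert hits >= 18


def test_quantization_error_closed_form():
    # data (1,0) vs weights (0,1) and (s2/2, s2/2): min cosine distance 1-s2/2
    s2 = np.sqrt(2) / 2
    model = SOMModel(2, np.array([[0.0, 1.0], [s2, s2]]), Metric.COSINE)
    qe = quantization_error(np.array([[1.0, 0.0]]), model)
    assert qe == pytest.approx((1 - s2) ** 2, abs=1e-12)


def test_quantization_error_zero_on_exact_match():
    W = np.array([[1.0, 2.0], [5.0, 5.0]])
    model = SOMModel(2, W, Metric.EUCLIDEAN)
    assert quantization_error(W.copy(), model) == 0.0


def test_quantization_error_mean_invariant_to_duplication(rng):
    X = rng.normal(size=(10, 4)) + 2
    model = SOMModel(3, rng.normal(size=(3, 4)) + 2, Metric.EUCLIDEAN)
    qe1 = quantization_error(X, model)
    qe2 = quantization_error(np.vstack([X, X]), model)
    assert qe1 == pytest.approx(qe2, rel=1e-12)


def test_assignments_identity_on_weight_rows(rng):
    W = rng.normal(size=(5, 4)) + 3
    model = SOMModel(5, W, Metric.EUCLIDEAN)
    np.testing.assert_array_equal(assign_clusters(W, model), np.arange(5))


def test_model_json_round_trip(tmp_path, rng):
    from somscore import load_model, save_model
    model = train_som(rng.normal(size=(15, 4)) + 2, 3, Metric.COSINE,
                      TrainingConfig(epochs=3, seed=9))
    path = tmp_path / "som.json"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.weights, model.weights)
    assert back.metric is Metric.COSINE
    assert back.config == model.config


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TrainingConfig(lr0=0.01, lr_final=0.5).validate()
    with pytest.raises(ValueError):
        TrainingConfig(sigma0=0.1, sigma_final=0.5).validate()
    with pytest.raises(ValueError):
        TrainingConfig(init_scheme="bogus").validate()
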
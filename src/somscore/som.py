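"""1-D Kohonen self-organizing map.

The map is a chain of M output neurons, one per posture cluster: the neuron
count *is* the cluster count, which is the quantity the whole toolbox exists
to choose.  Training is the classic online rule — per sample, find the
best-matching unit (BMU) under the configured metric (cosine or Euclidean),
then pull every neuron toward the sample with a Gaussian neighborhood on the
chain:

    w_m <- w_m + alpha(t) * exp(-(m - b)^2 / (2 sigma(t)^2)) * (f - w_m)

alpha and sigma decay exponentially from their initial to final values over
the total number of steps (epochs x N).  The metric affects only BMU search;
the additive update is shared, so cosine training orients weights while
Euclidean training places them.

Quantization error (QE) is the mean over samples of the squared distance to
the BMU, under the model's own metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .metrics import DegenerateInputError, Metric, pairwise_distances

INIT_SCHEMES = ("uniform", "gaussian", "sample")


@dataclass
class TrainingConfig:
    """Hyperparameters of the online training schedule.

    sigma0 defaults to M/2 at train time when left as None; all schedules
    decay exponentially.  Every run is fully reproducible from ``seed``.
    """

    epochs: int = 50
    lr0: float = 0.5
    lr_final: float = 0.01
    sigma0: float | None = None
    sigma_final: float = 0.5
    init_scheme: str = "uniform"
    seed: int = 0
    shuffle: bool = True

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not (self.lr0 >= self.lr_final > 0):
            raise ValueError("require lr0 >= lr_final > 0")
        if self.sigma0 is not None and not (self.sigma0 >= self.sigma_final > 0):
            raise ValueError("require sigma0 >= sigma_final > 0")
        if self.sigma0 is None and self.sigma_final <= 0:
            raise ValueError("sigma_final must be positive")
        if self.init_scheme not in INIT_SCHEMES:
            raise ValueError(
                f"init_scheme must be one of {INIT_SCHEMES}, got {self.init_scheme!r}"
            )


@dataclass
class SOMModel:
    """Trained (or freshly initialized) map: M neurons on a 1-D chain."""

    n_neurons: int
    weights: np.ndarray                # (M, D)
    metric: Metric
    config: TrainingConfig = field(default_factory=TrainingConfig)

    @property
    def n_dims(self) -> int:
        return int(self.weights.shape[1])


def init_som(
    M: int, D: int, config: TrainingConfig | None = None,
    metric: Metric | str = Metric.COSINE, data=None,
) -> SOMModel:
    """Randomly initialize an M-neuron map of dimension D.

    ``uniform`` draws i.i.d. entries on the data's per-dimension [min, max]
    (or [0, 1] without data); ``gaussian`` uses per-dimension data mean/sd
    (or N(0, 1)); ``sample`` picks M distinct data rows.
    """
    if M < 1 or D < 1:
        raise ValueError("need M >= 1 and D >= 1")
    config = config or TrainingConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    X = None if data is None else np.atleast_2d(np.asarray(data, dtype=float))
    if X is not None and X.shape[1] != D:
        raise ValueError(f"data dimension {X.shape[1]} != D={D}")

    if config.init_scheme == "sample":
        if X is None:
            raise ValueError("sample init requires data")
        if X.shape[0] < M:
            raise ValueError(f"sample init needs N >= M ({X.shape[0]} < {M})")
        idx = rng.choice(X.shape[0], size=M, replace=False)
        W = X[idx].copy()
    elif config.init_scheme == "gaussian":
        if X is None:
            W = rng.standard_normal((M, D))
        else:
            W = rng.standard_normal((M, D)) * X.std(axis=0) + X.mean(axis=0)
    else:  # uniform
        lo = np.zeros(D) if X is None else X.min(axis=0)
        hi = np.ones(D) if X is None else X.max(axis=0)
        W = rng.uniform(size=(M, D)) * (hi - lo) + lo

    return SOMModel(n_neurons=M, weights=W, metric=Metric.coerce(metric), config=config)


def _distances_to_weights(f: np.ndarray, W: np.ndarray, metric: Metric) -> np.ndarray:
    """Distances from one sample to all M weight rows (training fast path)."""
    if metric is Metric.EUCLIDEAN:
        diff = W - f
        return np.sqrt(np.einsum("md,md->m", diff, diff))
    fn = np.sqrt(f @ f)
    if fn == 0.0:
        raise DegenerateInputError("zero-norm sample under cosine metric")
    wn = np.sqrt(np.einsum("md,md->m", W, W))
    d = np.ones(W.shape[0])
    ok = wn > 0.0  # a zero-norm neuron is treated as orthogonal (distance 1)
    d[ok] = 1.0 - (W[ok] @ f) / (wn[ok] * fn)
    return np.clip(d, 0.0, 2.0)


def find_bmu(f, model: SOMModel) -> int:
    """Index of the best-matching unit; ties break to the lowest index."""
    fv = np.asarray(f, dtype=float).ravel()
    if fv.size != model.n_dims:
        raise ValueError(f"dimension mismatch: {fv.size} vs {model.n_dims}")
    d = _distances_to_weights(fv, model.weights, model.metric)
    return int(np.argmin(d))


def train_som(
    data, M: int, metric: Metric | str = Metric.COSINE,
    config: TrainingConfig | None = None,
) -> SOMModel:
    """Train an M-neuron chain map on the rows of ``data``.

    Deterministic given (data, config.seed): the same seed drives both the
    weight initialization and the per-epoch shuffling.
    """
    metric = Metric.coerce(metric)
    config = config or TrainingConfig()
    config.validate()
    X = np.atleast_2d(np.asarray(data, dtype=float))
    N, D = X.shape
    if N < 1:
        raise ValueError("empty data")

    model = init_som(M, D, config=config, metric=metric, data=X)
    W = model.weights
    sigma0 = config.sigma0 if config.sigma0 is not None else max(M / 2.0, config.sigma_final)

    total = config.epochs * N
    if total == 0:
        return model
    rng = np.random.default_rng(config.seed + 1)  # decoupled from init stream
    ts = np.arange(total) / max(total - 1, 1)
    alphas = config.lr0 * (config.lr_final / config.lr0) ** ts
    sigmas = sigma0 * (config.sigma_final / sigma0) ** ts
    chain = np.arange(M, dtype=float)

    t = 0
    for _ in range(config.epochs):
        order = rng.permutation(N) if config.shuffle else np.arange(N)
        for j in order:
            f = X[j]
            d = _distances_to_weights(f, W, metric)
            b = int(np.argmin(d))
            h = np.exp(-((chain - b) ** 2) / (2.0 * sigmas[t] ** 2))
            W += (alphas[t] * h)[:, None] * (f - W)
            t += 1
    return model


def assign_clusters(data, model: SOMModel) -> np.ndarray:
    """Per-row BMU index (vectorized); ties break to the lowest neuron index."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[1] != model.n_dims:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {model.n_dims}")
    d = pairwise_distances(X, model.weights, model.metric)
    return np.argmin(d, axis=1)


def quantization_error(data, model: SOMModel) -> float:
    """Mean over samples of the squared distance to the BMU (model metric)."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] < 1 or X.size == 0:
        raise ValueError("empty data")
    d = pairwise_distances(X, model.weights, model.metric)
    return float(np.mean(d.min(axis=1) ** 2))


def save_model(model: SOMModel, path) -> None:
    """Serialize the model to JSON at full float precision."""
    payload = {
        "n_neurons": model.n_neurons,
        "metric": model.metric.value,
        "weights": model.weights.tolist(),
        "config": asdict(model.config),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> SOMModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return SOMModel(
        n_neurons=int(payload["n_neurons"]),
        weights=np.asarray(payload["weights"], dtype=float),
        metric=Metric.coerce(payload["metric"]),
        config=TrainingConfig(**payload["config"]),
    )
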
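"""Independent brute-force evaluations of the validity indices.

Plain double loops over the index definitions, sharing no code with the
package implementations they check.
"""

import numpy as np


def _dist(x, y, metric):
    if metric == "cosine":
        return 1.0 - float(np.dot(x, y)) / (np.linalg.norm(x) * np.linalg.norm(y))
    return float(np.linalg.norm(np.asarray(x) - np.asarray(y)))


def brute_silhouette(X, labels, metric="euclidean"):
    """Per-sample silhouette by direct looping; singletons get 0."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    out = np.zeros(len(X))
    for i in range(len(X)):
        own = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([_dist(X[i], X[j], metric) for j in own])
        b_candidates = []
        for lab in set(labels.tolist()):
            if lab == labels[i]:
                continue
            members = [j for j in range(len(X)) if labels[j] == lab]
            if members:
                b_candidates.append(
                    np.mean([_dist(X[i], X[j], metric) for j in members])
                )
        b = min(b_candidates)
        denom = max(a, b)
        out[i] = (b - a) / denom if denom > 0 else 0.0
    return out


def brute_davies_bouldin(X, labels, metric="euclidean", mean_variant=True):
    """Davies-Bouldin by direct looping over the definition."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    labs = sorted(set(labels.tolist()))
    cents = {m: X[labels == m].mean(axis=0) for m in labs}
    av = {
        m: np.mean([_dist(x, cents[m], metric) for x in X[labels == m]])
        for m in labs
    }
    total = 0.0
    for m in labs:
        total += max(
            (av[m] + av[m1]) / _dist(cents[m], cents[m1], metric)
            for m1 in labs
            if m1 != m
        )
    return total / len(labs) if mean_variant else total


def brute_calinski_harabasz(X, labels):
    """Variance-ratio criterion by direct looping (Euclidean)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    labs = sorted(set(labels.tolist()))
    N, M = len(X), len(labs)
    c = X.mean(axis=0)
    between = sum(
        (labels == m).sum() * np.sum((X[labels == m].mean(axis=0) - c) ** 2)
        for m in labs
    )
    within = sum(
        np.sum((x - X[labels == m].mean(axis=0)) ** 2)
        for m in labs
        for x in X[labels == m]
    )
    return (between / (M - 1)) / (within / (N - M))


def random_labeled_dataset(rng, n_max=60, d_max=8, m_max=6):
    """Random dataset with every cluster non-empty and >= 1 non-singleton."""
    M = int(rng.integers(2, m_max + 1))
    N = int(rng.integers(max(M + 1, 8), n_max + 1))
    D = int(rng.integers(2, d_max + 1))
    centers = rng.normal(0.0, 4.0, size=(M, D))
    labels = np.concatenate([np.arange(M), rng.integers(0, M, size=N - M)])
    rng.shuffle(labels)
    X = centers[labels] + rng.normal(0.0, 1.0, size=(N, D))
    return X, labels
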
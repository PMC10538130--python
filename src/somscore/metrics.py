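"""Distance metrics shared by the SOM, the validity indices and the discriminant score.

Two metrics are supported: the cosine distance ``1 - x.y / (|x||y|)`` and the
Euclidean distance ``|x - y|``.  Cosine distance compares the *direction* of a
flattened skeleton frame (trunk inclination dominates), Euclidean distance its
absolute joint positions; the two can group postures differently, which is
precisely why both are exposed everywhere a distance is taken.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist


class DegenerateInputError(ValueError):
    """Raised for inputs on which a distance is undefined (e.g. an all-zero
    skeleton frame under the cosine metric)."""


class Metric(str, Enum):
    """Distance metric used for neuron matching and scoring."""

    COSINE = "cosine"
    EUCLIDEAN = "euclidean"

    @classmethod
    def coerce(cls, value: "Metric | str") -> "Metric":
        if isinstance(value, Metric):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown metric {value!r}; expected 'cosine' or 'euclidean'"
            ) from None


def _as_vector(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError(f"{name} must have at least one entry")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def cosine_distance(x, y) -> float:
    """Cosine distance ``1 - x.y/(|x||y|)`` in [0, 2].

    Zero iff the vectors are positively collinear; 2 for antipodal vectors.
    Raises :class:`DegenerateInputError` if either vector has zero norm.
    """
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if xv.shape != yv.shape:
        raise ValueError(f"dimension mismatch: {xv.shape} vs {yv.shape}")
    nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError(
            "cosine distance undefined for a zero-norm vector "
            "(all-zero skeleton frame?)"
        )
    d = 1.0 - float(np.dot(xv, yv)) / (nx * ny)
    # clip rounding noise outside the analytic range [0, 2]
    return min(max(d, 0.0), 2.0)


def euclidean_distance(x, y) -> float:
    """Euclidean distance ``|x - y|``."""
    xv, yv = _as_vector(x, "x"), _as_vector(y, "y")
    if xv.shape != yv.shape:
        raise ValueError(f"dimension mismatch: {xv.shape} vs {yv.shape}")
    return float(np.linalg.norm(xv - yv))


def distance(x, y, metric: Metric | str) -> float:
    """Dispatch to :func:`cosine_distance` or :func:`euclidean_distance`."""
    m = Metric.coerce(metric)
    if m is Metric.COSINE:
        return cosine_distance(x, y)
    return euclidean_distance(x, y)


def pairwise_distances(a, b, metric: Metric | str) -> np.ndarray:
    """Distance matrix between the rows of ``a`` and the rows of ``b``.

    Vectorized via :func:`scipy.spatial.distance.cdist`; the cosine branch
    rejects zero-norm rows the same way :func:`cosine_distance` does.
    """
    m = Metric.coerce(metric)
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if m is Metric.COSINE:
        if np.any(np.linalg.norm(A, axis=1) == 0.0) or np.any(
            np.linalg.norm(B, axis=1) == 0.0
        ):
            raise DegenerateInputError(
                "cosine distance undefined for zero-norm rows"
            )
        d = cdist(A, B, metric="cosine")
        return np.clip(d, 0.0, 2.0)
    return cdist(A, B, metric="euclidean")
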
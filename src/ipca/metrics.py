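"""Evaluation statistics: kurtosis, Davies-Bouldin index, loading angles,
identification rate.

Kurtosis here is always the *excess* kurtosis of the standardized signal,
``E{s^4} - 3`` with population (divisor ``q``) moments: zero for a
Gaussian, positive for spiky (super-Gaussian) densities such as the
Laplace, negative for flat (sub-Gaussian) ones.  The same estimator is
used both to order components and to report kurtosis tables, so the two
are always consistent.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, InputDataError, ParameterError

__all__ = ["kurtosis", "davies_bouldin", "loading_angle", "identification_rate"]


def kurtosis(x: np.ndarray) -> float:
    """Excess kurtosis ``E{z^4} - 3`` of the standardized vector.

    Uses raw population moments (no small-sample bias correction).
    Invariant under affine maps ``x -> a x + b`` with ``a != 0``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise InputDataError(f"kurtosis needs at least 4 values, got {x.size}")
    if np.var(x) == 0.0:
        raise DegenerateInputError("kurtosis undefined for a zero-variance vector")
    return float(stats.kurtosis(x, fisher=True, bias=True))


def davies_bouldin(scores: np.ndarray, labels) -> float:
    """Davies-Bouldin cluster-validity index; lower is better.

    ``(1/K) sum_i max_{j != i} (sigma_i + sigma_j) / d(c_i, c_j)`` where
    ``c_i`` is the centroid of class ``i``, ``sigma_i`` the mean Euclidean
    distance of its members to the centroid, and ``d`` the Euclidean
    distance between centroids in the component-score space.  Measures
    whether known biological conditions form compact, well-separated
    clusters in the reduced space.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.ndim != 2:
        raise InputDataError("scores must be an n x m matrix")
    labels = np.asarray(labels)
    if labels.shape[0] != scores.shape[0]:
        raise InputDataError("labels and scores disagree on the number of samples")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ParameterError("Davies-Bouldin needs at least 2 classes")
    centroids = np.stack([scores[labels == c].mean(axis=0) for c in classes])
    scatter = np.array(
        [
            np.linalg.norm(scores[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(classes)
        ]
    )
    k = classes.size
    dist = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    if np.any(dist[~np.eye(k, dtype=bool)] == 0.0):
        raise DegenerateInputError("coincident class centroids: index undefined")
    ratios = (scatter[:, None] + scatter[None, :]) / np.where(dist > 0, dist, np.inf)
    np.fill_diagonal(ratios, -np.inf)
    return float(ratios.max(axis=1).mean())


def loading_angle(true_v: np.ndarray, estimated_v: np.ndarray) -> float:
    """Angle in degrees, in [0, 90], between two direction vectors.

    Sign-invariant (``v`` and ``-v`` are the same direction) because SVD
    and ICA component signs are arbitrary.
    """
    a = np.asarray(true_v, dtype=float).ravel()
    b = np.asarray(estimated_v, dtype=float).ravel()
    if a.shape != b.shape:
        raise InputDataError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("angle undefined for a zero vector")
    cos = np.abs(a @ b) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))


def identification_rate(true_support, selected) -> float:
    """Percentage of the true non-zero support recovered by a selection.

    ``100 * |true ∩ selected| / |true|``.
    """
    true_set = set(int(i) for i in true_support)
    sel_set = set(int(i) for i in selected)
    if not sel_set:
        raise InputDataError("empty selection")
    if not true_set:
        raise InputDataError("empty true support")
    return 100.0 * len(true_set & sel_set) / len(true_set)
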
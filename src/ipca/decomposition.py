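"""Independent principal component analysis (IPCA) and its sparse variant.

IPCA treats the PCA loading vectors -- not the data or the components --
as the signals to denoise.  The reasoning: in a biological system only a
few variables drive any given process, so a noiseless loading vector
should look super-Gaussian (a spiky density: many near-zero weights, a
few large ones), while additive noise pushes it toward a Gaussian shape.
Maximizing the non-Gaussianity of the loading vectors with FastICA
therefore strips noise from the weights.

The algorithm:

1. center the ``n x p`` matrix ``X`` and compute its SVD ``X = U D V^T``;
2. keep the first ``m`` loading columns ``V`` (``p x m``), standardize
   each to zero mean and unit variance, and run (stabilized) FastICA on
   the ``m x p`` transposed matrix to obtain independent loading vectors
   ``S`` (rows, unit variance);
3. project: the independent principal components are ``XS^T`` (``n x m``);
4. order components by descending kurtosis of their loading vectors --
   the spikier the loading, the more biologically concentrated the
   component, and a sudden kurtosis drop flags the irrelevant dimensions.

Sparse IPCA (sIPCA) soft-thresholds each kurtosis-ordered independent
loading so that exactly ``keepX[j]`` variables keep non-zero weight, then
recomputes the component scores by projecting onto the sparse loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamatrix import DataMatrix, center
from .exceptions import ParameterError
from .fastica import FastICAOptions, stabilized_fastica
from .metrics import kurtosis
from .pca import pca

__all__ = [
    "IpcaResult",
    "SparsityPlan",
    "ipca_fit",
    "sipca_fit",
    "soft_threshold",
    "keepx_to_gamma",
    "kurtosis_drop_report",
]


@dataclass(frozen=True)
class SparsityPlan:
    """Per-component sparsity: number of variables kept and the induced
    soft-thresholds.

    ``gamma[j]`` is the ``(keepX[j]+1)``-th largest absolute weight of
    loading ``j`` (0 when ``keepX[j] = p``), i.e. the threshold at which
    soft-thresholding retains exactly ``keepX[j]`` non-zeros.
    """

    keepX: tuple[int, ...]
    gamma: tuple[float, ...]


@dataclass(frozen=True)
class IpcaResult:
    """Fitted IPCA (or sIPCA) decomposition.

    ``independent_loadings`` is ``m x p`` (rows = independent loading
    vectors, zero mean and unit variance before any sparsification);
    ``scores`` is ``n x m`` with the independent principal components
    ``X S^T``; ``loading_kurtosis`` holds the excess kurtosis of each
    stored loading row; ``order`` is the permutation (on the FastICA
    output) that produced the kurtosis-descending arrangement.
    """

    independent_loadings: np.ndarray
    scores: np.ndarray
    loading_kurtosis: np.ndarray
    order: np.ndarray
    sparsity: SparsityPlan | None = None

    @property
    def ncomp(self) -> int:
        return self.independent_loadings.shape[0]


def soft_threshold(loading: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise ``sign(s) (|s| - gamma)_+``.

    A contraction: magnitudes never grow, and the support
    ``{k : |s_k| > gamma}`` shrinks monotonically as ``gamma`` grows.
    ``gamma = 0`` is the identity.
    """
    if gamma < 0:
        raise ParameterError(f"gamma must be nonnegative, got {gamma}")
    s = np.asarray(loading, dtype=float)
    return np.sign(s) * np.maximum(np.abs(s) - gamma, 0.0)


def _ranked_indices(loading: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing |value|, ties broken by lower index."""
    a = np.abs(np.asarray(loading, dtype=float).ravel())
    return np.argsort(-a, kind="stable")


def keepx_to_gamma(loading: np.ndarray, keepX: int) -> float:
    """Threshold inducing a given degree of sparsity.

    Returns the ``(keepX+1)``-th largest absolute value of ``loading``
    (0 if ``keepX = p``), so that soft-thresholding at that level keeps
    exactly ``keepX`` non-zero weights.  Ties in absolute value are
    resolved by retaining the lower variable index first.
    """
    a = np.abs(np.asarray(loading, dtype=float).ravel())
    p = a.size
    if not 1 <= int(keepX) <= p:
        raise ParameterError(f"keepX must be in [1, {p}], got {keepX}")
    if int(keepX) == p:
        return 0.0
    return float(a[_ranked_indices(a)[int(keepX)]])


def _sparsify(loading: np.ndarray, keepX: int) -> tuple[np.ndarray, float]:
    """Soft-threshold a loading row to exactly ``keepX`` retained variables.

    The retained set is the top ``keepX`` by absolute weight (lower index
    first on ties); surviving weights are shrunk by the induced gamma.
    """
    gamma = keepx_to_gamma(loading, keepX)
    sparse = soft_threshold(loading, gamma)
    keep = _ranked_indices(loading)[: int(keepX)]
    mask = np.zeros(loading.size, dtype=bool)
    mask[keep] = True
    sparse[~mask] = 0.0
    return sparse, gamma


def _fix_row_signs(S: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(S), axis=1)
    signs = np.sign(S[np.arange(S.shape[0]), idx])
    signs[signs == 0] = 1.0
    return S * signs[:, None]


def ipca_fit(
    data: DataMatrix,
    ncomp: int,
    fastica_options: FastICAOptions | None = None,
) -> IpcaResult:
    """Fit IPCA with ``ncomp`` components.

    ``ncomp`` must be at least 2 (FastICA needs two signals to unmix) and
    at most ``min(n, p)``.  The data are centered internally if needed.
    Deterministic given the seed in ``fastica_options``.
    """
    opts = fastica_options or FastICAOptions()
    if not data.centered:
        data = center(data)
    n, p = data.shape
    if not 2 <= int(ncomp) <= min(n, p):
        raise ParameterError(f"ncomp must be in [2, {min(n, p)}], got {ncomp}")
    m = int(ncomp)
    V = pca(data, m).V  # p x m
    # The loading columns are unit-norm with near-zero means, hence only
    # approximately whitened; standardize explicitly before unmixing.
    V_std = (V - V.mean(axis=0)) / V.std(axis=0)
    unmix = stabilized_fastica(
        V_std.T,
        contrast=opts.contrast,
        tol=opts.tol,
        max_iter=opts.max_iter,
        n_restarts=opts.n_restarts,
        seed=opts.seed,
    )
    S = unmix.S  # m x p, rows zero mean / unit variance
    kurt = np.array([kurtosis(row) for row in S])
    order = np.argsort(-kurt, kind="stable")
    S = _fix_row_signs(S[order])
    scores = data.values @ S.T
    return IpcaResult(
        independent_loadings=S,
        scores=scores,
        loading_kurtosis=kurt[order],
        order=order,
    )


def sipca_fit(
    data: DataMatrix,
    ncomp: int,
    keepX,
    fastica_options: FastICAOptions | None = None,
) -> IpcaResult:
    """Fit sparse IPCA: IPCA followed by per-component soft-thresholding.

    ``keepX`` gives the number of variables to retain on each of the
    ``ncomp`` kurtosis-ordered components (``keepX[0]`` applies to the
    highest-kurtosis loading).  Scores are recomputed by projecting the
    centered data onto the sparse loadings, so noisy variables are removed
    from the components themselves, not just from the report.  With
    ``keepX[j] = p`` everywhere the result equals :func:`ipca_fit`.
    """
    keepX = tuple(int(k) for k in np.atleast_1d(keepX))
    if len(keepX) != int(ncomp):
        raise ParameterError(f"keepX must list {ncomp} values, got {len(keepX)}")
    if not data.centered:
        data = center(data)
    dense = ipca_fit(data, ncomp, fastica_options)
    sparse_rows = []
    gammas = []
    for j, row in enumerate(dense.independent_loadings):
        sparse, gamma = _sparsify(row, keepX[j])
        sparse_rows.append(sparse)
        gammas.append(gamma)
    S = np.stack(sparse_rows)
    # Kurtosis is re-reported on the (zero-padded) sparse rows, but the
    # kurtosis ordering established by the dense fit is kept.
    kurt = np.array([kurtosis(row) for row in S])
    return IpcaResult(
        independent_loadings=S,
        scores=data.values @ S.T,
        loading_kurtosis=kurt,
        order=dense.order,
        sparsity=SparsityPlan(keepX=keepX, gamma=tuple(gammas)),
    )


def kurtosis_drop_report(result: IpcaResult) -> list[tuple[int, float, float]]:
    """Kurtosis of each component and its drop from the previous one.

    Purely descriptive: a sudden drop marks where the remaining
    components stop carrying non-Gaussian (i.e. concentrated, likely
    biological) loading structure, guiding the choice of ``ncomp``.
    Rows are ``(component, kurtosis, drop_from_previous)`` with the first
    drop reported as 0.
    """
    k = result.loading_kurtosis
    return [
        (j + 1, float(k[j]), 0.0 if j == 0 else float(k[j - 1] - k[j]))
        for j in range(k.size)
    ]
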
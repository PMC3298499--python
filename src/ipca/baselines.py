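"""Comparison methods: classical ICA on samples, and sparse PCA via
regularized SVD with soft-thresholding (sPCA-rSVD).

Classical ICA whitens the data with PCA (keeping ``ncomp`` components),
unmixes the whitened principal components with FastICA, and orders the
resulting independent components by their kurtosis.  For comparisons
against true eigenvectors each component also gets a variable-space
loading direction: the unit vector that the centered data are projected
onto to produce that component (``V D^{-1} w_j`` up to scale).  Because
the inverse singular values weight the low-variance principal directions
most heavily, these directions are typically dominated by noise axes in
high dimension -- which is exactly the well-known failure mode of ICA on
fat matrices that IPCA was designed to avoid.

sPCA-rSVD extracts sparse rank-1 factors sequentially: alternate a power
step ``u = Xv/||Xv||`` with a soft-thresholded regression step
``v = soft_threshold(X^T u, gamma)`` until the direction stabilizes, then
deflate ``X <- X - u (u^T X)``.  The threshold is refreshed every
iteration from the requested degree of sparsity, so each loading carries
exactly ``keepX[j]`` non-zero weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamatrix import DataMatrix, center
from .decomposition import _ranked_indices, keepx_to_gamma, soft_threshold
from .exceptions import ConvergenceWarning, ParameterError
from .fastica import FastICAOptions, stabilized_fastica
from .metrics import kurtosis
from .pca import pca, whiten_components

__all__ = ["IcaResult", "SpcaResult", "ica_fit", "spca_rsvd_fit"]


@dataclass(frozen=True)
class IcaResult:
    """Classical ICA fit on an ``n x p`` matrix.

    ``sources`` (``m x p``): standardized variable-space loading
    directions, one row per component (see module docstring).
    ``scores`` (``n x m``): the independent components across samples.
    ``mixing`` (``n x m``): least-squares coefficients reconstructing the
    centered data from ``sources`` (``X ~= mixing @ sources``).
    ``component_kurtosis``: excess kurtosis of each sample-space
    independent component -- the ordering key, descending.
    """

    sources: np.ndarray
    scores: np.ndarray
    mixing: np.ndarray
    component_kurtosis: np.ndarray
    order: np.ndarray

    @property
    def ncomp(self) -> int:
        return self.sources.shape[0]


@dataclass(frozen=True)
class SpcaResult:
    """Sequential sparse-PCA fit: ``sparse_loadings`` is ``p x m`` with
    exactly ``keepX[j]`` non-zeros and unit Euclidean norm per column;
    ``scores = X @ sparse_loadings`` uses the pre-deflation data for each
    component."""

    sparse_loadings: np.ndarray
    scores: np.ndarray
    keepX: tuple[int, ...]
    converged: bool


def ica_fit(
    data: DataMatrix,
    ncomp: int,
    fastica_options: FastICAOptions | None = None,
) -> IcaResult:
    """Classical ICA: PCA whitening of ``ncomp`` components, FastICA on
    the whitened sample-space components, kurtosis-descending order."""
    opts = fastica_options or FastICAOptions()
    if not data.centered:
        data = center(data)
    n, p = data.shape
    if not 2 <= int(ncomp) <= min(n, p):
        raise ParameterError(f"ncomp must be in [2, {min(n, p)}], got {ncomp}")
    m = int(ncomp)
    pr = pca(data, m)
    U_white = whiten_components(pr, n)  # n x m
    unmix = stabilized_fastica(
        U_white.T,
        contrast=opts.contrast,
        tol=opts.tol,
        max_iter=opts.max_iter,
        n_restarts=opts.n_restarts,
        seed=opts.seed,
    )
    ic = unmix.S  # m x n independent components over samples
    kurt = np.array([kurtosis(row) for row in ic])
    order = np.argsort(-kurt, kind="stable")
    # Total rotation from the whitened PCs to the ICs, including the
    # internal re-whitening step.
    W_total = unmix.W @ unmix.whitening
    # Variable-space projection direction of component j: X @ (V D^-1 w_j)
    # reproduces IC j up to scale.
    directions = (pr.V / pr.D) @ W_total.T  # p x m
    directions = directions[:, order]
    ic = ic[order]
    sources = (directions - directions.mean(axis=0)) / directions.std(axis=0)
    sources = sources.T  # m x p, standardized rows
    # Deterministic signs: largest-|.| entry of each loading positive.
    idx = np.argmax(np.abs(sources), axis=1)
    signs = np.sign(sources[np.arange(m), idx])
    signs[signs == 0] = 1.0
    sources = sources * signs[:, None]
    scores = (ic * signs[:, None]).T  # n x m
    mixing, *_ = np.linalg.lstsq(sources.T, data.values.T, rcond=None)
    return IcaResult(
        sources=sources,
        scores=scores,
        mixing=mixing.T,
        component_kurtosis=kurt[order],
        order=order,
    )


def spca_rsvd_fit(
    data: DataMatrix,
    ncomp: int,
    keepX,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> SpcaResult:
    """Sparse PCA by sequential rank-1 regularized SVD with soft-thresholding.

    With ``keepX[j] = p`` (no sparsity) the loadings coincide with the PCA
    loading vectors.  Non-convergence of a component's alternating
    iteration raises a warning and flags the result, never an exception.
    """
    if not data.centered:
        data = center(data)
    n, p = data.shape
    if not 1 <= int(ncomp) <= min(n, p):
        raise ParameterError(f"ncomp must be in [1, {min(n, p)}], got {ncomp}")
    m = int(ncomp)
    keepX = tuple(int(k) for k in np.atleast_1d(keepX))
    if len(keepX) == 1 and m > 1:
        keepX = keepX * m
    if len(keepX) != m:
        raise ParameterError(f"keepX must list {m} values, got {len(keepX)}")
    X = data.values.copy()
    loadings = np.zeros((p, m))
    scores = np.zeros((n, m))
    all_converged = True
    for j in range(m):
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        v = vt[0]
        converged = False
        for _ in range(int(max_iter)):
            u = X @ v
            u /= np.linalg.norm(u)
            z = X.T @ u
            gamma = keepx_to_gamma(z, keepX[j])
            v_new = soft_threshold(z, gamma)
            keep = _ranked_indices(z)[: keepX[j]]
            mask = np.zeros(p, dtype=bool)
            mask[keep] = True
            v_new[~mask] = 0.0
            v_new /= np.linalg.norm(v_new)
            if 1.0 - abs(float(v_new @ v)) < tol:
                v = v_new
                converged = True
                break
            v = v_new
        if not converged:
            all_converged = False
            warnings.warn(
                f"sPCA-rSVD component {j + 1} did not converge in {max_iter} iterations",
                ConvergenceWarning,
                stacklevel=2,
            )
        i_max = int(np.argmax(np.abs(v)))
        if v[i_max] < 0:
            v = -v
        loadings[:, j] = v
        scores[:, j] = X @ v
        u = X @ v
        u /= np.linalg.norm(u)
        X = X - np.outer(u, u @ X)
    return SpcaResult(
        sparse_loadings=loadings, scores=scores, keepX=keepX, converged=all_converged
    )
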
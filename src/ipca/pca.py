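"""SVD-based principal component analysis.

PCA is the workhorse underneath everything else here: the decomposition
``X = U D V^T`` of the centered matrix supplies the loading vectors
(columns of ``V``) that IPCA denoises, and the whitened components that
classical ICA unmixes.  Only the thin SVD is computed (``r = min(n, p)``),
which is plenty at typical omics scale (p up to ~10^4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamatrix import DataMatrix
from .exceptions import DegenerateInputError, ParameterError

__all__ = ["PcaResult", "pca", "whiten_components"]


@dataclass(frozen=True)
class PcaResult:
    """Truncated SVD factors of a centered matrix.

    ``U`` is ``n x m`` with orthonormal columns, ``D`` the ``m``
    nonincreasing singular values, ``V`` the ``p x m`` loading matrix with
    orthonormal columns.  ``u_j d_j`` is the j-th principal component and
    ``v_j`` the corresponding loading vector.  ``explained_variance_ratio``
    is ``d_j^2 / sum_k d_k^2`` with the sum over the *full* spectrum, so the
    ratios of a truncated result do not generally sum to one.
    """

    U: np.ndarray
    D: np.ndarray
    V: np.ndarray
    explained_variance_ratio: np.ndarray
    n_samples: int

    @property
    def ncomp(self) -> int:
        return self.D.shape[0]


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD signs are arbitrary; make the largest-|.| entry of each loading
    # column positive so results are deterministic and comparable.
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def pca(data: DataMatrix, ncomp: int) -> PcaResult:
    """Rank-``ncomp`` SVD of a centered data matrix.

    Parameters
    ----------
    data
        A :class:`DataMatrix` with ``centered=True`` (use
        :func:`ipca.center` first).
    ncomp
        Number of components to retain, ``1 <= ncomp <= min(n, p)``.

    Raises
    ------
    ParameterError
        If ``data`` is not centered or ``ncomp`` is out of range.
    DegenerateInputError
        If the matrix, or any single variable, has zero variance.
        Zero-variance variables are rejected rather than silently dropped.
    """
    if not data.centered:
        raise ParameterError("pca() requires a centered matrix; apply center() first")
    X = data.values
    n, p = X.shape
    r = min(n, p)
    if not 1 <= int(ncomp) <= r:
        raise ParameterError(f"ncomp must be in [1, {r}], got {ncomp}")
    col_scale = np.abs(X).max(axis=0)
    if not col_scale.all():
        j = int(np.argmin(col_scale))
        raise DegenerateInputError(
            f"variable {data.variable_names[j]!r} has zero variance"
        )
    U, D, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(D**2))
    if total == 0.0:
        raise DegenerateInputError("matrix has zero variance")
    m = int(ncomp)
    U, V = _fix_signs(U[:, :m], Vt[:m].T)
    return PcaResult(
        U=U,
        D=D[:m].copy(),
        V=V,
        explained_variance_ratio=D[:m] ** 2 / total,
        n_samples=n,
    )


def whiten_components(pca_result: PcaResult, n: int) -> np.ndarray:
    """Whitened principal components, one column per component.

    Scales the orthonormal left factor ``U`` by ``sqrt(n - 1)`` so every
    component has zero mean and unit sample variance, with identity sample
    covariance -- the form FastICA expects.  Returns an ``n x m`` matrix.
    """
    U, D = pca_result.U, pca_result.D
    if n != U.shape[0]:
        raise ParameterError(f"n={n} does not match the fitted sample count {U.shape[0]}")
    if D[-1] <= D[0] * np.finfo(float).eps * max(U.shape[0], 1) or D[-1] <= 0:
        raise DegenerateInputError(
            "a retained singular value is (numerically) zero; reduce ncomp"
        )
    if n < 2:
        raise ParameterError("whitening needs n >= 2")
    return U * np.sqrt(n - 1)
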
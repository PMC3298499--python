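"""Fixed-point FastICA with symmetric decorrelation.

This is the non-Gaussianity maximizer at the heart of both IPCA (where the
"signals" are PCA loading vectors of length ``p``) and the classical ICA
baseline (where they are whitened principal components of length ``n``).
The implementation follows the standard symmetric (parallel) fixed-point
scheme of Hyvarinen's algorithm: the input signals are exactly whitened
internally, an orthogonal unmixing rotation ``W`` is iterated with a
negentropy-proxy contrast, and symmetric decorrelation
``W <- (W W^T)^{-1/2} W`` keeps ``W`` orthogonal after every step.

Because FastICA is a stochastic algorithm (the result depends on the random
initial rotation and the local optimum reached), :func:`stabilized_fastica`
runs several seeded restarts, aligns the recovered sources across runs by
absolute correlation, and returns the most independent run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import ConvergenceWarning, InputDataError, ParameterError

__all__ = ["FastICAOptions", "UnmixingResult", "fastica", "stabilized_fastica"]

_CONTRASTS = ("logcosh", "pow3")


@dataclass(frozen=True)
class FastICAOptions:
    """Options bundle passed through the higher-level fits.

    ``logcosh`` is the default contrast: it is the robust standard proxy
    for negentropy.  ``pow3`` (the kurtosis contrast) is available as an
    alternative.  Convergence follows the usual criterion: the largest
    deviation of ``|diag(W_new W_old^T)|`` from 1 must fall below ``tol``.
    The tight default (1e-6) matters: spiky signals saturate the tanh
    nonlinearity, and a looser tolerance can declare convergence at a
    mixed saddle point.  Non-convergence is reported with a warning and a
    ``converged=False`` flag, never an exception.
    """

    contrast: str = "logcosh"
    tol: float = 1e-6
    max_iter: int = 1000
    n_restarts: int = 3
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.contrast not in _CONTRASTS:
            raise ParameterError(f"contrast must be one of {_CONTRASTS}")
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ParameterError("tol, max_iter and n_restarts must be positive")


@dataclass(frozen=True)
class UnmixingResult:
    """Sources and the orthogonal unmixing rotation that produced them.

    ``W`` (``m x m``, orthogonal) acts on the internally whitened signals;
    ``whitening`` is the ``m x m`` transform from the centered input signals
    to their whitened version, so ``S = W @ whitening @ (signals - mean)``.
    Rows of ``S`` have zero mean and unit (population) variance and are
    mutually uncorrelated.
    """

    W: np.ndarray
    S: np.ndarray
    n_iterations: int
    converged: bool
    whitening: np.ndarray


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(W)
    return u @ vt


def _whiten_rows(signals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact whitening of row signals: zero mean, identity covariance
    (population convention, divisor q)."""
    m, q = signals.shape
    Xc = signals - signals.mean(axis=1, keepdims=True)
    cov = (Xc @ Xc.T) / q
    evals, E = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] <= evals[-1] * 1e-12:
        raise InputDataError("input signals are rank deficient; cannot whiten")
    K = (E / np.sqrt(evals)).T  # rows scaled: K = diag(1/sqrt(evals)) E^T
    return K @ Xc, K


def fastica(
    signals: np.ndarray,
    contrast: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
) -> UnmixingResult:
    """Extract independent sources from ``m`` (approximately) whitened signals.

    Parameters
    ----------
    signals
        ``m x q`` matrix, one signal per row, ``2 <= m < q``.  The rows are
        expected to be roughly whitened already (zero mean, covariance near
        identity); exact whitening is enforced internally regardless, which
        also makes the result equivariant to per-row rescaling.
    contrast
        ``"logcosh"`` (negentropy proxy, default) or ``"pow3"`` (kurtosis).
    seed
        Seeds the random orthogonal initial rotation (QR of a seeded
        Gaussian matrix).  The result is deterministic given the seed.
    """
    if contrast not in _CONTRASTS:
        raise ParameterError(f"contrast must be one of {_CONTRASTS}")
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2:
        raise InputDataError("signals must be a 2-d array (rows = signals)")
    m, q = X.shape
    if m < 2:
        raise ParameterError("FastICA needs at least 2 signals")
    if m >= q:
        raise InputDataError(f"need more observations than signals (m={m}, q={q})")
    if not np.isfinite(X).all():
        raise InputDataError("signals contain non-finite values")
    Z, K = _whiten_rows(X)

    rng = np.random.default_rng(seed)
    W, _ = np.linalg.qr(rng.standard_normal((m, m)))

    converged = False
    n_iterations = 0
    for n_iterations in range(1, max_iter + 1):
        Y = W @ Z
        if contrast == "logcosh":
            G = np.tanh(Y)
            g_prime = 1.0 - G**2
        else:
            G = Y**3
            g_prime = 3.0 * Y**2
        W_new = (G @ Z.T) / q - g_prime.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"FastICA did not converge in {max_iter} iterations (tol={tol})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return UnmixingResult(
        W=W, S=W @ Z, n_iterations=n_iterations, converged=converged, whitening=K
    )


def _restart_seeds(seed: int | None, n_restarts: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n_restarts, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def _align_to(reference: UnmixingResult, run: UnmixingResult) -> UnmixingResult:
    """Permute and sign-flip ``run``'s components to best match ``reference``
    (absolute-correlation assignment)."""
    ref_s = reference.S
    m = ref_s.shape[0]
    corr = np.corrcoef(ref_s, run.S)[:m, m:]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(m, dtype=int)
    perm[rows] = cols
    signs = np.sign(corr[rows, cols])
    signs[signs == 0] = 1.0
    order_signs = np.empty(m)
    order_signs[rows] = signs
    S = run.S[perm] * order_signs[:, None]
    W = run.W[perm] * order_signs[:, None]
    return UnmixingResult(
        W=W,
        S=S,
        n_iterations=run.n_iterations,
        converged=run.converged,
        whitening=run.whitening,
    )


def stabilized_fastica(
    signals: np.ndarray,
    contrast: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 3,
    seed: int | None = None,
) -> UnmixingResult:
    """FastICA with seeded restarts for robustness.

    Runs ``n_restarts`` independent seeded FastICA instances, aligns the
    recovered components across runs (sign/permutation resolution by
    absolute correlation), and returns the run whose sources have the
    lowest mean absolute pairwise correlation, i.e. the most independent
    solution.  Exact ties go to the earliest (lowest) restart seed.
    With ``n_restarts=1`` this is identical to :func:`fastica`.
    """
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    runs = [
        fastica(signals, contrast=contrast, tol=tol, max_iter=max_iter, seed=s)
        for s in _restart_seeds(seed, n_restarts)
    ]
    aligned = [runs[0]] + [_align_to(runs[0], run) for run in runs[1:]]
    scores = []
    m = signals.shape[0]
    off_diag = ~np.eye(m, dtype=bool)
    for run in aligned:
        corr = np.corrcoef(run.S)
        scores.append(float(np.abs(corr[off_diag]).mean()))
    best = int(np.argmin(scores))  # first minimum wins ties
    return aligned[best]
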
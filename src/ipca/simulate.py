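"""Planted-eigenvector covariance simulation and the replicate runner.

The simulation framework plants two known leading eigenvectors in a
``p x p`` covariance matrix and draws multivariate-normal datasets from
it, so that the directions a method should recover are known exactly:

* draw ``v1``, ``v2`` from one of four distributional cases (Gaussian,
  Laplace/uniform "super-Gaussian" mixture, or their sparse variants
  supported on 50 disjoint variables each);
* draw the remaining ``p - 2`` basis columns i.i.d. from U(0, 1);
* orthonormalize everything with Gram-Schmidt, processing ``v1`` then
  ``v2`` first, giving an orthogonal ``V``;
* set eigenvalues ``C = diag(c1, c2, 1, ..., 1)`` with ``c1 = 400`` and
  ``c2 = 300`` so the planted directions dominate, and form
  ``Sigma = V C V^T``;
* sample ``n = 50`` rows from ``N(0, Sigma)`` through the eigen-factor
  ``Sigma^(1/2) = V C^(1/2)`` (no Cholesky of the full matrix needed).

Note the samples themselves are Gaussian in every case; what varies is
the distribution of the planted *loading* structure -- precisely the
regime IPCA targets.

:func:`run_replicates` repeats draw-and-fit over many seeded replicates
for any subset of {pca, ica, ipca, spca, sipca} and aggregates angles to
the true eigenvectors, loading-kurtosis tables, and (for the sparse
methods) support-identification rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .baselines import ica_fit, spca_rsvd_fit
from .datamatrix import DataMatrix, center
from .decomposition import ipca_fit, sipca_fit
from .exceptions import ParameterError
from .fastica import FastICAOptions
from .metrics import identification_rate, kurtosis, loading_angle
from .pca import pca

__all__ = [
    "CASES",
    "SimulationDesign",
    "SimulatedDataset",
    "EvaluationReport",
    "make_design",
    "build_covariance",
    "sample_dataset",
    "run_replicates",
]

CASES = ("gaussian", "super_gaussian", "sparse_gaussian", "sparse_super_gaussian")
METHODS = ("pca", "ica", "ipca", "spca", "sipca")


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulation case.

    Defaults are the study conditions used throughout: ``n=50`` samples,
    ``p=500`` variables, leading eigenvalues 400 and 300 against a flat
    bulk of 1, Laplace scale 25 for the super-Gaussian entries, and sparse
    supports of 50 variables starting at (1-based) positions 1 and 301.
    """

    case: str = "gaussian"
    n: int = 50
    p: int = 500
    c1: float = 400.0
    c2: float = 300.0
    c_rest: float = 1.0
    laplace_scale: float = 25.0
    support_size: int = 50
    support2_start: int = 300  # 0-based; printed 1-based as 301
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ParameterError(f"case must be one of {CASES}, got {self.case!r}")
        if self.n < 4 or self.p < 4:
            raise ParameterError("need n >= 4 and p >= 4")
        if not self.c1 >= self.c2 > self.c_rest > 0:
            raise ParameterError("eigenvalues must satisfy c1 >= c2 > c_rest > 0")
        if self.laplace_scale <= 0:
            raise ParameterError("laplace_scale must be positive")
        if self.case != "gaussian":  # the Gaussian case plants dense vectors
            if self.support_size < 1 or self.support2_start < self.support_size:
                raise ParameterError("supports must be disjoint: start2 >= support_size")
            if self.support2_start + self.support_size > self.p:
                raise ParameterError("second support exceeds the number of variables")

    @property
    def support1(self) -> np.ndarray:
        return np.arange(self.support_size)

    @property
    def support2(self) -> np.ndarray:
        return np.arange(self.support2_start, self.support2_start + self.support_size)

    @property
    def sparse(self) -> bool:
        return self.case.startswith("sparse")


@dataclass(frozen=True)
class SimulatedDataset:
    """One draw: the data plus the ground truth it was generated from.

    ``true_v1``/``true_v2`` are the post-Gram-Schmidt orthonormal planted
    eigenvectors (the quantities any estimate is compared against);
    supports are 0-based index arrays, present only for the sparse cases.
    """

    data: DataMatrix
    true_v1: np.ndarray
    true_v2: np.ndarray
    true_support_1: np.ndarray | None = None
    true_support_2: np.ndarray | None = None


def make_design(case: str, **overrides) -> SimulationDesign:
    """A validated :class:`SimulationDesign` for one of the four cases."""
    return SimulationDesign(case=case, **overrides)


def _draw_planted(design: SimulationDesign, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    p, k = design.p, design.support_size
    s1, s2 = design.support1, design.support2
    if design.case == "gaussian":
        return rng.standard_normal(p), rng.standard_normal(p)
    if design.case == "super_gaussian":
        v1 = rng.uniform(0.0, 1.0, p)
        v1[s1] = rng.laplace(0.0, design.laplace_scale, k)
        v2 = rng.uniform(0.0, 1.0, p)
        v2[s2] = rng.laplace(0.0, design.laplace_scale, k)
        return v1, v2
    v1 = np.zeros(p)
    v2 = np.zeros(p)
    if design.case == "sparse_gaussian":
        v1[s1] = rng.standard_normal(k)
        v2[s2] = rng.standard_normal(k)
    else:  # sparse_super_gaussian
        v1[s1] = rng.laplace(0.0, design.laplace_scale, k)
        v2[s2] = rng.laplace(0.0, design.laplace_scale, k)
    return v1, v2


def _orthonormal_basis(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Gram-Schmidt basis with the planted vectors processed first.

    Computed via the QR factorization (identical to classical
    Gram-Schmidt up to column signs, which are fixed so each basis vector
    keeps a positive projection on its raw column).  Collinear draws are
    resampled with a warning, with bounded retries.
    """
    p = design.p
    for attempt in range(5):
        v1, v2 = _draw_planted(design, rng)
        A = np.empty((p, p))
        A[:, 0] = v1
        A[:, 1] = v2
        A[:, 2:] = rng.uniform(0.0, 1.0, (p, p - 2))
        Q, R = np.linalg.qr(A)
        diag = np.diagonal(R)
        if np.min(np.abs(diag)) <= 1e-12 * np.max(np.abs(diag)):
            warnings.warn("collinear draw in Gram-Schmidt step; resampling")
            continue
        return Q * np.sign(diag)
    raise RuntimeError("Gram-Schmidt failed after 5 resampling attempts")


def _eigenvalues(design: SimulationDesign) -> np.ndarray:
    c = np.full(design.p, design.c_rest)
    c[0], c[1] = design.c1, design.c2
    return c


def build_covariance(design: SimulationDesign, seed=None):
    """The planted covariance ``Sigma = V C V^T`` and its ground truth.

    Returns ``(Sigma, true_v1, true_v2, supports)`` where ``supports`` is
    ``(support1, support2)`` for the sparse cases and ``None`` otherwise.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    V = _orthonormal_basis(design, rng)
    sigma = (V * _eigenvalues(design)) @ V.T
    supports = (design.support1, design.support2) if design.sparse else None
    return sigma, V[:, 0].copy(), V[:, 1].copy(), supports


def sample_dataset(design: SimulationDesign, seed=None) -> SimulatedDataset:
    """Draw one ``n x p`` dataset from ``N(0, Sigma)``.

    A fresh planted basis is drawn per call, then ``n`` rows are sampled
    through the eigen-factor ``V C^(1/2)``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    V = _orthonormal_basis(design, rng)
    factor = V * np.sqrt(_eigenvalues(design))  # Sigma^(1/2)
    X = rng.standard_normal((design.n, design.p)) @ factor.T
    return SimulatedDataset(
        data=DataMatrix(values=X),
        true_v1=V[:, 0].copy(),
        true_v2=V[:, 1].copy(),
        true_support_1=design.support1.copy() if design.sparse else None,
        true_support_2=design.support2.copy() if design.sparse else None,
    )


@dataclass
class EvaluationReport:
    """Per-replicate evaluation records plus aggregation helpers.

    ``angles[method]`` is ``(n_reps, 2)`` (degrees to ``v1``/``v2``),
    ``kurtosis_table[method]`` is ``(n_reps, k)`` (loading kurtosis,
    component-ordered), ``rates[method]`` is ``(n_reps, 2)`` (percent of
    each true support recovered).  Aggregates (median/mean/SD) are always
    recomputed from the stored per-replicate values.
    """

    design: SimulationDesign
    methods: tuple[str, ...]
    n_reps: int
    seed: int | None
    keepX: tuple[int, ...] | None
    angles: dict = field(default_factory=dict)
    kurtosis_table: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    n_failed: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out: dict = {
            "case": self.design.case,
            "n": self.design.n,
            "p": self.design.p,
            "n_reps": self.n_reps,
            "methods": {},
        }
        for method in self.methods:
            entry: dict = {"n_failed": int(self.n_failed.get(method, 0))}
            if method in self.angles and len(self.angles[method]):
                a = np.asarray(self.angles[method])
                entry["angle_median"] = [float(x) for x in np.median(a, axis=0)]
            if method in self.kurtosis_table and len(self.kurtosis_table[method]):
                k = np.asarray(self.kurtosis_table[method])
                entry["kurtosis_mean"] = [float(x) for x in k.mean(axis=0)]
            if method in self.rates and len(self.rates[method]):
                r = np.asarray(self.rates[method])
                entry["rate_mean"] = [float(x) for x in r.mean(axis=0)]
                entry["rate_sd"] = [float(x) for x in r.std(axis=0, ddof=1)]
            out["methods"][method] = entry
        return out

    def to_tidy_records(self) -> list[dict]:
        """One record per replicate x method x metric, for CSV export."""
        records = []
        for method in self.methods:
            for name, table in (
                ("angle", self.angles),
                ("kurtosis", self.kurtosis_table),
                ("identification_rate", self.rates),
            ):
                if method not in table:
                    continue
                for rep, row in enumerate(table[method]):
                    for j, value in enumerate(np.atleast_1d(row)):
                        records.append(
                            {
                                "replicate": rep + 1,
                                "method": method,
                                "metric": name,
                                "component": j + 1,
                                "value": float(value),
                            }
                        )
        return records


def _support_of(loading: np.ndarray) -> np.ndarray:
    return np.flatnonzero(loading)


def _match_to_truth(true_vs: list[np.ndarray], loadings: list[np.ndarray]) -> np.ndarray:
    """Assign estimated components to true eigenvectors.

    Kurtosis (and ICA output) ordering carries no information about
    *which* planted direction a component estimates -- the two planted
    loadings are drawn from the same distribution, so their rank order is
    arbitrary.  Components are therefore paired with the true vectors by
    the assignment minimizing the total angle.  For methods with an
    informative order (PCA's variance ranking, sPCA's deflation sequence)
    this reduces to the identity pairing.  Returns ``perm`` such that
    ``loadings[perm[j]]`` estimates ``true_vs[j]``.
    """
    cost = np.array(
        [[loading_angle(v, est) for est in loadings] for v in true_vs]
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(true_vs), dtype=int)
    perm[rows] = cols
    return perm


def run_replicates(
    design: SimulationDesign,
    methods,
    n_reps: int,
    keepX=None,
    seed=None,
    ncomp: int = 2,
    kurtosis_components: int | None = 5,
    ica_components: int = 5,
    fastica_options: FastICAOptions | None = None,
) -> EvaluationReport:
    """Simulate ``n_reps`` datasets and evaluate each requested method.

    Per replicate: draw a dataset, fit each method with ``ncomp``
    components for the angle/identification comparisons (estimated
    component ``j`` is matched to true ``v_j`` by index, after each
    method's own ordering), and -- when ``kurtosis_components`` is not
    None -- refit with that many components for the loading-kurtosis
    table.  Classical ICA always whitens with ``ica_components``
    principal components (5 by default, the fixed-components convention).
    Sparse methods additionally report identification rates against the
    true supports and require ``keepX``.  Replicate-level failures are
    logged, counted in ``n_failed`` and excluded from aggregates.

    Fully seeded: replicate ``i`` derives its data seed and its FastICA
    seed from ``SeedSequence(seed).spawn``.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ParameterError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    needs_keepx = {"spca", "sipca"} & set(methods)
    if needs_keepx and keepX is None:
        raise ParameterError("spca/sipca need keepX")
    if keepX is not None:
        keepX = tuple(int(k) for k in np.atleast_1d(keepX))
        if len(keepX) == 1:
            keepX = keepX * ncomp
    if needs_keepx and not design.sparse:
        warnings.warn("identification rates are only meaningful for sparse cases")
    base_opts = fastica_options or FastICAOptions()

    report = EvaluationReport(
        design=design, methods=methods, n_reps=n_reps, seed=seed, keepX=keepX
    )
    for method in methods:
        report.n_failed[method] = 0
        if method in ("pca", "ica", "ipca"):
            report.angles[method] = []
            if kurtosis_components:
                report.kurtosis_table[method] = []
        else:
            report.rates[method] = []

    children = np.random.SeedSequence(seed).spawn(n_reps)
    for rep, child in enumerate(children):
        data_ss, fica_ss = child.spawn(2)
        sim = sample_dataset(design, seed=data_ss)
        centered = center(sim.data)
        fica_seed = int(fica_ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
        opts = replace(base_opts, seed=fica_seed)
        kc = kurtosis_components
        for method in methods:
            try:
                if method == "pca":
                    pr = pca(centered, max(ncomp, kc or 0))
                    report.angles[method].append(
                        [
                            loading_angle(sim.true_v1, pr.V[:, 0]),
                            loading_angle(sim.true_v2, pr.V[:, 1]),
                        ]
                    )
                    if kc:
                        report.kurtosis_table[method].append(
                            [kurtosis(pr.V[:, j]) for j in range(kc)]
                        )
                elif method == "ipca":
                    fit = ipca_fit(centered, ncomp, opts)
                    L = fit.independent_loadings
                    perm = _match_to_truth([sim.true_v1, sim.true_v2], list(L[:2]))
                    report.angles[method].append(
                        [
                            loading_angle(sim.true_v1, L[perm[0]]),
                            loading_angle(sim.true_v2, L[perm[1]]),
                        ]
                    )
                    if kc:
                        fit_k = ipca_fit(centered, kc, opts)
                        report.kurtosis_table[method].append(
                            [float(x) for x in fit_k.loading_kurtosis]
                        )
                elif method == "ica":
                    fit = ica_fit(centered, max(ica_components, ncomp, kc or 0), opts)
                    L = fit.sources
                    perm = _match_to_truth([sim.true_v1, sim.true_v2], list(L[:ncomp]))
                    report.angles[method].append(
                        [
                            loading_angle(sim.true_v1, L[perm[0]]),
                            loading_angle(sim.true_v2, L[perm[1]]),
                        ]
                    )
                    if kc:
                        report.kurtosis_table[method].append(
                            [kurtosis(fit.sources[j]) for j in range(kc)]
                        )
                elif method == "spca":
                    fit = spca_rsvd_fit(centered, ncomp, keepX)
                    L = [fit.sparse_loadings[:, j] for j in range(2)]
                    perm = _match_to_truth([sim.true_v1, sim.true_v2], L)
                    report.rates[method].append(
                        [
                            identification_rate(
                                sim.true_support_1, _support_of(L[perm[0]])
                            ),
                            identification_rate(
                                sim.true_support_2, _support_of(L[perm[1]])
                            ),
                        ]
                    )
                else:  # sipca
                    fit = sipca_fit(centered, ncomp, keepX, opts)
                    L = list(fit.independent_loadings[:2])
                    perm = _match_to_truth([sim.true_v1, sim.true_v2], L)
                    report.rates[method].append(
                        [
                            identification_rate(
                                sim.true_support_1, _support_of(L[perm[0]])
                            ),
                            identification_rate(
                                sim.true_support_2, _support_of(L[perm[1]])
                            ),
                        ]
                    )
            except Exception as exc:  # noqa: BLE001 - per-replicate robustness
                report.n_failed[method] += 1
                warnings.warn(f"replicate {rep + 1}, method {method!r} failed: {exc}")
    for table in (report.angles, report.kurtosis_table, report.rates):
        for method, rows in table.items():
            table[method] = np.asarray(rows, dtype=float)
    return report
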
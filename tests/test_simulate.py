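import numpy as np
import pytest

from ipca import (
    ParameterError,
    build_covariance,
    make_design,
    run_replicates,
    sample_dataset,
)
from ipca.simulate import _draw_planted, _eigenvalues, _orthonormal_basis


SMALL = dict(n=20, p=80, support_size=10, support2_start=40)


class TestDesign:
    def test_defaults_are_the_study_conditions(self):
        d = make_design("gaussian")
        assert (d.n, d.p) == (50, 500)
        assert (d.c1, d.c2, d.c_rest) == (400.0, 300.0, 1.0)
        assert d.laplace_scale == 25.0
        assert d.support1[0] == 0 and d.support2[0] == 300

    def test_overrides_validated(self):
        d = make_design("gaussian", p=100, support2_start=50)
        assert d.p == 100
        with pytest.raises(ParameterError):
            make_design("gaussian", c1=200.0, c2=300.0)
        with pytest.raises(ParameterError):
            make_design("no_such_case")
        with pytest.raises(ParameterError):
            make_design("sparse_gaussian", p=100)  # support 301-350 out of range


class TestCovariance:
    @pytest.mark.parametrize("case", ["gaussian", "super_gaussian", "sparse_gaussian"])
    def test_eigenvalue_spectrum(self, case):
        d = make_design(case, **SMALL)
        sigma, v1, v2, _ = build_covariance(d, seed=0)
        evals = np.linalg.eigvalsh(sigma)[::-1]
        expected = np.concatenate([[400.0, 300.0], np.ones(d.p - 2)])
        np.testing.assert_allclose(evals, expected, atol=1e-6)
        # planted vectors are eigenvectors with the two leading eigenvalues
        np.testing.assert_allclose(sigma @ v1, 400.0 * v1, atol=1e-8)
        np.testing.assert_allclose(sigma @ v2, 300.0 * v2, atol=1e-8)

    def test_basis_is_orthonormal(self):
        d = make_design("super_gaussian", **SMALL)
        v = _orthonormal_basis(d, np.random.default_rng(1))
        np.testing.assert_allclose(v.T @ v, np.eye(d.p), atol=1e-10)

    def test_sigma_reconstruction(self):
        d = make_design("gaussian", **SMALL)
        rng = np.random.default_rng(3)
        v = _orthonormal_basis(d, rng)
        sigma = (v * _eigenvalues(d)) @ v.T
        sigma2, *_ = build_covariance(d, seed=3)
        assert np.linalg.norm(sigma - sigma2) / np.linalg.norm(sigma2) < 1e-10

    def test_sparse_truths_vanish_off_support(self):
        d = make_design("sparse_super_gaussian", **SMALL)
        _, v1, v2, supports = build_covariance(d, seed=5)
        s1, s2 = supports
        off1 = np.setdiff1d(np.arange(d.p), s1)
        off2 = np.setdiff1d(np.arange(d.p), s2)
        np.testing.assert_allclose(v1[off1], 0.0, atol=1e-12)
        np.testing.assert_allclose(v2[off2], 0.0, atol=1e-12)

    def test_disjoint_supports_orthogonal_before_gram_schmidt(self):
        d = make_design("sparse_gaussian", **SMALL)
        v1, v2 = _draw_planted(d, np.random.default_rng(7))
        assert v1 @ v2 == 0.0


class TestSampling:
    def test_deterministic_given_seed(self):
        d = make_design("super_gaussian", **SMALL)
        a = sample_dataset(d, seed=11)
        b = sample_dataset(d, seed=11)
        np.testing.assert_array_equal(a.data.values, b.data.values)
        np.testing.assert_array_equal(a.true_v1, b.true_v1)

    def test_leading_sample_eigenvalue_near_planted(self):
        d = make_design("gaussian")
        tops = []
        for seed in range(5):
            sim = sample_dataset(d, seed=seed)
            x = sim.data.values - sim.data.values.mean(axis=0)
            tops.append(np.linalg.eigvalsh(x.T @ x / (d.n - 1))[-1])
        assert all(250.0 < t < 600.0 for t in tops)

    def test_truths_are_orthonormal(self):
        d = make_design("sparse_gaussian", **SMALL)
        sim = sample_dataset(d, seed=2)
        assert np.linalg.norm(sim.true_v1) == pytest.approx(1.0, abs=1e-10)
        assert abs(sim.true_v1 @ sim.true_v2) < 1e-10


class TestRunReplicates:
    def test_single_replicate_is_deterministic(self):
        d = make_design("super_gaussian", **SMALL)
        kw = dict(n_reps=2, seed=4, kurtosis_components=3, ica_components=3)
        a = run_replicates(d, ("pca", "ipca"), **kw)
        b = run_replicates(d, ("pca", "ipca"), **kw)
        for method in ("pca", "ipca"):
            np.testing.assert_array_equal(a.angles[method], b.angles[method])
            np.testing.assert_array_equal(
                a.kurtosis_table[method], b.kurtosis_table[method]
            )

    def test_summary_recomputable_from_records(self):
        d = make_design("sparse_gaussian", **SMALL)
        rep = run_replicates(
            d, ("spca", "sipca"), n_reps=3, seed=9, keepX=5, kurtosis_components=None
        )
        summary = rep.summary()
        for method in ("spca", "sipca"):
            np.testing.assert_allclose(
                summary["methods"][method]["rate_mean"],
                np.asarray(rep.rates[method]).mean(axis=0),
            )
        records = rep.to_tidy_records()
        assert len(records) == 2 * 3 * 2  # methods x reps x components
        assert all(r["metric"] == "identification_rate" for r in records)

    def test_keepx_required_for_sparse_methods(self):
        d = make_design("sparse_gaussian", **SMALL)
        with pytest.raises(ParameterError, match="keepX"):
            run_replicates(d, ("spca",), n_reps=1, seed=0)

    def test_unknown_method_rejected(self):
        d = make_design("gaussian", **SMALL)
        with pytest.raises(ParameterError, match="unknown"):
            run_replicates(d, ("pca", "tsne"), n_reps=1, seed=0)
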
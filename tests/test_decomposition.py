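import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import subspace_angles

from ipca import (
    DataMatrix,
    FastICAOptions,
    ParameterError,
    center,
    ipca_fit,
    keepx_to_gamma,
    kurtosis,
    kurtosis_drop_report,
    pca,
    sipca_fit,
    soft_threshold,
)
from ipca.decomposition import _sparsify


@pytest.fixture(scope="module")
def superg_fit():
    """One IPCA fit on a dataset with planted super-Gaussian loadings."""
    from ipca import make_design, sample_dataset

    sim = sample_dataset(make_design("super_gaussian"), seed=123)
    data = center(sim.data)
    return data, ipca_fit(data, 4, FastICAOptions(seed=0))


class TestSoftThreshold:
    def test_elementwise_shrinkage(self):
        out = soft_threshold(np.array([0.5, -0.2, 0.1]), 0.15)
        np.testing.assert_allclose(out, [0.35, -0.05, 0.0], atol=1e-15)

    def test_zero_gamma_is_identity(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_total_shrinkage(self):
        x = np.array([0.3, -0.8, 0.5])
        np.testing.assert_array_equal(soft_threshold(x, 0.8), np.zeros(3))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ParameterError):
            soft_threshold(np.ones(3), -0.1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=30),
        st.floats(0, 5),
        st.floats(0, 5),
    )
    def test_contraction_and_support_monotonicity(self, values, g1, g2):
        x = np.asarray(values)
        lo, hi = sorted((g1, g2))
        a, b = soft_threshold(x, lo), soft_threshold(x, hi)
        assert np.max(np.abs(a)) <= np.max(np.abs(x)) + 1e-12
        assert set(np.flatnonzero(b)) <= set(np.flatnonzero(a))


class TestKeepxToGamma:
    def test_order_statistic(self):
        x = np.array([3.0, 1.0, 2.0])
        assert keepx_to_gamma(x, 2) == 1.0
        sparse, _ = _sparsify(x, 2)
        assert set(np.flatnonzero(sparse)) == {0, 2}

    def test_keepx_equals_p_gives_zero(self):
        assert keepx_to_gamma(np.array([3.0, 1.0, 2.0]), 3) == 0.0

    def test_tie_keeps_lower_index(self):
        x = np.array([2.0, 2.0, 1.0])
        gamma = keepx_to_gamma(x, 1)
        assert gamma == 2.0
        keep = np.argsort(-np.abs(x), kind="stable")[:1]
        assert keep.tolist() == [0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            keepx_to_gamma(np.ones(3), 0)
        with pytest.raises(ParameterError):
            keepx_to_gamma(np.ones(3), 4)


class TestIpcaFit:
    def test_kurtosis_ordering_invariant(self, superg_fit):
        _, fit = superg_fit
        assert np.all(np.diff(fit.loading_kurtosis) <= 0)
        # stored kurtosis is recomputable from the stored rows
        recomputed = [kurtosis(row) for row in fit.independent_loadings]
        np.testing.assert_allclose(fit.loading_kurtosis, recomputed, atol=1e-10)

    def test_loading_rows_standardized(self, superg_fit):
        _, fit = superg_fit
        rows = fit.independent_loadings
        np.testing.assert_allclose(rows.mean(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose((rows**2).mean(axis=1), 1.0, atol=1e-6)

    def test_projection_consistency_bit_for_bit(self, superg_fit):
        data, fit = superg_fit
        np.testing.assert_array_equal(
            fit.scores, data.values @ fit.independent_loadings.T
        )

    def test_deterministic_given_seed(self, superg_fit):
        data, fit = superg_fit
        again = ipca_fit(data, 4, FastICAOptions(seed=0))
        np.testing.assert_array_equal(fit.independent_loadings, again.independent_loadings)

    def test_ncomp_validation(self, small_centered):
        with pytest.raises(ParameterError):
            ipca_fit(small_centered, 1)
        with pytest.raises(ParameterError):
            ipca_fit(small_centered, 9)

    def test_independent_laplace_loadings_span_pca_subspace(self):
        # data built so its loading vectors are already independent
        # Laplace signals: IPCA should only rotate within the PCA subspace
        rng = np.random.default_rng(5)
        p, n, m = 400, 30, 2
        basis, _ = np.linalg.qr(rng.laplace(size=(p, m)))
        scores = rng.standard_normal((n, m)) * [10.0, 7.0]
        x = scores @ basis.T + 0.01 * rng.standard_normal((n, p))
        data = center(DataMatrix(values=x))
        fit = ipca_fit(data, m, FastICAOptions(seed=1))
        v = pca(data, m).V
        angles = np.degrees(subspace_angles(v, fit.independent_loadings.T))
        # entry-centering of the loading vectors before unmixing adds a
        # small ones-direction component, so the match is near, not exact
        assert np.max(angles) < 6.0


class TestSipcaFit:
    def test_exact_nonzero_counts(self, superg_fit):
        data, _ = superg_fit
        keep = (40, 25, 10, 5)
        fit = sipca_fit(data, 4, keep, FastICAOptions(seed=0))
        counts = (fit.independent_loadings != 0).sum(axis=1)
        np.testing.assert_array_equal(counts, keep)
        assert fit.sparsity.keepX == keep
        # gamma is the (keepX+1)-th largest |weight| of the dense loading
        dense = ipca_fit(data, 4, FastICAOptions(seed=0))
        for j, k in enumerate(keep):
            assert fit.sparsity.gamma[j] == pytest.approx(
                keepx_to_gamma(dense.independent_loadings[j], k)
            )

    def test_full_keepx_reduces_to_dense_fit(self, superg_fit):
        data, dense = superg_fit
        p = data.n_variables
        fit = sipca_fit(data, 4, (p, p, p, p), FastICAOptions(seed=0))
        np.testing.assert_allclose(
            fit.independent_loadings, dense.independent_loadings, atol=1e-12
        )
        np.testing.assert_allclose(fit.scores, dense.scores, atol=1e-9)

    def test_variable_lists_are_nested_across_keepx(self, superg_fit):
        data, _ = superg_fit
        supports = []
        for k in (100, 50, 20):
            fit = sipca_fit(data, 4, (k,) * 4, FastICAOptions(seed=0))
            supports.append(set(np.flatnonzero(fit.independent_loadings[0])))
        assert supports[2] <= supports[1] <= supports[0]

    def test_scores_recomputed_from_sparse_loadings(self, superg_fit):
        data, _ = superg_fit
        fit = sipca_fit(data, 4, (30,) * 4, FastICAOptions(seed=0))
        np.testing.assert_array_equal(
            fit.scores, data.values @ fit.independent_loadings.T
        )

    def test_keepx_length_validated(self, superg_fit):
        data, _ = superg_fit
        with pytest.raises(ParameterError):
            sipca_fit(data, 4, (10, 10))


def test_kurtosis_drop_report(superg_fit):
    _, fit = superg_fit
    report = kurtosis_drop_report(fit)
    assert [row[0] for row in report] == [1, 2, 3, 4]
    k = fit.loading_kurtosis
    assert report[0][2] == 0.0
    for j in range(1, 4):
        assert report[j][2] == pytest.approx(k[j - 1] - k[j])
    # planted structure: large drop after the two real components
    drops = [row[2] for row in report]
    assert drops[2] == max(drops)
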
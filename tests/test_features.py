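import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sipfft.features import (
    FeatureMatrix,
    cov_features,
    dct_features,
    extract_features,
    fft_features,
    gram_matrix,
    pca_fit,
    pca_transform,
    svd_features,
)
from sipfft.pssm_io import CANONICAL_ORDER, PssmProfile


def make_profile(matrix, pid="P1"):
    matrix = np.asarray(matrix, dtype=float)
    seq = "".join(CANONICAL_ORDER[i % 20] for i in range(matrix.shape[0]))
    return PssmProfile(protein_id=pid, matrix=matrix, sequence=seq)


def naive_dft2_modulus(A):
    n, m = A.shape
    out = np.zeros((n, m))
    for u in range(n):
        for v in range(m):
            s = 0.0 + 0.0j
            for t in range(n):
                for r in range(m):
                    s += A[t, r] * np.exp(-2j * np.pi * (u * t / n + v * r / m))
            out[u, v] = abs(s) / (n * m)
    return out.ravel()


def naive_dct2(A):
    n, m = A.shape
    out = np.zeros((n, m))
    for u in range(n):
        cu = np.sqrt(1.0 / n) if u == 0 else np.sqrt(2.0 / n)
        for v in range(m):
            cv = np.sqrt(1.0 / m) if v == 0 else np.sqrt(2.0 / m)
            s = 0.0
            for t in range(n):
                for r in range(m):
                    s += A[t, r] * np.cos(np.pi * (2 * t + 1) * u / (2 * n)) * np.cos(
                        np.pi * (2 * r + 1) * v / (2 * m)
                    )
            out[u, v] = cu * cv * s
    return out.ravel()


class TestGramMatrix:
    def test_all_ones_row(self):
        A = gram_matrix(make_profile(np.ones((1, 20))))
        np.testing.assert_array_equal(A, np.ones((20, 20)))

    def test_single_nonzero_entry(self):
        M = np.zeros((3, 20))
        M[0, 2] = 2.0
        A = gram_matrix(make_profile(M))
        expected = np.zeros((20, 20))
        expected[2, 2] = 4.0
        np.testing.assert_array_equal(A, expected)

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(50, 20))
        A = gram_matrix(make_profile(M))
        expected = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                expected[i, j] = sum(M[a, i] * M[a, j] for a in range(50))
        np.testing.assert_allclose(A, expected, atol=1e-10)

    def test_symmetric_psd_for_any_profile(self):
        rng = np.random.default_rng(2)
        A = gram_matrix(make_profile(rng.normal(size=(33, 20))))
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(A)) > -1e-8


class TestGramZScoring:
    def test_zscored_columns_have_unit_diagonal_scale(self):
        rng = np.random.default_rng(20)
        p = make_profile(rng.normal(size=(50, 20)) * np.arange(1, 21))
        A = gram_matrix(p, zscore_columns=True)
        # each standardised column has norm^2 = N
        np.testing.assert_allclose(np.diag(A), 50.0, atol=1e-8)

    def test_constant_column_does_not_blow_up(self):
        M = np.ones((10, 20))
        A = gram_matrix(make_profile(M), zscore_columns=True)
        assert np.all(np.isfinite(A))


class TestFftFeatures:
    def test_constant_matrix_has_only_dc(self):
        v = fft_features(np.ones((20, 20)))
        assert v[0] == pytest.approx(1.0)
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-12)

    def test_conjugate_symmetry_of_modulus(self):
        rng = np.random.default_rng(3)
        V = fft_features(rng.normal(size=(20, 20))).reshape(20, 20)
        for u in range(20):
            for v in range(20):
                assert V[u, v] == pytest.approx(V[(-u) % 20, (-v) % 20], abs=1e-10)

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(20, 20))
        np.testing.assert_allclose(fft_features(A), naive_dft2_modulus(A), atol=1e-10)

    def test_modulus_invariant_to_cyclic_row_shift(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(20, 20))
        np.testing.assert_allclose(
            fft_features(A), fft_features(np.roll(A, 3, axis=0)), atol=1e-10
        )


class TestDctFeatures:
    def test_constant_matrix_single_coefficient(self):
        v = dct_features(np.ones((20, 20)))
        assert abs(v[0]) > 0
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-12)

    def test_orthonormal_preserves_frobenius_norm(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(20, 20))
        assert np.linalg.norm(dct_features(A)) == pytest.approx(np.linalg.norm(A))

    def test_matches_naive_cosine_sum(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(20, 20))
        np.testing.assert_allclose(dct_features(A), naive_dct2(A), atol=1e-10)


class TestSvdFeatures:
    def test_identity_matrix(self):
        v = np.sort(np.abs(svd_features(np.eye(20))))[::-1]
        np.testing.assert_allclose(v[:20], 1.0, atol=1e-12)
        np.testing.assert_allclose(v[20:], 0.0, atol=1e-12)

    def test_psd_singular_values_equal_eigenvalues(self):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(40, 20))
        A = M.T @ M
        _, S, _ = np.linalg.svd(A)
        np.testing.assert_allclose(np.sort(S), np.sort(np.linalg.eigvalsh(A)), rtol=1e-8)

    def test_reconstruction(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(20, 20))
        U, S, Vt = np.linalg.svd(A)
        US = svd_features(A).reshape(20, 20)
        np.testing.assert_allclose(US @ Vt, A, atol=1e-8)


class TestCovFeatures:
    def test_identical_rows_give_zero(self):
        M = np.tile(np.arange(20.0), (5, 1))
        np.testing.assert_allclose(cov_features(make_profile(M)), 0.0, atol=1e-12)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(10)
        C = cov_features(make_profile(rng.normal(size=(25, 20)))).reshape(20, 20)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(C)) > -1e-10

    def test_matches_two_pass_loop(self):
        rng = np.random.default_rng(11)
        M = rng.normal(size=(30, 20))
        expected = np.zeros((20, 20))
        means = [M[:, j].mean() for j in range(20)]
        for i in range(20):
            for j in range(20):
                expected[i, j] = sum(
                    (M[a, i] - means[i]) * (M[a, j] - means[j]) for a in range(30)
                ) / 29
        np.testing.assert_allclose(cov_features(make_profile(M)), expected.ravel(), atol=1e-10)

    def test_single_position_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            cov_features(make_profile(np.ones((1, 20))))


class TestPca:
    def test_full_rank_transform_preserves_distances(self):
        rng = np.random.default_rng(12)
        fm = FeatureMatrix(ids=[f"p{i}" for i in range(30)], X=rng.normal(size=(30, 8)))
        model = pca_fit(fm, q=8)
        Z = pca_transform(model, fm).X
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(Z), pdist(fm.X), atol=1e-8)

    def test_rank_one_data_has_single_nonzero_variance(self):
        rng = np.random.default_rng(13)
        u = rng.normal(size=10)
        X = np.outer(rng.normal(size=25), u)
        fm = FeatureMatrix(ids=[f"p{i}" for i in range(25)], X=X)
        model = pca_fit(fm, q=5)
        assert model.explained_variance[0] > 1e-6
        np.testing.assert_allclose(model.explained_variance[1:], 0.0, atol=1e-10)

    def test_variances_equal_covariance_eigenvalues(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 6))
        fm = FeatureMatrix(ids=[f"p{i}" for i in range(40)], X=X)
        model = pca_fit(fm, q=6)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(model.explained_variance, eig, rtol=1e-8)
        # components orthonormal, variances non-increasing
        np.testing.assert_allclose(model.components.T @ model.components, np.eye(6), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-10)

    def test_q_exceeding_cap_errors(self):
        fm = FeatureMatrix(ids=["a", "b", "c"], X=np.random.default_rng(0).normal(size=(3, 10)))
        with pytest.raises(ValueError, match="exceeds"):
            pca_fit(fm, q=5)

    def test_transformed_total_variance_matches_model(self):
        rng = np.random.default_rng(15)
        fm = FeatureMatrix(ids=[f"p{i}" for i in range(50)], X=rng.normal(size=(50, 12)))
        model = pca_fit(fm, q=12)
        Z = pca_transform(model, fm).X
        assert np.var(Z, axis=0, ddof=1).sum() == pytest.approx(model.explained_variance.sum())

    def test_dimension_mismatch_errors(self):
        rng = np.random.default_rng(16)
        fm = FeatureMatrix(ids=[f"p{i}" for i in range(20)], X=rng.normal(size=(20, 6)))
        model = pca_fit(fm, q=3)
        other = FeatureMatrix(ids=["x"], X=rng.normal(size=(1, 7)))
        with pytest.raises(ValueError, match="does not match"):
            pca_transform(model, other)


class TestExtraction:
    @pytest.mark.parametrize("extractor", ["FFT", "DCT", "SVD", "COV"])
    def test_vectors_are_400_dim_and_finite(self, extractor):
        rng = np.random.default_rng(17)
        profiles = [make_profile(rng.normal(size=(rng.integers(5, 60), 20)), f"p{i}") for i in range(4)]
        fm = extract_features(profiles, labels=[0, 1, 0, 1], extractor=extractor)
        assert fm.X.shape == (4, 400)
        assert np.all(np.isfinite(fm.X))

    def test_pipeline_is_deterministic(self):
        rng = np.random.default_rng(18)
        p = make_profile(rng.normal(size=(40, 20)))
        a = extract_features([p]).X
        b = extract_features([p]).X
        np.testing.assert_array_equal(a, b)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(19)
        fm = FeatureMatrix(
            ids=["a", "b"], X=rng.normal(size=(2, 5)), labels=np.array([0, 1])
        )
        path = tmp_path / "f.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        np.testing.assert_allclose(back.X, fm.X, rtol=1e-12)
        assert back.ids == fm.ids
        np.testing.assert_array_equal(back.labels, fm.labels)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_extractors_finite_on_random_input(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(scale=10.0, size=(20, 20))
    for f in (fft_features, dct_features, svd_features):
        assert np.all(np.isfinite(f(A)))
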
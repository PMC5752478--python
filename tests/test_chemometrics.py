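import numpy as np
import pytest

from triomix.chemometrics import (
    PreprocessSpec,
    opls,
    pca,
    pls1,
    preprocess,
    q2_cv,
    select_by_vip,
    vip,
)
from triomix.io import OmicsMatrix, TriomixError


def _metabolite(values):
    values = np.asarray(values, float)
    return OmicsMatrix(
        layer="metabolite",
        feature_ids=[f"m{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        values=values,
    )


class TestPreprocess:
    def test_halfmin_imputes_half_the_observed_minimum(self):
        m = _metabolite([[4.0, 8.0, np.nan], [1.0, 2.0, 3.0]])
        out = preprocess(m, PreprocessSpec(scaling="none", centering=False))
        assert out.values[0, 2] == pytest.approx(2.0)

    def test_centering_only_zeroes_feature_means(self):
        rng = np.random.default_rng(0)
        m = _metabolite(rng.normal(8, 1, size=(10, 6)))
        out = preprocess(m, PreprocessSpec(scaling="none"))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)

    def test_uv_scaling_gives_unit_variance(self):
        rng = np.random.default_rng(1)
        m = _metabolite(rng.normal(8, 3, size=(10, 8)))
        out = preprocess(m, PreprocessSpec(scaling="uv"))
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0)

    def test_entirely_missing_feature_errors(self):
        m = _metabolite([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(TriomixError, match="m0"):
            preprocess(m)

    def test_sum_normalization_equalizes_linear_totals(self):
        rng = np.random.default_rng(2)
        m = _metabolite(rng.normal(8, 1, size=(20, 5)))
        out = preprocess(m, PreprocessSpec(normalization="sum", scaling="none", centering=False))
        totals = np.power(2.0, out.values).sum(axis=0)
        np.testing.assert_allclose(totals, totals[0])


class TestPca:
    def test_rank_one_matrix_explains_everything(self):
        X = np.outer([1.0, 2.0, -1.0, 0.5], [3.0, 1.0, 2.0])
        model = pca(X, 2)
        assert model.explained[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        model = pca(X, 6)
        recon = model.mean + model.scores @ model.loadings.T
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_diagonal_cloud_loading(self):
        X = np.array([[1.0, 1.0], [-1.0, -1.0], [2.0, 2.0], [-2.0, -2.0]])
        model = pca(X, 1)
        np.testing.assert_allclose(model.loadings[:, 0], [np.sqrt(0.5)] * 2, atol=1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        model = pca(rng.normal(size=(12, 7)), 5)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(5), atol=1e-8)


class TestPls1:
    def test_single_informative_column(self):
        rng = np.random.default_rng(5)
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        X = np.column_stack([2.0 * y + 3.0])
        model = pls1(X, y, 1)
        assert model.r2y == pytest.approx(1.0)

    def test_orthogonal_y_gives_no_explained_variance(self):
        y = np.array([-1.0, 1, -1, 1])
        x = np.array([1.0, 1, -1, -1])  # orthogonal to y
        model = pls1(np.column_stack([x + 0.0, 2 * x]), y + 1e-9 * np.arange(4), 1)
        assert abs(model.q[0]) < 1e-6
        assert model.r2y < 1e-10

    def test_fitted_matches_least_squares_on_scores(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        model = pls1(X, y, 2)
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(model.T, yc, rcond=None)
        np.testing.assert_allclose(model.fitted, model.T @ coef + y.mean(), atol=1e-8)


class TestOpls:
    def test_zero_ortho_equals_one_component_pls(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        y = np.repeat([-1.0, 1.0], 5)
        o = opls(X, y, 0)
        p = pls1(X, y, 1)
        np.testing.assert_allclose(o.fitted, p.fitted, atol=1e-10)
        np.testing.assert_allclose(o.w_pred, p.W[:, 0], atol=1e-10)
        assert o.n_ortho == 0

    def test_pure_predictive_structure_stops_early(self):
        y = np.repeat([-1.0, 1.0], 4)
        X = np.outer(y, [1.0, -2.0, 0.5])
        model = opls(X, y, 2)
        assert model.n_ortho == 0

    def test_orthogonal_scores_uncorrelated_with_y(self):
        rng = np.random.default_rng(8)
        y = np.repeat([-1.0, 1.0], 6)
        X = rng.normal(size=(12, 20)) + np.outer(y, rng.normal(size=20))
        model = opls(X, y, 2)
        yc = y - y.mean()
        for k in range(model.n_ortho):
            t_o = model.T_o[:, k]
            corr = abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
            assert corr < 1e-8

    def test_filtering_strong_orthogonal_direction_raises_r2y(self):
        rng = np.random.default_rng(9)
        y = np.repeat([-1.0, 1.0], 6)
        u = rng.normal(size=12)
        u -= u @ y / (y @ y) * y  # orthogonal nuisance direction
        X = np.outer(y, rng.normal(size=15)) + 5.0 * np.outer(u, rng.normal(size=15)) \
            + 0.1 * rng.normal(size=(12, 15))
        assert opls(X, y, 1).r2y >= pls1(X, y, 1).r2y

    def test_orthogonal_weights_unit_norm_and_perpendicular(self):
        rng = np.random.default_rng(10)
        y = np.repeat([-1.0, 1.0], 5)
        X = rng.normal(size=(10, 12))
        model = opls(X, y, 2)
        for k in range(model.n_ortho):
            assert np.linalg.norm(model.W_o[:, k]) == pytest.approx(1.0)
            assert abs(model.W_o[:, k] @ model.w_pred) < 1e-8


class TestVip:
    def test_single_variable_is_one(self):
        y = np.repeat([-1.0, 1.0], 3)
        X = np.column_stack([y + 0.01 * np.arange(6)])
        np.testing.assert_allclose(vip(pls1(X, y, 1)), [1.0], atol=1e-9)

    def test_equal_weights_all_one(self):
        y = np.repeat([-1.0, 1.0], 4)
        X = np.outer(y, np.ones(4))
        np.testing.assert_allclose(vip(pls1(X, y, 1)), np.ones(4), atol=1e-6)

    def test_sum_of_squares_equals_feature_count(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n, J = rng.integers(6, 14), rng.integers(3, 30)
            X = rng.normal(size=(n, J))
            y = rng.normal(size=n)
            v = vip(pls1(X, y, 1))
            assert np.sum(v**2) == pytest.approx(J, rel=1e-6)

    def test_select_by_vip_ordering_and_threshold(self):
        ids = ["f1", "f2", "f3"]
        assert select_by_vip(np.array([8.5, 7.9, 9.1]), ids, 8.0) == ["f3", "f1"]
        assert select_by_vip(np.array([8.5, 7.9, 9.1]), ids, 10.0) == []
        assert select_by_vip(np.array([2.0, 2.0]), ["b", "a"], 1.0) == ["a", "b"]


class TestQ2:
    def test_separable_classes_give_high_q2(self):
        rng = np.random.default_rng(12)
        y = np.repeat([-1.0, 1.0], 6)
        X = np.outer(y, np.ones(8)) + 0.05 * rng.normal(size=(12, 8))
        assert q2_cv(X, y, n_ortho=1, folds=6, seed=0) > 0.9

    def test_permuted_labels_give_low_q2(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 10))
        ok = 0
        for seed in range(10):
            y = np.repeat([-1.0, 1.0], 6)
            np.random.default_rng(seed).shuffle(y)
            ok += q2_cv(X, y, n_ortho=1, folds=4, seed=seed) <= 0.2
        assert ok >= 9

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(14)
        y = np.repeat([-1.0, 1.0], 6)
        X = np.outer(y, np.ones(5)) + rng.normal(size=(12, 5))
        assert q2_cv(X, y, 1, folds=6, seed=5) == q2_cv(X, y, 1, folds=6, seed=5)
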
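import dataclasses

import numpy as np
import pytest
from scipy import stats

from triomix.config import RunConfig
from triomix.diffexpr import (
    bh_adjust,
    classify_de,
    log2_fold_change,
    quantile_normalize,
    run_de,
    welch_t,
)
from triomix.io import Contrast, OmicsMatrix, SampleMetadata, TriomixError


def _matrix(values, layer="mirna"):
    values = np.asarray(values, float)
    return OmicsMatrix(
        layer=layer,
        feature_ids=[f"f{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i + 1}" for i in range(values.shape[1])],
        values=values,
    )


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        m = _matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        m = _matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_column_means_equal_after_normalization(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(8, 2, size=(50, 6)))
        out = quantile_normalize(m)
        means = out.values.mean(axis=0)
        np.testing.assert_allclose(means, means[0])

    def test_missing_values_rejected(self):
        m = _matrix([[1.0, np.nan], [2.0, 3.0]], layer="metabolite")
        with pytest.raises(TriomixError, match="impute"):
            quantile_normalize(m)


class TestFoldChangeAndWelch:
    def test_lfc_is_difference_of_group_means(self, two_group_meta, contrast):
        m = _matrix([[5, 5, 5, 7, 7, 7], [8.25, 8.25, 8.25, 6, 6, 6], [1, 1, 1, 1, 1, 1]])
        lfc = log2_fold_change(m, two_group_meta, contrast)
        np.testing.assert_allclose(lfc, [2.0, -2.25, 0.0])

    def test_welch_on_1_2_3_vs_4_5_6(self, two_group_meta, contrast):
        m = _matrix([[1, 2, 3, 4, 5, 6]])
        t, df, p = welch_t(m, two_group_meta, contrast)
        # positive t: higher in the comparison group, matching the lfc sign
        assert t[0] == pytest.approx(3.674, abs=1e-3)
        assert df[0] == pytest.approx(4.0)
        assert p[0] == pytest.approx(0.0212, abs=2e-4)
        # independent oracle
        ref = stats.ttest_ind([4, 5, 6], [1, 2, 3], equal_var=False)
        assert t[0] == pytest.approx(ref.statistic)
        assert p[0] == pytest.approx(ref.pvalue)

    def test_swapping_contrast_negates_t_keeps_p(self, two_group_meta, contrast):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(4, 6)))
        t1, _, p1 = welch_t(m, two_group_meta, contrast)
        t2, _, p2 = welch_t(m, two_group_meta, Contrast("treated", "model"))
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)

    def test_degenerate_zero_variance(self, two_group_meta, contrast):
        m = _matrix([[2, 2, 2, 2, 2, 2], [1, 1, 1, 5, 5, 5]])
        t, _, p = welch_t(m, two_group_meta, contrast)
        assert t[0] == 0 and p[0] == 1
        assert p[1] == 0 and np.isinf(t[1])

    def test_agrees_with_permutation_test(self, contrast):
        """Welch p matches a label-permutation null within Monte-Carlo error.

        Eight samples per group keep the permutation support fine enough
        (C(16,8)=12870 splits) for the t-approximation to be comparable.
        """
        rng = np.random.default_rng(42)
        meta = SampleMetadata(
            group_of={f"s{i + 1}": ("model" if i < 8 else "treated") for i in range(16)}
        )
        m = _matrix(rng.normal(0, 1, size=(5, 16)) + rng.normal(0, 0.3, size=(5, 1)))
        t, _, p = welch_t(m, meta, contrast)
        n_perm = 4000
        for i in range(5):
            vals = m.values[i]
            obs = abs(t[i])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(vals)
                a, b = perm[:8], perm[8:]
                tp = (b.mean() - a.mean()) / np.sqrt(a.var(ddof=1) / 8 + b.var(ddof=1) / 8)
                count += abs(tp) >= obs - 1e-12
            p_perm = count / n_perm
            sd = np.sqrt(max(p[i] * (1 - p[i]), 1e-4) / n_perm)
            assert abs(p_perm - p[i]) < 3 * sd + 0.02


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust(np.array([1.0])), [1.0])

    def test_bounds_and_rank_monotonicity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert np.all(q <= 1) and np.all(q >= p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestClassifyAndRunDe:
    def test_threshold_logic(self):
        cfg = RunConfig()
        table = classify_de(["a", "b", "c"], np.array([2.0, 2.0, -2.0]),
                            np.array([0.01, 0.2, 0.01]), cfg)
        d = dict(zip(table["feature_id"], table["direction"]))
        assert d == {"a": "up", "b": "ns", "c": "down"}

    def test_sorted_by_p_then_abs_lfc_then_id(self):
        table = classify_de(
            ["b", "a", "c"], np.array([1.0, 3.0, 3.0]), np.array([0.5, 0.01, 0.5])
        )
        assert table["feature_id"].tolist() == ["a", "c", "b"]

    def test_column_order_invariance(self, tiny_matrix, two_group_meta, contrast):
        cfg = RunConfig()
        out1 = run_de(tiny_matrix, two_group_meta, contrast, cfg)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = dataclasses.replace(
            tiny_matrix,
            sample_ids=[tiny_matrix.sample_ids[i] for i in perm],
            values=tiny_matrix.values[:, perm],
        )
        out2 = run_de(shuffled, two_group_meta, contrast, cfg)
        assert out1["feature_id"].tolist() == out2["feature_id"].tolist()
        np.testing.assert_allclose(out1["p"], out2["p"])
        np.testing.assert_allclose(out1["log2fc"], out2["log2fc"])

    def test_tiny_matrix_calls(self, tiny_matrix, two_group_meta, contrast):
        out = run_de(tiny_matrix, two_group_meta, contrast, RunConfig(), normalization="none")
        d = dict(zip(out["feature_id"], out["direction"]))
        assert d == {"f1": "up", "f2": "ns", "f3": "down"}
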
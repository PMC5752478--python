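import numpy as np
import pytest

from triomix.crossomics import (
    CrossEdge,
    correlate_layers,
    filter_edges,
    pearson_p,
    pearson_r,
    rank_hubs,
)
from triomix.io import OmicsMatrix, TriomixError
from triomix.simulate import SimConfig, generate_triomics


def _layer(layer, ids, values, samples=None):
    values = np.asarray(values, float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return OmicsMatrix(layer=layer, feature_ids=ids, sample_ids=samples, values=values)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        assert pearson_r([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [6, 4, 2])[0] == pytest.approx(-1.0)

    def test_hand_computed_point_eight(self):
        r, n = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8) and n == 4

    def test_pairwise_complete_deletion_updates_n(self):
        r, n = pearson_r([1, 2, np.nan, 4, 5], [2, 4, 6, 8, np.nan])
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_constant_vector_flagged_not_computable(self):
        r, _ = pearson_r([1.0, 1.0, 1.0], [1, 2, 3])
        assert r is None

    def test_p_values(self):
        assert pearson_p(0.0, 10) == pytest.approx(1.0)
        assert pearson_p(1.0, 5) == 0.0
        assert pearson_p(-1.0, 5) == 0.0
        # closed form at n=4: p = 1 - r exactly (df=2 t-CDF)
        assert pearson_p(0.9, 4) == pytest.approx(0.1, abs=1e-9)

    def test_p_agrees_with_permutation_null(self):
        """Pearson p matches a shuffle test within 3 Monte-Carlo SDs."""
        rng = np.random.default_rng(0)
        n_perm = 3000
        for _ in range(5):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.3 * x
            r, n = pearson_r(x, y)
            p = pearson_p(r, n)
            count = 0
            for _ in range(n_perm):
                rp, _ = pearson_r(x, rng.permutation(y))
                count += abs(rp) >= abs(r) - 1e-12
            sd = np.sqrt(max(p * (1 - p), 1e-4) / n_perm)
            assert abs(count / n_perm - p) < 3 * sd + 0.02


class TestCorrelateLayers:
    def test_edge_combinatorics(self):
        rng = np.random.default_rng(1)
        mats = {
            "mirna": _layer("mirna", ["a", "b"], rng.normal(size=(2, 6))),
            "protein": _layer("protein", ["p", "q", "r"], rng.normal(size=(3, 6))),
        }
        edges = correlate_layers({"mirna": ["a", "b"], "protein": ["p", "q", "r"]}, mats)
        assert len(edges) == 6
        assert all(e.layer_a < e.layer_b for e in edges)

    def test_empty_sig_sets_give_empty_list(self):
        mats = {"mirna": _layer("mirna", ["a"], np.zeros((1, 4)))}
        assert correlate_layers({"mirna": [], "protein": []}, mats) == []

    def test_unmatched_samples_error(self):
        mats = {
            "mirna": _layer("mirna", ["a"], np.zeros((1, 4)), [f"s{i}" for i in range(4)]),
            "protein": _layer("protein", ["p"], np.zeros((1, 4)), [f"x{i}" for i in range(4)]),
        }
        with pytest.raises(TriomixError, match="matched"):
            correlate_layers({"mirna": ["a"], "protein": ["p"]}, mats)

    def test_invariant_to_feature_and_sample_permutation(self):
        rng = np.random.default_rng(2)
        vals_m = rng.normal(size=(3, 8))
        vals_p = rng.normal(size=(2, 8))
        samples = [f"s{i}" for i in range(8)]
        mats = {
            "mirna": _layer("mirna", ["a", "b", "c"], vals_m, samples),
            "protein": _layer("protein", ["p", "q"], vals_p, samples),
        }
        e1 = correlate_layers({"mirna": ["a", "b", "c"], "protein": ["p", "q"]}, mats)
        perm = [5, 2, 7, 0, 3, 6, 1, 4]
        mats2 = {
            "mirna": _layer("mirna", ["c", "a", "b"], vals_m[[2, 0, 1]][:, perm],
                            [samples[i] for i in perm]),
            "protein": _layer("protein", ["q", "p"], vals_p[[1, 0]][:, perm],
                              [samples[i] for i in perm]),
        }
        e2 = correlate_layers({"mirna": ["c", "b", "a"], "protein": ["q", "p"]}, mats2,
                              samples=[samples[i] for i in perm])
        assert [(e.feat_a, e.feat_b) for e in e1] == [(e.feat_a, e.feat_b) for e in e2]
        np.testing.assert_allclose([e.r for e in e1], [e.r for e in e2], atol=1e-12)

    def test_planted_block_hub_member_edge_is_strong(self, small_sim_cfg):
        mats, meta, truth = generate_triomics(small_sim_cfg)
        block = truth.blocks[0]
        member = block.members[0][0]
        edges = correlate_layers(
            {"mirna": [block.hub], "protein": [member]}, mats, meta
        )
        assert len(edges) == 1
        assert abs(edges[0].r) >= 0.9


class TestFilterAndRank:
    def test_filter_thresholds(self):
        e_keep = CrossEdge("a", "mirna", "p", "protein", r=0.95, p=0.01, n=12)
        e_p = CrossEdge("a", "mirna", "p", "protein", r=0.95, p=0.06, n=12)
        e_neg = CrossEdge("a", "mirna", "p", "protein", r=-0.92, p=0.01, n=12)
        out = filter_edges([e_keep, e_p, e_neg], 0.9, 0.05)
        assert out == [e_keep, e_neg]
        assert out[1].r < 0  # sign preserved

    def test_filter_identity_and_monotonicity(self):
        rng = np.random.default_rng(3)
        edges = [
            CrossEdge("a%d" % i, "mirna", "p%d" % i, "protein",
                      r=float(rng.uniform(-1, 1)), p=float(rng.uniform()), n=12)
            for i in range(50)
        ]
        assert filter_edges(edges, 0.0, 1.0) == edges
        loose = set(id(e) for e in filter_edges(edges, 0.5, 0.2))
        tight = filter_edges(edges, 0.7, 0.1)
        assert all(id(e) in loose for e in tight)

    def test_rank_hubs_ordering(self):
        def e(m, p, r):
            return CrossEdge(m, "mirna", p, "protein", r=r, p=0.01, n=12)

        edges = [e("hubA", "p1", 0.95), e("hubA", "p2", 0.95), e("hubA", "p3", 0.95),
                 e("hubB", "p1", 0.99),
                 e("hubC", "p1", 0.95), e("hubC", "p2", 0.95), e("hubC", "p3", 0.92)]
        hubs = rank_hubs(edges)
        assert [h.mirna_id for h in hubs] == ["hubA", "hubC", "hubB"]
        assert hubs[0].degree == 3
        assert hubs[0].partners == ["p1", "p2", "p3"]
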
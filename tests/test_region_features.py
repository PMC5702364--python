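import numpy as np
import pandas as pd
import pytest

from hyperbrain.region_features import (RegionFeatureTable,
                                        compute_region_features, hcc1, hcc2,
                                        hcc3, ks_fdr_select,
                                        residualize_confounds)
from conftest import make_network, random_hypergraph
from oracles import hcc_brute


class TestHandCases:
    def test_isolated_node_all_zero(self):
        net = make_network([{1, 2}], 4)
        assert hcc1(net, 3) == hcc2(net, 3) == hcc3(net, 3) == 0.0

    def test_hcc1_pair_connected_without_v(self):
        net = make_network([{0, 1, 2}, {1, 2}], 3)
        assert hcc1(net, 0) == 1.0

    def test_hcc2_single_edge_triangle(self):
        net = make_network([{0, 1, 2}], 3)
        assert hcc2(net, 0) == 1.0

    def test_hcc2_zero_for_disjoint_pairs(self):
        net = make_network([{0, 1}, {0, 2}], 3)
        assert hcc2(net, 0) == 0.0

    def test_hcc3_overlapping_star(self):
        # edges {v,a,b}, {v,a,c}: sum(|e|-1)=4, |N|=3 -> 2*(4-3)/(3*1)=2/3
        net = make_network([{0, 1, 2}, {0, 1, 3}], 4)
        assert hcc3(net, 0) == pytest.approx(2 / 3)

    def test_hcc3_disjoint_star_is_zero(self):
        net = make_network([{0, 1}, {0, 2}], 3)
        assert hcc3(net, 0) == 0.0

    def test_single_edge_star_degenerate_zero(self):
        net = make_network([{0, 1, 2}], 3)
        assert hcc3(net, 0) == 0.0

    def test_out_of_range_node(self):
        net = make_network([{0, 1}], 2)
        with pytest.raises(IndexError):
            hcc1(net, 7)


class TestOracleEquivalence:
    def test_all_three_match_brute_force(self, rng):
        for _ in range(200):
            net = random_hypergraph(rng)
            v = int(rng.integers(net.n_nodes))
            b1, b2, b3 = hcc_brute(net, v)
            assert hcc1(net, v) == b1
            assert hcc2(net, v) == b2
            assert hcc3(net, v) == b3
            assert 0 <= b1 <= 1 and 0 <= b2 <= 1 and b3 >= 0

    def test_invariant_under_edge_order_and_relabeling(self, rng):
        for _ in range(20):
            net = random_hypergraph(rng)
            if not net.edges:
                continue
            perm = rng.permutation(net.n_nodes)
            shuffled = list(net.edges)
            rng.shuffle(shuffled)
            relabeled = make_network(
                [{int(perm[v]) for v in e.nodes} for e in shuffled],
                net.n_nodes)
            v = int(rng.integers(net.n_nodes))
            assert hcc1(net, v) == hcc1(relabeled, int(perm[v]))
            assert hcc2(net, v) == hcc2(relabeled, int(perm[v]))
            assert hcc3(net, v) == hcc3(relabeled, int(perm[v]))


class TestFeatureTable:
    def test_matches_per_node_calls_and_equivariance(self, rng):
        nets = [random_hypergraph(rng, max_nodes=8) for _ in range(6)]
        nets = [make_network([e.nodes for e in n.edges], 8) for n in nets]
        table = compute_region_features(nets)
        for i, net in enumerate(nets):
            for v in range(8):
                assert table.features.iloc[i][f"ROI{v + 1:03d}_HCC1"] == hcc1(net, v)
                assert table.features.iloc[i][f"ROI{v + 1:03d}_HCC2"] == hcc2(net, v)
                assert table.features.iloc[i][f"ROI{v + 1:03d}_HCC3"] == hcc3(net, v)
        perm = [3, 1, 0, 5, 2, 4]
        permuted = compute_region_features([nets[i] for i in perm])
        np.testing.assert_array_equal(permuted.features.to_numpy(),
                                      table.features.to_numpy()[perm])

    def test_empty_networks_zero_table(self):
        table = compute_region_features([make_network([], 5)] * 3)
        assert (table.features.to_numpy() == 0).all()

    def test_mismatched_node_counts_rejected(self):
        with pytest.raises(ValueError, match="node count"):
            compute_region_features([make_network([], 4), make_network([], 5)])


def toy_table(x, labels, covariates=None):
    frame = pd.DataFrame(np.asarray(x, float),
                         columns=[f"f{i}" for i in range(np.shape(x)[1])])
    return RegionFeatureTable(features=frame,
                              labels=np.asarray(labels, int),
                              covariates=covariates)


class TestResidualize:
    def test_constant_covariates_leave_table_unchanged(self, rng):
        x = rng.random((10, 4))
        table = toy_table(x, [0] * 5 + [1] * 5,
                          covariates=np.ones((10, 3)))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            out = residualize_confounds(table)
        np.testing.assert_allclose(out.features.to_numpy(), x, atol=1e-12)

    def test_linear_in_age_becomes_constant(self, rng):
        covs = np.column_stack([rng.normal(70, 5, 12),
                                rng.integers(0, 2, 12),
                                rng.normal(12, 3, 12)])
        x = np.outer(2.0 * covs[:, 0] - 1.0, np.ones(3))
        table = toy_table(x, [0] * 6 + [1] * 6, covariates=covs)
        out = residualize_confounds(table)
        expect = np.tile(x.mean(axis=0), (12, 1))
        np.testing.assert_allclose(out.features.to_numpy(), expect, atol=1e-8)

    def test_matches_normal_equations_and_orthogonality(self, rng):
        covs = rng.standard_normal((15, 3))
        x = rng.standard_normal((15, 6))
        table = toy_table(x, [0] * 7 + [1] * 8, covariates=covs)
        out = residualize_confounds(table)
        design = np.column_stack([np.ones(15), covs])
        beta = np.linalg.solve(design.T @ design, design.T @ x)
        expect = x - design @ beta + x.mean(axis=0)
        np.testing.assert_allclose(out.features.to_numpy(), expect, atol=1e-10)
        resid = out.features.to_numpy() - x.mean(axis=0)
        centered = covs - covs.mean(axis=0)
        np.testing.assert_allclose(centered.T @ resid, 0, atol=1e-8)


class TestKSSelect:
    def test_identical_groups_select_nothing(self):
        x = np.tile(np.tile(np.arange(4.0), 2)[:, None], (1, 3))
        out = ks_fdr_select(toy_table(x, [0] * 4 + [1] * 4))
        assert (out.selection["D"] == 0).all()
        assert (out.selection["p"] == 1).all()
        assert not out.selection["selected"].any()

    def test_d_statistic_matches_ecdf_sup_difference(self):
        col = np.array([0.1, 0.2, 0.3, 0.4, 0.15, 0.25, 0.9, 0.95])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        out = ks_fdr_select(toy_table(col[:, None], labels))
        grid = np.unique(col)
        ecdf0 = [(col[labels == 0] <= g).mean() for g in grid]
        ecdf1 = [(col[labels == 1] <= g).mean() for g in grid]
        d_expected = max(abs(a - b) for a, b in zip(ecdf0, ecdf1))
        assert out.selection["D"].iloc[0] == pytest.approx(d_expected)

    def test_lowering_q_never_adds_selections(self, rng):
        x = rng.standard_normal((30, 40))
        x[:15, :5] += 2.0
        table = toy_table(x, [0] * 15 + [1] * 15)
        sel_strict = ks_fdr_select(table, q=0.01).selection["selected"]
        sel_loose = ks_fdr_select(table, q=0.10).selection["selected"]
        assert (sel_loose | ~sel_strict).all()

    def test_small_group_rejected(self):
        x = np.random.default_rng(0).random((5, 2))
        with pytest.raises(ValueError, match="at least 3"):
            ks_fdr_select(toy_table(x, [0, 0, 1, 1, 1]))
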
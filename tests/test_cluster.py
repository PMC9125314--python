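"""Cluster-based permutation statistics: statistic maps, clustering under the
combined sensor × feature adjacency, and Monte-Carlo inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegcomplex import (
    FeatureMap,
    InvalidArgumentError,
    Montage,
    NeighborhoodGraph,
    build_neighborhood,
    find_clusters,
    group_tmap,
    permutation_test,
    report_clusters,
    score_rmap,
)


def chain_graph(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return NeighborhoodGraph(adj, tuple(f"E{i}" for i in range(n)))


def make_fm(data, kind="scale"):
    data = np.asarray(data, dtype=float)
    _, n_ch, n_feat = data.shape
    return FeatureMap(
        data, tuple(f"E{i}" for i in range(n_ch)), tuple(range(n_feat)), kind
    )


class TestGroupTMap:
    def test_identical_groups_zero(self, rng):
        half = rng.standard_normal((4, 3, 5))
        fm = make_fm(np.concatenate([half, half]))
        sm = group_tmap(fm, np.array([True] * 4 + [False] * 4))
        np.testing.assert_allclose(sm.stat, 0.0, atol=1e-12)
        assert not sm.pos_mask.any() and not sm.neg_mask.any()

    def test_hand_computed_t(self):
        # {1,2,3} vs {4,5,6}: pooled sd 1, se √(2/3) → t = −3.674
        data = np.array([1.0, 2, 3, 4, 5, 6]).reshape(6, 1, 1)
        sm = group_tmap(make_fm(data), np.array([True] * 3 + [False] * 3))
        assert sm.stat[0, 0] == pytest.approx(-3.674, abs=1e-3)
        assert sm.df == 4

    def test_label_swap_negates(self, rng):
        fm = make_fm(rng.standard_normal((10, 4, 6)))
        g = np.array([True] * 5 + [False] * 5)
        np.testing.assert_allclose(
            group_tmap(fm, g).stat, -group_tmap(fm, ~g).stat, atol=1e-12
        )

    def test_nan_excluded_pairwise(self, rng):
        data = rng.standard_normal((8, 2, 2))
        data[0, 0, 0] = np.nan
        sm = group_tmap(make_fm(data), np.array([True] * 4 + [False] * 4))
        assert np.isfinite(sm.stat[0, 0])

    def test_empty_group_rejected(self, rng):
        fm = make_fm(rng.standard_normal((4, 2, 2)))
        with pytest.raises(InvalidArgumentError):
            group_tmap(fm, np.array([True] * 4))


class TestScoreRMap:
    def test_scores_equal_to_pixel_give_unit_rho(self, rng):
        data = rng.standard_normal((8, 1, 1))
        fm = make_fm(data)
        sm = score_rmap(fm, data[:, 0, 0])
        assert sm.rho[0, 0] == pytest.approx(1.0)
        assert sm.pos_mask[0, 0]
        sm = score_rmap(fm, -data[:, 0, 0])
        assert sm.rho[0, 0] == pytest.approx(-1.0)

    def test_matches_scipy_spearman(self):
        vals = np.array([2.0, 1, 4, 3, 5])
        fm = make_fm(vals.reshape(5, 1, 1))
        sm = score_rmap(fm, np.arange(1.0, 6.0))
        expected = stats.spearmanr(np.arange(5), vals).statistic  # = 0.8
        assert sm.rho[0, 0] == pytest.approx(expected)
        assert sm.rho[0, 0] == pytest.approx(0.8)

    def test_constant_scores_rejected(self, rng):
        fm = make_fm(rng.standard_normal((6, 2, 2)))
        with pytest.raises(InvalidArgumentError):
            score_rmap(fm, np.ones(6))


class TestFindClusters:
    def _statmap(self, t, tcrit=2.0):
        from eegcomplex.cluster import StatMap

        t = np.asarray(t, dtype=float)
        return StatMap(t, 10, t > tcrit, t < -tcrit)

    def test_single_pixel_cluster(self):
        t = np.zeros((3, 3))
        t[1, 1] = 3.0
        cl = find_clusters(self._statmap(t), chain_graph(3))
        assert len(cl) == 1
        assert cl[0].pixels == [(1, 1)]
        assert cl[0].mass == pytest.approx(3.0)

    def test_nonadjacent_channels_split(self):
        t = np.zeros((3, 2))
        t[0, 0] = t[2, 0] = 2.5  # ends of a chain, not adjacent
        cl = find_clusters(self._statmap(t), chain_graph(3))
        assert len(cl) == 2

    def test_block_flood_fill_oracle(self):
        t = np.zeros((4, 5))
        t[0:3, 1:4] = 2.5  # 3×3 block on a chain montage
        cl = find_clusters(self._statmap(t), chain_graph(4))
        assert len(cl) == 1
        assert cl[0].n_pixels == 9
        assert cl[0].mass == pytest.approx(9 * 2.5)

    def test_pair_features_cluster_spatially_only(self):
        t = np.zeros((2, 2))
        t[0, 0] = t[0, 1] = 2.5  # same channel, two PAC pairs
        from eegcomplex.cluster import StatMap

        sm = StatMap(t, 10, t > 2, t < -2)
        cl = find_clusters(sm, chain_graph(2), features_adjacent=False)
        assert len(cl) == 2

    def test_mixed_signs_cluster_separately(self):
        t = np.zeros((2, 3))
        t[0, 0], t[0, 1] = 2.5, -2.5
        cl = find_clusters(self._statmap(t), chain_graph(2))
        signs = sorted(c.sign for c in cl)
        assert signs == [-1, 1]


class TestPermutationTest:
    def test_exact_enumeration_matches_bruteforce(self, rng):
        # 4+4 subjects → 70 distinct splits: compare against a brute-force
        data = rng.standard_normal((8, 3, 4))
        data[:4, 1, :] += 2.0
        fm = make_fm(data)
        graph = chain_graph(3)
        labels = np.array([True] * 4 + [False] * 4)
        with pytest.warns(UserWarning, match="complete enumeration"):
            cr = permutation_test(fm, labels, graph, n_perm=100, seed=0)
        assert cr.exact and cr.n_permutations == 70

        # independent oracle: enumerate splits, flood-fill via find_clusters
        tcrit = stats.t.ppf(0.975, 6)
        null_pos = []
        for pick in itertools.combinations(range(8), 4):
            g = np.zeros(8, dtype=bool)
            g[list(pick)] = True
            sm = group_tmap(fm, g)
            masses = [c.mass for c in find_clusters(sm, graph) if c.sign > 0]
            null_pos.append(max(masses) if masses else 0.0)
        obs = max(c.mass for c in cr.clusters if c.sign > 0)
        b = sum(m >= obs for m in null_pos)
        expected_p = min(1.0, 2 * b / 70)
        top = max(cr.clusters, key=lambda c: c.mass)
        assert top.p_mc == pytest.approx(expected_p)

    def test_strong_effect_detected(self, rng):
        data = rng.standard_normal((20, 6, 8))
        data[:10, :3, :4] += 1.8
        fm = make_fm(data)
        cr = permutation_test(
            fm, np.array([True] * 10 + [False] * 10), chain_graph(6),
            n_perm=500, seed=1,
        )
        sig = cr.significant()
        assert sig and sig[0].sign > 0
        assert {c for c, _ in sig[0].pixels} >= {0, 1, 2}

    def test_subject_order_invariance(self, rng):
        # exact under complete enumeration (4+4 → 70 splits)
        data = rng.standard_normal((8, 4, 4))
        data[:4] += 1.5
        labels = np.array([True] * 4 + [False] * 4)
        fm = make_fm(data)
        perm = rng.permutation(8)
        fm2 = make_fm(data[perm])
        graph = chain_graph(4)
        with pytest.warns(UserWarning):
            p1 = permutation_test(fm, labels, graph, n_perm=100, seed=5)
        with pytest.warns(UserWarning):
            p2 = permutation_test(fm2, labels[perm], graph, n_perm=100, seed=5)
        assert [c.p_mc for c in p1.clusters] == [c.p_mc for c in p2.clusters]

    def test_channel_permutation_invariance(self, rng):
        data = rng.standard_normal((12, 4, 3))
        data[:6, 0] += 1.5
        labels = np.array([True] * 6 + [False] * 6)
        graph = chain_graph(4)
        perm = np.array([2, 0, 3, 1])
        adj2 = graph.adjacency[np.ix_(perm, perm)]
        graph2 = NeighborhoodGraph(adj2, tuple(f"E{i}" for i in perm))
        p1 = permutation_test(make_fm(data), labels, graph, n_perm=300, seed=7)
        p2 = permutation_test(
            make_fm(data[:, perm, :]), labels, graph2, n_perm=300, seed=7
        )
        assert sorted(c.p_mc for c in p1.clusters) == pytest.approx(
            sorted(c.p_mc for c in p2.clusters)
        )

    def test_score_design_detects_correlation(self, rng):
        scores = rng.normal(size=16)
        data = rng.standard_normal((16, 4, 5)) * 0.5
        data[:, :2, :] += scores[:, None, None]
        fm = make_fm(data)
        cr = permutation_test(
            fm, {"scores": scores}, chain_graph(4), n_perm=300, seed=2
        )
        sig = cr.significant()
        assert sig and sig[0].sign > 0

    def test_no_suprathreshold_is_empty_not_p1(self, rng):
        data = rng.standard_normal((12, 3, 3)) * 1e-3
        data += rng.standard_normal((1, 3, 3)) * 10  # common offset, no contrast
        fm = make_fm(np.tile(data.mean(axis=0), (12, 1, 1)))
        cr = permutation_test(
            fm, np.array([True] * 6 + [False] * 6), chain_graph(3),
            n_perm=200, seed=0,
        )
        assert cr.clusters == []

    def test_p_floor_respected(self, rng):
        data = rng.standard_normal((20, 3, 3))
        data[:10] += 5.0
        cr = permutation_test(
            make_fm(data), np.array([True] * 10 + [False] * 10), chain_graph(3),
            n_perm=200, seed=0,
        )
        for c in cr.clusters:
            assert 1.0 / (cr.n_permutations + 1) <= c.p_mc <= 1.0


class TestReport:
    def test_empty_result_header_only(self):
        from eegcomplex.cluster import ClusterResult

        rep = report_clusters(ClusterResult([], 100, 0), ("a", "b"), (1, 2))
        assert len(rep) == 0
        assert "p_mc" in rep.columns

    def test_round_trip(self, tmp_path, rng):
        data = rng.standard_normal((12, 3, 3))
        data[:6, 0, :] += 3.0
        cr = permutation_test(
            make_fm(data), np.array([True] * 6 + [False] * 6), chain_graph(3),
            n_perm=200, seed=0,
        )
        rep = report_clusters(cr, ("E0", "E1", "E2"), (1, 2, 3))
        assert len(rep) == len(cr.clusters)
        path = tmp_path / "report.csv"
        rep.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert len(back) == len(rep)
        np.testing.assert_allclose(back["mass"], rep["mass"])
        assert (back["n_pixels"] == rep["n_pixels"]).all()
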
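"""fROI labeling, voxel correlations, thresholded networks, fROI weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flnet.config import ValidationError
from flnet.networks import (
    LabelMap,
    build_voxel_network,
    froi_weights,
    label_frois,
    region_network,
    voxel_correlations,
)

from conftest import froi_weight_oracle, make_froi_nodes


def _label_map(labels, names, excluded=()):
    return LabelMap(np.asarray(labels, dtype=np.int32), names, frozenset(excluded))


class TestLabelFrois:
    def test_two_blobs_become_two_named_frois(self):
        labels = np.zeros((8, 8, 4), int)
        labels[1:3, 1:3, 1:3] = 1
        labels[5:7, 5:7, 1:3] = 2
        lm = _label_map(labels, {1: "BA(L)", 2: "WA(L)"})
        active = labels > 0
        nodes = label_frois(active, lm)
        regions = sorted(f.region for f in nodes.frois.values())
        assert regions == ["BA(L)", "WA(L)"]
        assert sorted(f.size for f in nodes.frois.values()) == [8, 8]

    def test_excluded_region_emits_no_froi(self):
        labels = np.zeros((6, 6, 4), int)
        labels[1:3, 1:3, 1:3] = 7
        lm = _label_map(labels, {7: "visual"}, excluded={7})
        nodes = label_frois(labels > 0, lm)
        assert nodes.n_nodes == 0

    def test_component_spanning_two_labels_splits_by_label(self):
        # one contiguous 10-voxel bar: 6 voxels in region A, 4 in region B
        labels = np.zeros((10, 3, 3), int)
        labels[0:6, 0, 0] = 1
        labels[6:10, 0, 0] = 2
        lm = _label_map(labels, {1: "A", 2: "B"})
        active = np.zeros_like(labels, bool)
        active[0:10, 0, 0] = True
        nodes = label_frois(active, lm)
        by_region = {f.region: f.size for f in nodes.frois.values()}
        assert by_region == {"A": 6, "B": 4}

    def test_background_active_voxels_kept_as_flagged_unlabeled(self):
        labels = np.zeros((5, 5, 3), int)
        active = np.zeros_like(labels, bool)
        active[2, 2, 1] = True
        nodes = label_frois(active, _label_map(labels, {}))
        (froi,) = nodes.frois.values()
        assert froi.region == "unlabeled" and froi.flagged

    def test_grid_mismatch_rejected(self):
        lm = _label_map(np.zeros((4, 4, 4), int), {})
        with pytest.raises(ValidationError, match="grid"):
            label_frois(np.zeros((5, 4, 4), bool), lm)


class TestVoxelCorrelations:
    def test_identical_and_negated_series(self, rng):
        T = 160
        x = rng.standard_normal(T)
        data = np.stack([x, x, -x]).reshape(3, 1, 1, T)
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        C = voxel_correlations(data, coords)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)

    def test_independent_noise_stays_below_null_bound(self):
        # T = 160: |C| < 0.32 for independent series except with prob < 1e-3
        rng = np.random.default_rng(77)
        data = rng.standard_normal((20, 1, 1, 160))
        coords = np.array([[i, 0, 0] for i in range(20)])
        C = voxel_correlations(data, coords)
        off = C[~np.eye(20, dtype=bool)]
        assert np.max(np.abs(off)) < 0.32

    def test_constant_series_flagged_as_zero(self, paradigm):
        data = np.ones((2, 1, 1, 160))
        data[0, 0, 0] = np.random.default_rng(0).standard_normal(160)
        C = voxel_correlations(data, np.array([[0, 0, 0], [1, 0, 0]]))
        assert C[0, 1] == 0.0 and C[1, 1] == 1.0


class TestBuildVoxelNetwork:
    def test_absolute_value_thresholding_keeps_negative_links(self):
        C = np.array([[1.0, -0.9], [-0.9, 1.0]])
        nodes = make_froi_nodes({0: 1, 1: 1})
        net = build_voxel_network(C, nodes, theta=0.8)
        assert net.graph.has_edge(0, 1)
        assert net.frac_negative == 1.0

    def test_unreachable_threshold_gives_edgeless_network(self):
        C = np.array([[1.0, 0.3], [0.3, 1.0]])
        nodes = make_froi_nodes({0: 1, 1: 1})
        net = build_voxel_network(C, nodes, theta=0.5)
        assert net.graph.number_of_edges() == 0

    def test_adjacency_equals_elementwise_indicator(self):
        C = np.array(
            [[1.0, 0.6, -0.2], [0.6, 1.0, 0.55], [-0.2, 0.55, 1.0]]
        )
        nodes = make_froi_nodes({0: 3})
        net = build_voxel_network(C, nodes, theta=0.5)
        edges = {tuple(sorted(e)) for e in net.graph.edges()}
        assert edges == {(0, 1), (1, 2)}

    @pytest.mark.parametrize("theta", [0.0, 1.2, -0.5])
    def test_invalid_theta_rejected(self, theta):
        nodes = make_froi_nodes({0: 2})
        with pytest.raises(ValidationError):
            build_voxel_network(np.eye(2), nodes, theta)


class TestFroiWeights:
    def _net_from_edges(self, sizes, edges, regions=None):
        n = sum(sizes.values())
        C = np.eye(n)
        for i, j in edges:
            C[i, j] = C[j, i] = 0.9
        nodes = make_froi_nodes(sizes, regions)
        return build_voxel_network(C, nodes, theta=0.5)

    def test_complete_bipartite_pair_reaches_upper_bound(self):
        # S_i = S_j = 2, all 4 cross pairs linked: W = 4/4 = 1
        net = self._net_from_edges({0: 2, 1: 2}, [(0, 2), (0, 3), (1, 2), (1, 3)])
        G = froi_weights(net)
        assert G[0][1]["W"] == pytest.approx(1.0)

    def test_sparse_cross_links_give_small_weights(self):
        # 2 cross links, sizes 10+10 -> W = 0.1 ; sizes 100+100 -> W = 0.01
        net = self._net_from_edges({0: 10, 1: 10}, [(0, 10), (1, 11)])
        assert froi_weights(net)[0][1]["W"] == pytest.approx(0.1)
        net = self._net_from_edges({0: 100, 1: 100}, [(0, 100), (1, 101)])
        assert froi_weights(net)[0][1]["W"] == pytest.approx(0.01)

    def test_intra_froi_edges_do_not_contribute(self):
        net = self._net_from_edges({0: 3, 1: 3}, [(0, 1), (1, 2), (0, 3)])
        G = froi_weights(net)
        assert G[0][1]["W"] == pytest.approx(1 / 6)

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_double_loop_oracle_on_random_networks(self, data):
        n_frois = data.draw(st.integers(2, 4))
        sizes = {f: data.draw(st.integers(1, 8)) for f in range(n_frois)}
        n = sum(sizes.values())
        membership = {}
        i = 0
        for f, s in sizes.items():
            for _ in range(s):
                membership[i] = f
                i += 1
        possible = [(a, b) for a in range(n) for b in range(a + 1, n)]
        edges = set(data.draw(st.lists(st.sampled_from(possible), unique=True, max_size=len(possible))))
        net = self._net_from_edges(sizes, edges)
        ours = {
            (min(u, v), max(u, v)): d["W"] for u, v, d in froi_weights(net).edges(data=True)
        }
        oracle = froi_weight_oracle(edges, membership)
        assert set(ours) == set(oracle)
        for k in oracle:
            assert ours[k] == pytest.approx(oracle[k])
            s1, s2 = sizes[k[0]], sizes[k[1]]
            assert ours[k] <= s1 * s2 / (s1 + s2) + 1e-12

    def test_adding_cross_edge_strictly_increases_weight(self):
        base = self._net_from_edges({0: 4, 1: 4}, [(0, 4)])
        more = self._net_from_edges({0: 4, 1: 4}, [(0, 4), (1, 5)])
        assert froi_weights(more)[0][1]["W"] > froi_weights(base)[0][1]["W"]

    def test_voxel_relabeling_leaves_weights_invariant(self, rng):
        sizes = {0: 5, 1: 4, 2: 3}
        n = 12
        edges = {(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.3}
        net = self._net_from_edges(sizes, edges)
        perm = rng.permutation(n)
        perm_edges = {(min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j in edges}
        membership = {int(perm[i]): (0 if i < 5 else 1 if i < 9 else 2) for i in range(n)}
        oracle = froi_weight_oracle(perm_edges, membership)
        ours = {
            (min(u, v), max(u, v)): d["W"] for u, v, d in froi_weights(net).edges(data=True)
        }
        assert {round(v, 12) for v in ours.values()} == {round(v, 12) for v in oracle.values()}

    def test_region_network_pools_frois_of_one_region(self):
        # two fROIs named alike pool into one region node
        net = self._net_from_edges(
            {0: 2, 1: 2, 2: 2}, [(0, 4), (2, 4)], regions={0: "BA", 1: "BA", 2: "WA"}
        )
        G = region_network(net)
        assert set(G.nodes) == {"BA", "WA"}
        assert G.nodes["BA"]["size"] == 4
        assert G["BA"]["WA"]["W"] == pytest.approx(2 / 6)
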
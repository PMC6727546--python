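"""Thinning, path smoothing, and skeleton-to-graph conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myceliotrack.skeleton_graph import (
    Skeleton,
    build_graph,
    path_length,
    prune_skeleton,
    skeletonize,
    smooth_path,
    smooth_path_length,
    to_graphml,
)


def _staircase(n):
    """4-connected 45° staircase of n pixels."""
    pts, r, c = [], 0, 0
    for i in range(n):
        pts.append((r, c))
        if i % 2 == 0:
            c += 1
        else:
            r += 1
    return np.asarray(pts, dtype=float)


class TestSkeletonize:
    def test_bar_collapses_to_line(self):
        bar = np.zeros((20, 60), dtype=bool)
        bar[9:12, 5:55] = True
        sk = skeletonize(bar)
        counts = sk.neighbour_counts()
        assert counts[sk.pixels].max() <= 2  # a simple line
        cols = np.nonzero(sk.pixels)[1]
        assert cols.max() - cols.min() >= 45  # spans the long axis

    def test_disc_collapses_to_near_point(self):
        yy, xx = np.mgrid[0:30, 0:30]
        disc = np.hypot(yy - 15, xx - 15) <= 10
        sk = skeletonize(disc)
        assert 1 <= sk.pixels.sum() <= 5

    def test_no_2x2_blocks_on_mycelium_masks(self, small_run):
        """Thinning of filamentous masks yields single-pixel-wide skeletons
        (no 2x2 all-foreground block)."""
        _, _, _, result = small_run
        for sk_obj in result.skeletons:
            sk = sk_obj.pixels
            blocks = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
            assert not blocks.any()

    def test_component_count_preserved(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:8, 5:25] = True
        mask[30:33, 30:55] = True
        mask[50:55, 5:10] = True
        import scipy.ndimage as ndi
        eight = np.ones((3, 3), int)
        _, n_mask = ndi.label(mask, structure=eight)
        sk = skeletonize(mask)
        _, n_skel = ndi.label(sk.pixels, structure=eight)
        assert n_skel == n_mask == 3

    def test_empty_mask_empty_skeleton(self):
        sk = skeletonize(np.zeros((16, 16), dtype=bool))
        assert not sk.pixels.any()


class TestBuildGraph:
    def test_straight_line(self):
        sk = np.zeros((10, 20), dtype=bool)
        sk[5, 3:13] = True  # 10 pixels
        g = build_graph(Skeleton(sk), calibration=0.5)
        assert len(g.tips) == 2
        assert len(g.junctions) == 0
        assert g.graph.number_of_edges() == 1
        (_, _, d), = g.graph.edges(data=True)
        assert d["raw_length_um"] == pytest.approx(9 * 0.5)

    def test_plus_sign(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[19:22, 5:36] = True
        mask[5:36, 19:22] = True
        g = build_graph(skeletonize(mask), calibration=1.0)
        assert len(g.tips) == 4
        assert len(g.junctions) == 1
        assert g.graph.number_of_edges() == 4

    def test_y_shape_arm_lengths(self):
        sk = np.zeros((70, 70), dtype=bool)
        for i in range(21):
            sk[35, 35 - i] = True         # straight arm, 20 steps
            sk[35 - i, 35 + i] = True     # diagonal arm, 20 steps
        for i in range(31):
            sk[35 + i, 35 + i] = True     # diagonal arm, 30 steps
        g = build_graph(Skeleton(sk), calibration=1.0)
        assert len(g.tips) == 3
        assert len(g.junctions) == 1
        lengths = sorted(d["raw_length_um"] for _, _, d in g.graph.edges(data=True))
        assert lengths == pytest.approx([20.0, 20 * np.sqrt(2), 30 * np.sqrt(2)])

    def test_ring_with_tail_has_self_loop(self):
        yy, xx = np.mgrid[0:60, 0:60]
        r = np.hypot(yy - 25, xx - 25)
        mask = (r > 10) & (r < 14)
        mask[37:40, 25:50] = True
        g = build_graph(skeletonize(mask), calibration=1.0)
        kinds = sorted(g.graph.nodes[n]["kind"] for n in g.graph.nodes)
        assert kinds == ["junction", "tip"]
        assert g.graph.number_of_edges() == 2
        assert sum(1 for u, v in g.graph.edges() if u == v) == 1

    def test_pure_ring_anchor_node(self):
        yy, xx = np.mgrid[0:60, 0:60]
        mask = (np.hypot(yy - 25, xx - 25) > 10) & (np.hypot(yy - 25, xx - 25) < 14)
        g = build_graph(skeletonize(mask), calibration=1.0)
        assert g.graph.number_of_nodes() == 1
        assert g.graph.number_of_edges() == 1
        (u, v), = g.graph.edges()
        assert u == v

    def test_isolated_pixel(self):
        sk = np.zeros((8, 8), dtype=bool)
        sk[4, 4] = True
        g = build_graph(Skeleton(sk), calibration=1.0)
        assert [g.graph.nodes[n]["kind"] for n in g.graph.nodes] == ["isolated"]
        assert len(g.tips) == 0

    def test_pixel_conservation(self):
        """Edge interiors plus node pixels partition the skeleton exactly."""
        rng = np.random.default_rng(3)
        mask = np.zeros((120, 120), dtype=bool)
        # random filament doodle
        r, c = 60.0, 60.0
        theta = 0.0
        for _ in range(300):
            theta += rng.normal(0, 0.3)
            r += np.sin(theta)
            c += np.cos(theta)
            rr, cc = int(round(r)) % 120, int(round(c)) % 120
            mask[max(rr - 1, 0):rr + 2, max(cc - 1, 0):cc + 2] = True
        sk = skeletonize(mask)
        g = build_graph(sk, calibration=1.0)
        node_px = set()
        for n, d in g.graph.nodes(data=True):
            node_px.update(d["pixels"])
        edge_px = []
        for _, _, d in g.graph.edges(data=True):
            edge_px.extend(map(tuple, d["path"][1:-1]))
        all_px = set(zip(*np.nonzero(sk.pixels)))
        assert node_px | set(edge_px) == all_px
        assert len(edge_px) == len(set(edge_px))  # each interior pixel once
        assert not (set(edge_px) & node_px)

    def test_total_length_close_to_truth_on_synthetic(self, small_run):
        truth, _, _, result = small_run
        meas = result.position_timeseries["total_length_um"].to_numpy()
        true = truth.total_length_um
        sel = true > 10
        assert np.all(np.abs(meas[sel] - true[sel]) / true[sel] < 0.10)

    def test_graphml_round_trip(self):
        import io
        import networkx as nx
        mask = np.zeros((41, 41), dtype=bool)
        mask[19:22, 5:36] = True
        mask[5:36, 19:22] = True
        g = build_graph(skeletonize(mask), calibration=0.65)
        doc = to_graphml(g)
        h = nx.read_graphml(io.BytesIO(doc.encode()))
        assert h.number_of_nodes() == g.graph.number_of_nodes()
        assert h.number_of_edges() == g.graph.number_of_edges()


class TestSmoothing:
    def test_straight_path_unchanged(self):
        path = np.stack([np.zeros(15), np.arange(15.0)], axis=1)
        assert smooth_path_length(path, 1.0, 5) == pytest.approx(14.0)
        assert smooth_path_length(path, 1.0, 50) == pytest.approx(14.0)

    def test_two_point_path_euclidean(self):
        assert smooth_path_length(np.array([[0.0, 0.0], [3.0, 4.0]]), 1.0, 5) \
            == pytest.approx(5.0)

    def test_staircase_approaches_diagonal(self):
        path = _staircase(40)
        raw = path_length(path)
        assert raw == pytest.approx(39.0)
        smoothed = smooth_path_length(path, 1.0, 5)
        diag = np.linalg.norm(path[-1] - path[0])
        assert abs(smoothed - diag) / diag < 0.05

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(3, 40))
    def test_length_non_increasing_in_iterations(self, seed, n):
        rng = np.random.default_rng(seed)
        path = np.cumsum(rng.normal(0, 1, (n, 2)), axis=0)
        lengths = [path_length(smooth_path(path, k)) for k in range(6)]
        assert all(b <= a + 1e-9 for a, b in zip(lengths, lengths[1:]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 40))
    def test_bounded_by_raw_and_chord(self, seed, n):
        rng = np.random.default_rng(seed)
        path = np.cumsum(rng.normal(0, 1, (n, 2)), axis=0)
        raw = path_length(path)
        smoothed = smooth_path_length(path, 1.0, 5)
        chord = np.linalg.norm(path[-1] - path[0])
        assert smoothed <= raw + 1e-9
        assert smoothed >= chord - 1e-9


class TestPruning:
    def test_short_spur_removed_long_arms_kept(self):
        sk = np.zeros((40, 40), dtype=bool)
        sk[20, 5:35] = True   # main filament
        sk[18:20, 20] = True  # 2-px spur
        pruned = prune_skeleton(Skeleton(sk), calibration=1.0, min_spur_um=3.0)
        assert not pruned.pixels[18, 20] and not pruned.pixels[19, 20]
        assert pruned.pixels[20, 5:35].all()

    def test_isolated_segment_never_pruned(self):
        sk = np.zeros((10, 10), dtype=bool)
        sk[5, 3:6] = True  # 3-px isolated segment
        pruned = prune_skeleton(Skeleton(sk), calibration=1.0, min_spur_um=10.0)
        np.testing.assert_array_equal(pruned.pixels, sk)
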
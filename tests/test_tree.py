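import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasodose.boundary import BoxBoundary, SphereBoundary, VoxelMaskBoundary
from vasodose.tree import (
    CenterlineGraph,
    GrowthConfig,
    check_intersections,
    grow_tree,
    interpolate_curvature,
    match_endpoint_triplets,
    murray_split_radii,
    optimize_bifurcation,
    sample_candidate_points,
    segment_pair_distance,
)


class TestSampling:
    def test_unit_sphere_all_inside(self):
        pts = sample_candidate_points(SphereBoundary(radius=1.0), 1000, seed=7)
        assert len(pts) == 1000
        assert (np.linalg.norm(pts, axis=1) < 1.0).all()

    def test_deterministic(self):
        b = SphereBoundary(radius=1.0)
        a = sample_candidate_points(b, 100, seed=5)
        c = sample_candidate_points(b, 100, seed=5)
        np.testing.assert_array_equal(a, c)

    def test_single_voxel_mask(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 2, 0] = True
        b = VoxelMaskBoundary(mask, spacing=0.3)
        pts = sample_candidate_points(b, 200, seed=1)
        lo = np.array([1, 2, 0]) * 0.3
        assert ((pts >= lo) & (pts <= lo + 0.3)).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            VoxelMaskBoundary(np.zeros((2, 2, 2), bool))


class TestMurray:
    def test_even_split(self):
        r = murray_split_radii(1.0, [0.5, 0.5])
        assert r == pytest.approx([2 ** (-1 / 3)] * 2)
        assert r[0] == pytest.approx(0.79370, abs=1e-5)

    def test_uneven_split(self):
        r = murray_split_radii(1.0, [0.75, 0.25])
        assert r[0] == pytest.approx(0.90856, abs=1e-5)
        assert r[1] == pytest.approx(0.62996, abs=1e-5)
        assert (r**3).sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_child(self):
        assert murray_split_radii(2.5, [1.0])[0] == pytest.approx(2.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            murray_split_radii(-1.0, [0.5, 0.5])
        with pytest.raises(ValueError):
            murray_split_radii(1.0, [0.5, 0.6])
        with pytest.raises(ValueError):
            murray_split_radii(1.0, [1.5, -0.5])

    @given(
        st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=1, max_size=5),
        st.floats(min_value=1.0, max_value=4.0),
    )
    def test_power_conservation_property(self, flows, exponent):
        f = np.array(flows) / np.sum(flows)
        r = murray_split_radii(2.0, f, exponent=exponent)
        assert (r**exponent).sum() == pytest.approx(2.0**exponent, rel=1e-9)
        assert (r <= 2.0 + 1e-12).all()


class TestOptimizeBifurcation:
    def test_symmetric_junction_on_axis(self):
        x = optimize_bifurcation((0, 0, 1), [(-1, 0, -1), (1, 0, -1)], [1.0, 0.7937, 0.7937])
        assert abs(x[0]) < 1e-4
        assert abs(x[1]) < 1e-4

    def test_zero_radius_child_limit(self):
        x = optimize_bifurcation((0, 0, 0), [(0, 0, 2), (5, 5, 5)], [1.0, 1.0, 1e-6])
        # junction collapses onto the parent-child segment
        assert np.linalg.norm(np.cross(x - np.zeros(3), np.array([0, 0, 2.0]))) / 2.0 < 1e-3

    def test_beats_naive_grid_oracle(self, rng):
        anchors = rng.normal(size=(3, 3))
        radii = rng.uniform(0.3, 1.0, size=3)
        w = np.pi * radii**2
        x = optimize_bifurcation(anchors[0], [anchors[1], anchors[2]], radii)

        def cost(p):
            return (w * np.linalg.norm(anchors - p, axis=1)).sum()

        # coarse grid oracle over the anchor bounding box
        lo, hi = anchors.min(axis=0), anchors.max(axis=0)
        grid = np.stack(
            np.meshgrid(*[np.linspace(lo[i], hi[i], 12) for i in range(3)], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        best_grid = min(cost(p) for p in grid)
        assert cost(x) <= best_grid + 1e-9
        assert cost(x) <= cost(anchors[0]) + 1e-12

    def test_degenerate_collinear_fallback(self):
        x = optimize_bifurcation((0, 0, 0), [(0, 0, 0), (0, 0, 0)], [1.0, 1.0, 1.0])
        np.testing.assert_allclose(x, np.zeros(3), atol=1e-12)


class TestCurvature:
    def test_two_points_straight(self):
        out = interpolate_curvature([(0, 0, 0), (1, 1, 1)], degree=3, samples=10)
        t = np.linspace(0, 1, 10)[:, None]
        np.testing.assert_allclose(out, t * np.ones(3), atol=1e-9)

    def test_collinear_stays_collinear(self):
        out = interpolate_curvature([(0, 0, 0), (1, 0, 0), (3, 0, 0)], degree=2, samples=20)
        assert np.abs(out[:, 1:]).max() < 1e-9

    def test_quadratic_through_knots(self):
        pts = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0]], float)
        out = interpolate_curvature(pts, degree=2, samples=101)
        for p in pts:
            assert np.linalg.norm(out - p, axis=1).min() < 1e-6

    def test_endpoints_exact(self):
        pts = np.array([[0, 0, 0], [0.3, 1, 0.2], [1.5, 0.1, -1], [2, 0, 0]], float)
        out = interpolate_curvature(pts, degree=2, samples=50)
        np.testing.assert_allclose(out[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(out[-1], pts[-1], atol=1e-12)

    def test_boundary_projection(self):
        b = SphereBoundary(radius=1.05)
        pts = np.array([[-1, 0, 0], [0, 1.0, 0], [1, 0, 0]], float)
        out = interpolate_curvature(pts, degree=2, samples=50, boundary=b)
        assert b.contains(out[1:-1]).all()


class TestIntersections:
    def _two_segment_graph(self, a0, a1, b0, b1, r=0.1):
        g = CenterlineGraph()
        n = [g.add_node(p) for p in (a0, a1, b0, b1)]
        g.add_edge(n[0], n[1], r)
        g.add_edge(n[2], n[3], r)
        return g

    def test_separated_parallel_empty(self):
        g = self._two_segment_graph((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0))
        assert check_intersections(g, 0.0) == []

    def test_crossing_reported(self):
        g = self._two_segment_graph((0, 0, 0), (1, 0, 0), (0.5, -0.5, 0), (0.5, 0.5, 0))
        assert len(check_intersections(g, 0.0)) == 1

    def test_adjacent_edges_excluded(self):
        g = CenterlineGraph()
        a, b, c = g.add_node((0, 0, 0)), g.add_node((1, 0, 0)), g.add_node((1.01, 1, 0))
        g.add_edge(a, b, 0.3)
        g.add_edge(b, c, 0.3)
        assert check_intersections(g, 0.0) == []

    def test_random_set_matches_brute_force(self, rng):
        g = CenterlineGraph()
        for _ in range(30):
            a = g.add_node(rng.uniform(0, 5, 3))
            b = g.add_node(rng.uniform(0, 5, 3))
            g.add_edge(a, b, rng.uniform(0.05, 0.4))
        fast = set(check_intersections(g, clearance=0.1))
        brute = set(check_intersections(g, clearance=0.1, brute=True))
        assert fast == brute

    def test_segment_distance_values(self):
        assert segment_pair_distance((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(1.0)
        assert segment_pair_distance((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)) == pytest.approx(1.0)
        assert segment_pair_distance((0, 0, 0), (2, 0, 0), (1, -1, 1), (1, 1, 1)) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def grown():
    cfg = GrowthConfig(
        boundary=SphereBoundary(radius=1.0),
        n_terminals=30,
        root_position=(0, 0, 1.0),
        root_radius=0.12,
        min_radius=0.01,
        seed=11,
    )
    return cfg, grow_tree(cfg)


class TestGrowth:
    def test_single_terminal(self):
        cfg = GrowthConfig(
            boundary=SphereBoundary(radius=1.0),
            n_terminals=1,
            root_position=(0, 0, 1.0),
            root_radius=0.2,
            min_radius=0.05,
            seed=4,
        )
        g = grow_tree(cfg)
        assert len(g.edges) == 1
        (e,) = g.edges.values()
        assert e.radius == pytest.approx(0.2)

    def test_nodes_inside_boundary(self, grown):
        cfg, g = grown
        g.validate(boundary=cfg.boundary)

    def test_murray_residual_below_1e9(self, grown):
        cfg, g = grown
        res = g.murray_residuals()
        assert res  # bifurcations exist
        for node, r in res.items():
            assert r < 1e-9 * cfg.root_radius**3

    def test_radii_non_increasing_root_to_leaf(self, grown):
        _, g = grown
        by_head = {e.head: e for e in g.edges.values()}
        for e in g.edges.values():
            if e.tail in by_head:
                assert e.radius <= by_head[e.tail].radius + 1e-12

    def test_no_intersections_at_zero_clearance(self, grown):
        _, g = grown
        assert check_intersections(g, 0.0) == []

    def test_deterministic(self, grown):
        cfg, g = grown
        g2 = grow_tree(cfg)
        assert len(g.edges) == len(g2.edges)
        for nid in g.nodes:
            np.testing.assert_allclose(g.nodes[nid].position, g2.nodes[nid].position)

    def test_segment_count_near_2T_minus_1(self, grown):
        _, g = grown
        assert len(g.edges) == 2 * 30 - 1

    def test_min_radius_config_guard(self):
        with pytest.raises(ValueError, match="min_radius"):
            GrowthConfig(
                boundary=SphereBoundary(radius=1.0),
                n_terminals=1000,
                root_position=(0, 0, 1.0),
                root_radius=0.1,
                min_radius=0.1,
            )

    def test_json_round_trip(self, grown, tmp_path):
        _, g = grown
        path = tmp_path / "tree.json"
        g.save(path)
        g2 = CenterlineGraph.load(path)
        assert g2.roots == g.roots
        assert len(g2.edges) == len(g.edges)
        for eid, e in g.edges.items():
            assert g2.edges[eid].radius == pytest.approx(e.radius)


class TestTripletMatching:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(6, 3))
        triplets = match_endpoint_triplets(pts, pts, pts)
        assert triplets == [(i, i, i) for i in range(6)]

    def test_single_point(self):
        p = np.array([[1.0, 2.0, 3.0]])
        assert match_endpoint_triplets(p, p + 1, p - 1) == [(0, 0, 0)]

    def test_matches_exhaustive_minimum(self, rng):
        A, V, P = rng.normal(size=(3, 3, 3))
        triplets = match_endpoint_triplets(A, V, P)
        got_av = sum(np.linalg.norm(A[a] - V[v]) for a, v, _ in triplets)
        got_pv = sum(np.linalg.norm(P[p] - V[v]) for _, v, p in triplets)
        best_av = min(
            sum(np.linalg.norm(A[perm[v]] - V[v]) for v in range(3))
            for perm in itertools.permutations(range(3))
        )
        best_pv = min(
            sum(np.linalg.norm(P[perm[v]] - V[v]) for v in range(3))
            for perm in itertools.permutations(range(3))
        )
        assert got_av == pytest.approx(best_av, rel=1e-12)
        assert got_pv == pytest.approx(best_pv, rel=1e-12)

    def test_each_endpoint_used_once(self, rng):
        A, V, P = rng.normal(size=(3, 8, 3))
        triplets = match_endpoint_triplets(A, V, P)
        assert sorted(t[0] for t in triplets) == list(range(8))
        assert sorted(t[1] for t in triplets) == list(range(8))
        assert sorted(t[2] for t in triplets) == list(range(8))

    def test_unequal_sizes_error(self, rng):
        with pytest.raises(ValueError):
            match_endpoint_triplets(rng.normal(size=(3, 3)), rng.normal(size=(4, 3)), rng.normal(size=(3, 3)))


class TestEndpointProportionality:
    def test_terminal_counts_proportional_to_subregion_volumes(self):
        # grow two trees whose terminal budgets follow configured volumes 2:1
        big = BoxBoundary((0, 0, 0), (2, 1, 1))
        small = BoxBoundary((2, 0, 0), (3, 1, 1))
        volumes = {"big": 2.0, "small": 1.0}
        total_terminals = 12
        share = {
            k: round(total_terminals * v / sum(volumes.values())) for k, v in volumes.items()
        }
        counts = {}
        for name, boundary, root in (("big", big, (0, 0.5, 0.5)), ("small", small, (3, 0.5, 0.5))):
            cfg = GrowthConfig(
                boundary=boundary,
                n_terminals=share[name],
                root_position=root,
                root_radius=0.05,
                min_radius=0.005,
                seed=2,
                tree_label=name,
            )
            counts[name] = len(grow_tree(cfg).terminals(name))
        assert abs(counts["big"] - 8) <= 1
        assert abs(counts["small"] - 4) <= 1
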
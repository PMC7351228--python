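"""Statistical geometry: g(r), nematic order, Delaunay, MST, containment.

Oracles (exhaustive empty-circumsphere Delaunay, complete-graph MST) live
in ``oracles.py`` and are independent of the scipy-based implementations.
"""

import numpy as np
import pytest

import sinunet as sn
from sinunet.geometry import edge_alignment_terms
from oracles import brute_force_delaunay, brute_force_mst_length


# ---------------------------------------------------------------------------
# g(r)
# ---------------------------------------------------------------------------

class TestRadialDistribution:
    def test_poisson_points_give_unit_g(self, rng):
        box = sn.Cuboid([0, 0, 0], [120.0, 120.0, 120.0])
        pts = rng.uniform(0, 120, (4000, 3))
        rdf = sn.radial_distribution(pts, box, r_max=25.0, dr=2.5)
        # ideal-gas reference: g = 1 at every radius, up to sampling noise
        assert np.all(np.abs(rdf.g[1:] - 1.0) < 0.12)

    def test_hard_sphere_exclusion_zone(self, packed_small):
        rdf = packed_small.rdf(dr=0.5)
        r0 = packed_small.config.radius
        assert np.all(rdf.g[rdf.r < 2 * r0 - 0.5] == 0)
        assert rdf.g[(rdf.r > 2 * r0) & (rdf.r < 3 * r0)].max() > 1.1

    def test_r_max_exceeding_box_rejected(self, rng):
        box = sn.Cuboid([0, 0, 0], [50.0, 50, 50])
        pts = rng.uniform(0, 50, (100, 3))
        with pytest.raises(ValueError):
            sn.radial_distribution(pts, box, r_max=30.0)


class TestSummaryStats:
    def test_triangle_all_degree_two(self, triangle_net):
        st = sn.summary_stats(triangle_net)
        assert st.mean_degree == pytest.approx(2.0)
        assert st.degree_values.tolist() == [2]
        assert st.degree_cdf[-1] == pytest.approx(1.0)

    def test_cdf_nondecreasing_and_normalized(self, random_net):
        st = sn.summary_stats(random_net)
        assert np.all(np.diff(st.degree_cdf) >= 0)
        assert st.degree_cdf[-1] == pytest.approx(1.0)
        assert st.mean_edge_length > 0


class TestNematicOrder:
    def test_parallel_and_perpendicular_limits(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.0, 10, 0],
                        [10.0, 10, 0]])
        par = sn.SpatialNetwork(pos, [[0, 1], [2, 3]])
        perp = sn.SpatialNetwork(pos, [[0, 2], [1, 3]])
        assert sn.nematic_order(par, (1, 0, 0)) == pytest.approx(1.0)
        assert sn.nematic_order(perp, (1, 0, 0)) == pytest.approx(-0.5)

    def test_isotropic_edges_give_zero(self, rng):
        # Monte-Carlo closed form: <cos^2 theta> = 1/3 for uniform axes
        n = 20000
        v = rng.normal(size=(n, 3))
        pos = np.vstack([np.zeros((n, 3)), v])
        edges = np.column_stack([np.arange(n), np.arange(n) + n])
        s = edge_alignment_terms(pos, edges, (1, 0, 0)).mean()
        assert abs(s) < 0.02

    def test_invariant_under_reversal_and_translation(self, random_net):
        s1 = sn.nematic_order(random_net, (0, 0, 1))
        flipped = sn.SpatialNetwork(random_net.positions,
                                    random_net.edges[:, ::-1].copy(),
                                    random_net.weights)
        shifted = sn.SpatialNetwork(random_net.positions + 123.4,
                                    random_net.edges, random_net.weights)
        assert sn.nematic_order(flipped, (0, 0, 1)) == pytest.approx(s1)
        assert sn.nematic_order(shifted, (0, 0, 1)) == pytest.approx(s1)
        assert -0.5 - 1e-12 <= s1 <= 1.0 + 1e-12

    def test_no_interior_edges_is_an_error(self, triangle_net):
        box = sn.Cuboid([100, 100, 100], [101, 101, 101])
        with pytest.raises(ValueError, match="no edges"):
            sn.nematic_order(triangle_net, (1, 0, 0), box)


class TestDelaunay:
    def test_regular_tetrahedron_is_complete(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                        [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3)]])
        edges = sn.delaunay_graph(pts)
        assert len(edges) == 6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_circumsphere_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (20, 3))
        fast = {tuple(e) for e in sn.delaunay_graph(pts)}
        slow = {tuple(e) for e in brute_force_delaunay(pts)}
        assert fast == slow

    def test_mirroring_removes_boundary_artifacts(self, rng):
        pts = rng.uniform(0, 50, (200, 3))
        box = sn.Cuboid([0, 0, 0], [50.0, 50, 50])
        plain = sn.delaunay_graph(pts)
        mirrored = sn.delaunay_graph(pts, mirror_box=box)
        len_plain = np.linalg.norm(pts[plain[:, 0]] - pts[plain[:, 1]],
                                   axis=1).max()
        len_mirr = np.linalg.norm(pts[mirrored[:, 0]] - pts[mirrored[:, 1]],
                                  axis=1).max()
        assert len_mirr <= len_plain  # long hull-spanning edges culled

    def test_degenerate_coplanar_points_jittered_with_warning(self):
        pts = np.zeros((8, 3))
        pts[:, :2] = np.random.default_rng(0).uniform(0, 10, (8, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            edges = sn.delaunay_graph(pts)
        assert len(edges) > 0


class TestMST:
    def test_three_collinear_points(self):
        pts = np.array([[0.0, 0, 0], [5.0, 0, 0], [9.0, 0, 0]])
        edges = sn.euclidean_mst(pts)
        assert {tuple(e) for e in edges} == {(0, 1), (1, 2)}

    @pytest.mark.parametrize("n,seed", [(8, 0), (10, 1), (10, 2)])
    def test_total_length_matches_exhaustive_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (n, 3))
        edges = sn.euclidean_mst(pts)
        total = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]],
                               axis=1).sum()
        assert total == pytest.approx(brute_force_mst_length(pts), rel=1e-9)

    def test_mst_contained_in_delaunay(self, rng):
        pts = rng.uniform(0, 30, (60, 3))
        d = {tuple(e) for e in sn.delaunay_graph(pts)}
        m = {tuple(e) for e in sn.euclidean_mst(pts)}
        assert m <= d

    def test_not_longer_than_random_spanning_trees(self, rng):
        import networkx as nx
        pts = rng.uniform(0, 10, (15, 3))
        edges = sn.euclidean_mst(pts)
        best = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]],
                              axis=1).sum()
        g = nx.complete_graph(15)
        for _ in range(20):
            t = nx.random_spanning_tree(g, seed=int(rng.integers(1 << 30)))
            tot = sum(np.linalg.norm(pts[i] - pts[j]) for i, j in t.edges)
            assert best <= tot + 1e-9


class TestContainment:
    def test_identical_and_disjoint_sets(self):
        e1 = np.array([[0, 1], [1, 2]])
        e2 = np.array([[3, 4]])
        assert sn.containment_fraction(e1, e1) == 1.0
        assert sn.containment_fraction(e1, e2) == 0.0

    def test_direction_insensitive(self):
        assert sn.containment_fraction([[1, 0]], [[0, 1]]) == 1.0

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            sn.containment_fraction(np.empty((0, 2)), [[0, 1]])


class TestSubsampleInvariance:
    def test_gr_of_uniform_subsample_matches_full_set(self, packed_small,
                                                      rng):
        full = packed_small.rdf(dr=1.0)
        idx = rng.choice(len(packed_small.points),
                         len(packed_small.points) // 3, replace=False)
        sub = sn.radial_distribution(packed_small.points[idx],
                                     packed_small.box, r_max=full.r[-1] + 0.5,
                                     dr=1.0, periodic=True)
        mask = full.r > 2 * packed_small.config.radius
        assert np.mean(np.abs(sub.g[mask] - full.g[mask])) < 0.15
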
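"""Permeability-at-risk curves, pruning, disconnection fractions."""

import numpy as np
import pytest

import sinunet as sn
from sinunet.resilience import (SCENARIO_HIGH_CURRENT, SCENARIO_RANDOM_LENGTH,
                                disconnected_fraction, permeability_at_risk,
                                prune_low_current)


@pytest.fixture(scope="module")
def sublattice_setup():
    a = 14.3
    net = sn.random_sublattice(8, 0.7, a, seed=2)
    roi = sn.lattice_roi(8, a)
    return net, roi


class TestPermeabilityAtRisk:
    def test_curves_start_at_one_and_never_increase(self, sublattice_setup):
        net, roi = sublattice_setup
        gammas = np.arange(0.0, 0.45, 0.05)
        for scenario in (SCENARIO_HIGH_CURRENT, SCENARIO_RANDOM_LENGTH):
            curve = permeability_at_risk(net, roi, scenario, gammas, seed=5,
                                         n_replicates=3)
            assert curve.k_over_k0[0] == pytest.approx(1.0)
            assert np.all(np.diff(curve.k_over_k0) <= 1e-9)
            assert np.all(curve.k_over_k0 >= 0)

    def test_targeted_removal_at_least_as_damaging_as_random(self,
                                                             sublattice_setup):
        net, roi = sublattice_setup
        gammas = np.arange(0.0, 0.45, 0.05)
        hi = permeability_at_risk(net, roi, SCENARIO_HIGH_CURRENT, gammas)
        rnd = permeability_at_risk(net, roi, SCENARIO_RANDOM_LENGTH, gammas,
                                   seed=6, n_replicates=5)
        assert np.all(hi.k_over_k0 <= rnd.k_over_k0 + 0.02)

    def test_single_path_percolates_at_first_removal(self):
        pos = [[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0], [30.0, 0, 0]]
        net = sn.SpatialNetwork(pos, [[0, 1], [1, 2], [2, 3]])
        roi = sn.Cuboid([0, -1, -1], [30.0, 1, 1])
        curve = permeability_at_risk(net, roi, SCENARIO_HIGH_CURRENT,
                                     [0.0, 1 / 3, 2 / 3])
        assert curve.k_over_k0[0] == 1.0
        assert np.all(curve.k_over_k0[1:] == 0.0)
        assert curve.gamma_star == pytest.approx(1 / 3)

    def test_random_scenario_reproducible_given_seed(self, sublattice_setup):
        net, roi = sublattice_setup
        gammas = [0.0, 0.1, 0.2]
        a = permeability_at_risk(net, roi, SCENARIO_RANDOM_LENGTH, gammas,
                                 seed=11, n_replicates=3)
        b = permeability_at_risk(net, roi, SCENARIO_RANDOM_LENGTH, gammas,
                                 seed=11, n_replicates=3)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_unknown_scenario_rejected(self, sublattice_setup):
        net, roi = sublattice_setup
        with pytest.raises(ValueError, match="scenario"):
            permeability_at_risk(net, roi, "meteor", [0.0, 0.1])

    def test_adaptive_ranking_variant_runs(self, sublattice_setup):
        net, roi = sublattice_setup
        curve = permeability_at_risk(net, roi, SCENARIO_HIGH_CURRENT,
                                     [0.0, 0.1, 0.2], recompute_ranking=True)
        assert curve.k_over_k0[0] == pytest.approx(1.0)
        assert np.all(np.diff(curve.k_over_k0) <= 1e-9)


class TestPruneLowCurrent:
    def test_equal_currents_remove_nothing(self):
        # a single series path: every edge carries the same current, the
        # strict-inequality rule removes none
        pos = [[x, 0.0, 0.0] for x in np.linspace(0, 100, 6)]
        net = sn.SpatialNetwork(pos, [[i, i + 1] for i in range(5)])
        roi = sn.Cuboid([0, -1, -1], [100.0, 1, 1])
        pruned, drop = prune_low_current(net, roi, percentile=25.0)
        assert pruned.n_edges == net.n_edges
        assert drop == pytest.approx(0.0)

    def test_pruning_reduces_permeability_moderately(self, sublattice_setup):
        net, roi = sublattice_setup
        pruned, drop = prune_low_current(net, roi, percentile=25.0)
        assert pruned.n_edges < net.n_edges
        assert 0.0 <= drop < 0.5

    def test_invalid_percentile_rejected(self, sublattice_setup):
        net, roi = sublattice_setup
        with pytest.raises(ValueError):
            prune_low_current(net, roi, percentile=0.0)
        with pytest.raises(ValueError):
            prune_low_current(net, roi, percentile=100.0)


class TestDisconnectedFraction:
    def test_no_removal_on_connected_network(self):
        net = sn.cubic_lattice(3, 10.0)
        f = disconnected_fraction(net, np.empty(0, int), [0], [26])
        assert f == 0.0

    def test_all_edges_removed(self):
        net = sn.cubic_lattice(3, 10.0)
        f = disconnected_fraction(net, np.arange(net.n_edges), [0], [26])
        assert f == 1.0

    def test_hand_enumerated_cut(self):
        # path 0-1-2-3-4 with source 0, sink 4; cutting edge (1,2)
        # strands nodes 1 (can reach source only) and leaves 2, 3 able to
        # reach the sink only -> all 3 interior nodes are disconnected
        # from source or sink
        pos = [[float(i), 0, 0] for i in range(5)]
        net = sn.SpatialNetwork(pos, [[i, i + 1] for i in range(4)],
                                np.ones(4))
        f = disconnected_fraction(net, np.array([1]), [0], [4])
        assert f == pytest.approx(1.0)
        # cutting (3,4) instead: interior nodes 1,2,3 all keep the source
        # but lose the sink
        f2 = disconnected_fraction(net, np.array([3]), [0], [4])
        assert f2 == pytest.approx(1.0)
        # no cut: everyone connected
        assert disconnected_fraction(net, np.empty(0, int), [0], [4]) == 0.0

    def test_partial_cut_fraction(self):
        # two parallel 3-hop paths between source 0 and sink 3; cutting
        # both anchor edges of the upper path strands its two interior
        # nodes -> 2 of 4 interior nodes disconnected; a single cut
        # disconnects nothing because the two paths form a cycle
        pos = [[0.0, 0, 0], [10.0, 1, 0], [20.0, 1, 0], [30.0, 0, 0],
               [10.0, -1, 0], [20.0, -1, 0]]
        edges = [[0, 1], [1, 2], [2, 3], [0, 4], [4, 5], [5, 3]]
        net = sn.SpatialNetwork(pos, edges)
        assert disconnected_fraction(net, np.array([1]), [0], [3]) == 0.0
        f = disconnected_fraction(net, np.array([0, 2]), [0], [3])
        assert f == pytest.approx(2 / 4)

    def test_fraction_reaches_one_at_percolation(self, sublattice_setup):
        net, roi = sublattice_setup
        gammas = np.arange(0.0, 0.9, 0.1)
        curve = permeability_at_risk(net, roi, SCENARIO_HIGH_CURRENT, gammas)
        if np.isfinite(curve.gamma_star):
            from sinunet.flow import boundary_nodes
            lo, hi = boundary_nodes(net, roi, 0, 1e-6)
            order = np.lexsort((np.arange(net.n_edges),))
            # remove everything up to the percolation threshold
            n_remove = int(round(curve.gamma_star * net.n_edges))
            _, _, sol = sn.axis_permeability(net, roi, 0)
            rank = np.lexsort((np.arange(net.n_edges),
                               -np.abs(sol.edge_currents)))
            f = disconnected_fraction(net, rank[:n_remove], lo, hi)
            assert f > 0.5
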
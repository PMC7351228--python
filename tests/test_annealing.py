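"""Edge-selection annealing: costs, initialization, invariants, Pareto."""

import numpy as np
import pytest

import sinunet as sn
from sinunet.annealing import (AnnealSchedule, Normalization,
                               distribution_costs, pareto_front)
from sinunet.targets import DistributionTarget


class TestDistributionCosts:
    def test_identical_distributions_cost_zero(self):
        target = DistributionTarget([2], [1.0], [5.0, 7.0])
        # square: 4 nodes all degree 2, lengths exactly the target samples
        edges = np.array([[0, 1], [1, 2], [2, 3], [0, 3]])
        cd, ce = distribution_costs(edges, 4, [5.0, 7.0, 5.0, 7.0], target)
        assert cd == pytest.approx(0.0)
        assert ce == pytest.approx(0.0)

    def test_hand_evaluated_degree_cost(self):
        # target all degree 3, simulated square has all degree 2:
        # CDFs differ only at d = 2 where |0 - 1|^2 = 1 -> C_d = 1
        target = DistributionTarget([3], [1.0], [1.0])
        edges = np.array([[0, 1], [1, 2], [2, 3], [0, 3]])
        cd, _ = distribution_costs(edges, 4, [1.0] * 4, target)
        assert cd == pytest.approx(1.0)

    def test_hand_evaluated_length_cost(self):
        # target lengths {1, 3}, simulated {2}, R_c = 1:
        # |F_t - F_s|^2 is 1/4 on [1,2) and 1/4 on [2,3) -> integral 1/2
        target = DistributionTarget([2], [1.0], [1.0, 3.0])
        edges = np.array([[0, 1]])
        _, ce = distribution_costs(edges, 2, [2.0], target, r_c=1.0)
        assert ce == pytest.approx(0.5)

    def test_length_cost_invariant_under_common_shift(self, rng):
        t_lengths = rng.gamma(4.0, 4.0, 200) + 1
        s_lengths = rng.gamma(5.0, 3.5, 150) + 1
        edges = np.column_stack([np.arange(150), np.arange(150) + 150])
        t1 = DistributionTarget([2], [1.0], t_lengths)
        t2 = DistributionTarget([2], [1.0], t_lengths + 10.0)
        _, ce1 = distribution_costs(edges, 300, s_lengths, t1)
        _, ce2 = distribution_costs(edges, 300, s_lengths + 10.0, t2)
        assert ce1 == pytest.approx(ce2, rel=1e-9)

    def test_empty_edge_set_rejected(self):
        target = DistributionTarget([2], [1.0], [1.0])
        with pytest.raises(ValueError):
            distribution_costs(np.empty((0, 2)), 3, [], target)


class TestInitialSelection:
    def test_zero_budget_gives_exactly_the_mst(self, sim_chain, rng):
        ann = sim_chain["annealer"]
        sel = ann.initial_selection(0, rng)
        assert sel.sum() == ann.n_nodes - 1
        assert np.array_equal(np.flatnonzero(sel), np.flatnonzero(ann.is_mst))

    def test_budget_counting_and_connectivity(self, sim_chain, rng):
        ann = sim_chain["annealer"]
        sel = ann.initial_selection(200, rng)
        assert sel.sum() == (ann.n_nodes - 1) + 200
        net = sn.SpatialNetwork(ann.positions, ann.cand[sel])
        assert net.connected_components()[0] == 1

    def test_budget_beyond_candidates_rejected(self, sim_chain, rng):
        ann = sim_chain["annealer"]
        with pytest.raises(ValueError, match="budget"):
            ann.initial_selection(len(ann.cand), rng)


class TestAnnealing:
    def test_reduces_cost_below_initial_and_returns_minimum_seen(self,
                                                                 annealed):
        ann = annealed["annealer"]
        res = annealed["result"]
        rng = np.random.default_rng(5)
        init = ann.initial_selection(None, rng)
        c0 = ann.costs(init, Normalization(), 0.5, 0.0)
        assert res.best.objective < c0.objective
        # elitist bookkeeping: the returned network is the best-seen one,
        # so no recorded trace point can lie below its cost
        assert res.best.objective <= res.trace.min() + 1e-12
        assert res.best.objective <= res.final.objective + 1e-12

    def test_edge_count_conserved_and_mst_contained(self, annealed):
        ann = annealed["annealer"]
        res = annealed["result"]
        rng = np.random.default_rng(5)
        assert res.selected.sum() == ann.initial_selection(None, rng).sum()
        assert np.all(res.selected[ann.is_mst])
        mst = {tuple(e) for e in ann.cand[ann.is_mst]}
        sel = {tuple(e) for e in res.edges}
        assert mst <= sel

    def test_incremental_costs_agree_with_from_scratch_oracle(self, annealed):
        """The annealer's bookkeeping must equal full recomputation."""
        ann = annealed["annealer"]
        res = annealed["result"]
        deg, hist, cum, s_sum = ann._state_from_selection(res.selected)
        m = res.selected.sum()
        cdf_sim = np.cumsum(hist) / ann.n_nodes
        cd_inc = float(np.sum((ann.cdf_t_deg - cdf_sim) ** 2))
        ce_inc = float(np.sum((ann.f_t - cum / m) ** 2 * ann.delta) / ann.r_c)
        oracle = ann.costs(res.selected, Normalization(), 0.5, 0.0)
        assert cd_inc == pytest.approx(oracle.c_d, rel=1e-9, abs=1e-12)
        assert ce_inc == pytest.approx(oracle.c_e, rel=1e-9, abs=1e-12)
        assert s_sum / m == pytest.approx(oracle.s_sim, rel=1e-9)

    def test_repeat_runs_reach_similar_minima(self, sim_chain):
        ann = sim_chain["annealer"]
        objs = [ann.anneal(schedule=AnnealSchedule.smoke(), seed=s).best.objective
                for s in (101, 202)]
        assert abs(objs[0] - objs[1]) < 0.25 * max(abs(o) for o in objs) + 5e-3

    def test_nematic_order_increases_with_field_strength(self, sim_chain):
        ann = sim_chain["annealer"]
        norm = Normalization(u_d=0.0, u_e=0.0, n_d=0.15, n_e=0.03)
        s_values = [ann.anneal(lam=lam, schedule=AnnealSchedule.smoke(),
                               norm=norm, seed=31).best.s_sim
                    for lam in (0.0, 0.5, 2.0)]
        assert s_values[0] < s_values[1] < s_values[2]

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t0=-1.0)
        with pytest.raises(ValueError):
            AnnealSchedule(cooling_factor=1.5)


class TestPareto:
    def test_normalized_costs_within_unit_box(self, front):
        # endpoints are exact by construction; interior points may stray
        # slightly outside through finite-schedule stochasticity
        assert np.all(front.c_d_norm >= -0.06)
        assert np.all(front.c_d_norm <= 1.06)
        assert np.all(front.c_e_norm >= -0.06)
        assert np.all(front.c_e_norm <= 1.06)
        assert front.c_d_norm[-1] == pytest.approx(0.0, abs=1e-12)
        assert front.c_e_norm[0] == pytest.approx(0.0, abs=1e-12)

    def test_alpha_bar_half_maps_to_alpha_star(self, front):
        assert front.norm.alpha_from_alpha_bar(0.5) == \
            pytest.approx(front.alpha_star, rel=1e-12)

    def test_objectives_trade_off_along_the_front(self, front):
        # degree cost falls, length cost rises as alpha_bar grows
        assert front.c_d[0] > front.c_d[-1]
        assert front.c_e[-1] > front.c_e[0]

    def test_single_point_grid_rejected(self, sim_chain):
        with pytest.raises(ValueError):
            pareto_front(sim_chain["annealer"], [0.5])
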
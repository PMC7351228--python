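"""Simulated-annealing edge selection: stage 2 of the network generator.

Given node positions P_sim, select an edge set E_sim with

    M(P_sim)  ⊆  E_sim  ⊆  D(P_sim)

(the Euclidean minimum spanning tree always kept, candidates restricted to
the Delaunay graph) minimizing a multi-objective cost built from the node
degree and edge-length distributions of a target network:

    C_d = sum_d |CDF(d) - CDF_sim(d)|^2
    C_e = (1/R_c) ∫ dl |CDF(l) - CDF_sim(l)|^2
    C_alpha = alpha C_d + (1 - alpha) C_e

An optional nematic alignment field of strength lambda rewards edges
parallel to a reference axis, subtracting lambda * S_sim from the
normalized cost; sweeping lambda tunes the nematic order parameter of the
generated network up to its saturation value.

Annealing uses Metropolis edge swaps (one selected non-tree edge out, one
unselected Delaunay edge in) so that the edge count is conserved and
connectivity is guaranteed at every step.  Costs are evaluated in
normalized form C̄ = (C - U)/(N - U) with utopia/nadir points U, N
estimated from single-objective endpoint runs, and the Pareto front over
the weight ᾱ is explored run by run.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .geometry import delaunay_graph, edge_alignment_terms, euclidean_mst
from .network import Cuboid
from .targets import DistributionTarget

_MAX_DEGREE = 64  # histogram capacity; Delaunay degrees stay far below this


# ---------------------------------------------------------------------------
# exact distribution costs (reference implementation / oracle)
# ---------------------------------------------------------------------------

def distribution_costs(edges: np.ndarray, n_nodes: int, lengths: np.ndarray,
                       target: DistributionTarget, r_c: float = 8.0
                       ) -> tuple[float, float]:
    """Exact (C_d, C_e) of an edge set against a target.

    C_d sums squared CDF differences over integer degrees; C_e integrates
    the squared difference of the two piecewise-constant empirical length
    CDFs exactly (no binning) and divides by the cut-off length R_c.
    """
    edges = np.asarray(edges)
    if len(edges) == 0:
        raise ValueError("empty edge set")
    deg = np.zeros(n_nodes, dtype=np.int64)
    np.add.at(deg, edges.ravel(), 1)
    dmax = int(max(deg.max(), target.degree_values.max()))
    hist = np.bincount(deg, minlength=dmax + 1)
    cdf_sim = np.cumsum(hist) / n_nodes
    cdf_t = target.degree_cdf_table(dmax)
    c_d = float(np.sum((cdf_t - cdf_sim) ** 2))

    ls = np.sort(np.asarray(lengths, dtype=float))
    grid = np.unique(np.concatenate([ls, target.length_samples]))
    f_t = target.length_cdf(grid)
    f_s = np.searchsorted(ls, grid, side="right") / len(ls)
    delta = np.diff(grid)
    c_e = float(np.sum((f_t[:-1] - f_s[:-1]) ** 2 * delta) / r_c)
    return c_d, c_e


# ---------------------------------------------------------------------------
# schedules and normalization
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule.

    Temperature starts at ``t0``, stays constant for ``melt_steps``
    attempted moves, then shrinks by ``cooling_factor`` after every
    ``steps_per_cool`` moves until it falls below ``t_final``.
    """

    t0: float = 1.0
    melt_steps: int = 10_000
    cooling_factor: float = 0.998
    steps_per_cool: int = 1000
    t_final: float = 1e-10

    def __post_init__(self):
        if self.t0 <= 0 or self.t_final <= 0:
            raise ValueError("temperatures must be positive")
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must be in (0, 1)")

    @property
    def n_cooling_stages(self) -> int:
        return int(math.ceil(math.log(self.t_final / self.t0)
                             / math.log(self.cooling_factor)))

    @property
    def total_steps(self) -> int:
        return self.melt_steps + self.steps_per_cool * self.n_cooling_stages

    @classmethod
    def production(cls) -> "AnnealSchedule":
        """The reference schedule (about 1.2e7 attempted moves)."""
        return cls()

    @classmethod
    def fast(cls) -> "AnnealSchedule":
        """100x shortened schedule for tests and desk-scale runs."""
        return cls(melt_steps=100, steps_per_cool=10)

    @classmethod
    def smoke(cls) -> "AnnealSchedule":
        """Very short schedule for smoke tests (coarse cooling)."""
        return cls(melt_steps=200, cooling_factor=0.98, steps_per_cool=10,
                   t_final=1e-6)


@dataclasses.dataclass(frozen=True)
class Normalization:
    """Utopia/nadir points of the two objectives."""

    u_d: float = 0.0
    u_e: float = 0.0
    n_d: float = 1.0
    n_e: float = 1.0

    @property
    def alpha_star(self) -> float:
        """Weight giving both normalized objectives equal influence."""
        return (self.n_e - self.u_e) / (self.n_d - self.u_d
                                        + self.n_e - self.u_e)

    @property
    def nu(self) -> float:
        """Scale of the normalized cost in raw-cost units."""
        a = self.alpha_star
        return a * (self.n_d - self.u_d) + (1 - a) * (self.n_e - self.u_e)

    def alpha_from_alpha_bar(self, alpha_bar: float) -> float:
        """Map the normalized weight ᾱ to the raw-cost weight α."""
        de, dd = self.n_e - self.u_e, self.n_d - self.u_d
        return de * alpha_bar / ((1 - alpha_bar) * dd + alpha_bar * de)

    def normalize(self, c_d: float, c_e: float) -> tuple[float, float]:
        return ((c_d - self.u_d) / (self.n_d - self.u_d),
                (c_e - self.u_e) / (self.n_e - self.u_e))


@dataclasses.dataclass
class CostBreakdown:
    c_d: float
    c_e: float
    c_alpha: float          # ᾱ-weighted normalized cost
    s_sim: float
    objective: float        # c_alpha - lambda * s_sim


@dataclasses.dataclass
class AnnealResult:
    selected: np.ndarray        # boolean mask over the candidate edge list
    edges: np.ndarray           # (M, 2) selected edges
    best: CostBreakdown         # cost of the returned (best-seen) edge set
    final: CostBreakdown        # cost of the end-of-schedule edge set
    trace: np.ndarray           # objective recorded along the run
    n_accepted: int
    n_steps: int


# ---------------------------------------------------------------------------
# the annealer
# ---------------------------------------------------------------------------

class EdgeAnnealer:
    """Shared state for annealing runs on one set of node positions.

    Precomputes the Delaunay candidate edges (with boundary mirroring when
    a box is given), the Euclidean MST, per-edge lengths and alignment
    terms, and the merged length grid on which the edge-length cost is
    evaluated exactly.
    """

    def __init__(self, positions: np.ndarray, target: DistributionTarget,
                 box: Cuboid | None = None, axis=(1.0, 0.0, 0.0),
                 r_c: float = 8.0):
        self.positions = np.asarray(positions, dtype=float)
        self.target = target
        self.r_c = float(r_c)
        self.n_nodes = len(self.positions)

        full_d = delaunay_graph(self.positions)
        mst = euclidean_mst(self.positions, full_d)
        cand = delaunay_graph(self.positions, mirror_box=box) \
            if box is not None else full_d
        # the MST must stay available even if mirroring discarded an edge
        cand = np.unique(np.vstack([cand, mst]), axis=0)
        self.cand = cand
        self.lengths = np.linalg.norm(
            self.positions[cand[:, 0]] - self.positions[cand[:, 1]], axis=1)
        self.align = edge_alignment_terms(self.positions, cand, axis)

        mst_set = {tuple(e) for e in mst}
        self.is_mst = np.array([tuple(e) in mst_set for e in cand])
        self.mst_count = int(self.is_mst.sum())

        # exact piecewise-constant length-CDF machinery
        self.grid = np.unique(np.concatenate([self.lengths,
                                              target.length_samples]))
        self.f_t = target.length_cdf(self.grid)
        self.delta = np.append(np.diff(self.grid), 0.0)
        # index of the grid point where each candidate edge's CDF step lands
        self.edge_pos = np.searchsorted(self.grid, self.lengths, side="left")
        self.cdf_t_deg = target.degree_cdf_table(_MAX_DEGREE - 1)

    # -- initialization ---------------------------------------------------

    def default_budget(self) -> int:
        """|E_rand| making the edge count match the target mean degree."""
        total = int(round(self.n_nodes * self.target.mean_degree / 2.0))
        return max(0, total - (self.n_nodes - 1))

    def budget_for_edge_density(self, density: float, volume: float) -> int:
        """|E_rand| matching a target edge count per volume (µm^-3, µm^3)."""
        total = int(round(density * volume))
        return max(0, total - (self.n_nodes - 1))

    def initial_selection(self, budget: int | None, rng) -> np.ndarray:
        """E_0 = MST plus ``budget`` uniformly chosen non-tree Delaunay edges."""
        if budget is None:
            budget = self.default_budget()
        free = np.flatnonzero(~self.is_mst)
        if budget > len(free):
            raise ValueError(
                f"budget {budget} exceeds |D \\ M| = {len(free)}")
        sel = self.is_mst.copy()
        if budget:
            sel[rng.choice(free, size=budget, replace=False)] = True
        return sel

    # -- cost evaluation --------------------------------------------------

    def _state_from_selection(self, sel: np.ndarray):
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.cand[sel].ravel(), 1)
        hist = np.bincount(deg, minlength=_MAX_DEGREE).astype(float)
        cum = np.zeros(len(self.grid))
        for p in self.edge_pos[sel]:
            cum[p:] += 1.0
        return deg, hist[:_MAX_DEGREE], cum, float(self.align[sel].sum())

    def costs(self, sel: np.ndarray, norm: Normalization,
              alpha_bar: float, lam: float) -> CostBreakdown:
        """Costs of a selection, recomputed from scratch (also the test
        oracle for the incremental bookkeeping)."""
        c_d, c_e = distribution_costs(self.cand[sel], self.n_nodes,
                                      self.lengths[sel], self.target, self.r_c)
        s = float(self.align[sel].mean())
        cbar_d, cbar_e = norm.normalize(c_d, c_e)
        c_a = alpha_bar * cbar_d + (1 - alpha_bar) * cbar_e
        return CostBreakdown(c_d, c_e, c_a, s, c_a - lam * s)

    # -- annealing --------------------------------------------------------

    def anneal(self, alpha_bar: float = 0.5, lam: float = 0.0,
               schedule: AnnealSchedule = AnnealSchedule.fast(),
               norm: Normalization = Normalization(),
               budget: int | None = None, seed=0,
               initial: np.ndarray | None = None,
               trace_every: int = 1000) -> AnnealResult:
        """Metropolis annealing of the edge selection.

        Moves swap a selected non-MST edge against an unselected candidate
        edge, accepted with probability exp(-dC/T) (1 when dC < 0), where C
        is the normalized multi-objective cost minus lam * S_sim.  The
        best-seen selection is returned (elitist bookkeeping); its cost
        equals the minimum cost encountered during the run by construction.
        """
        rng = np.random.default_rng(seed)
        sel = initial.copy() if initial is not None \
            else self.initial_selection(budget, rng)
        m_sel = int(sel.sum())
        n, grid_n = self.n_nodes, len(self.grid)

        deg, hist, cum, s_sum = self._state_from_selection(sel)

        # index bookkeeping for O(1) uniform sampling
        swappable = list(np.flatnonzero(sel & ~self.is_mst))
        unselected = list(np.flatnonzero(~sel))
        pos_in_pool = {}
        for k, e in enumerate(swappable):
            pos_in_pool[e] = ("sel", k)
        for k, e in enumerate(unselected):
            pos_in_pool[e] = ("uns", k)

        f_t, delta, cdf_t_deg = self.f_t, self.delta, self.cdf_t_deg

        def total_cost():
            cdf_sim = np.cumsum(hist) / n
            c_d = float(np.sum((cdf_t_deg - cdf_sim) ** 2))
            c_e = float(np.sum((f_t - cum / m_sel) ** 2 * delta) / self.r_c)
            cbar_d, cbar_e = norm.normalize(c_d, c_e)
            c_a = alpha_bar * cbar_d + (1 - alpha_bar) * cbar_e
            return c_a - lam * (s_sum / m_sel)

        def swap(e_out, e_in):
            nonlocal s_sum
            for node in self.cand[e_out]:
                hist[deg[node]] -= 1
                deg[node] -= 1
                hist[deg[node]] += 1
            for node in self.cand[e_in]:
                hist[deg[node]] -= 1
                deg[node] += 1
                hist[deg[node]] += 1
            cum[self.edge_pos[e_out]:] -= 1.0
            cum[self.edge_pos[e_in]:] += 1.0
            s_sum += self.align[e_in] - self.align[e_out]

        cur = total_cost()
        best = cur
        best_sel = sel.copy()
        trace = [cur]
        accepted = 0

        t = schedule.t0
        step = 0
        total_steps = schedule.total_steps
        while step < total_steps:
            step += 1
            if step > schedule.melt_steps and \
                    (step - schedule.melt_steps) % schedule.steps_per_cool == 0:
                t *= schedule.cooling_factor
                if t < schedule.t_final:
                    break
            if not swappable or not unselected:
                break
            k1 = rng.integers(len(swappable))
            k2 = rng.integers(len(unselected))
            e_out, e_in = swappable[k1], unselected[k2]
            swap(e_out, e_in)
            new = total_cost()
            d_c = new - cur
            if d_c < 0 or rng.random() < math.exp(-d_c / t):
                cur = new
                accepted += 1
                sel[e_out] = False
                sel[e_in] = True
                swappable[k1], unselected[k2] = e_in, e_out
                pos_in_pool[e_in] = ("sel", k1)
                pos_in_pool[e_out] = ("uns", k2)
                if cur < best:
                    best = cur
                    best_sel = sel.copy()
            else:
                swap(e_in, e_out)  # revert
            if step % trace_every == 0:
                trace.append(cur)

        final_cb = self.costs(sel, norm, alpha_bar, lam)
        best_cb = self.costs(best_sel, norm, alpha_bar, lam)
        return AnnealResult(best_sel, self.cand[best_sel], best_cb, final_cb,
                            np.asarray(trace), accepted, step)

    # -- normalization / Pareto front -------------------------------------

    def estimate_normalization(self, schedule: AnnealSchedule,
                               budget: int | None = None, seed=0,
                               eps: float = 1e-4) -> Normalization:
        """Endpoint runs estimating utopia and nadir points.

        The run at ᾱ = 1 - eps optimizes the degree cost: its C_d is the
        utopia point U_d and its C_e the nadir proxy N_e (finite-weight
        stand-in for the limit ᾱ -> 1); symmetrically at ᾱ = eps.
        """
        rng = np.random.default_rng(seed)
        init = self.initial_selection(budget, rng)
        hi = self.anneal(alpha_bar=1 - eps, schedule=schedule,
                         initial=init, seed=seed + 1)
        lo = self.anneal(alpha_bar=eps, schedule=schedule,
                         initial=init, seed=seed + 2)
        return Normalization(u_d=hi.best.c_d, u_e=lo.best.c_e,
                             n_d=lo.best.c_d, n_e=hi.best.c_e)


@dataclasses.dataclass
class ParetoResult:
    alpha_bar: np.ndarray
    c_d: np.ndarray
    c_e: np.ndarray
    c_d_norm: np.ndarray
    c_e_norm: np.ndarray
    norm: Normalization
    alpha_star: float
    alphas: np.ndarray          # raw-cost weights mapped from alpha_bar


def pareto_front(annealer: EdgeAnnealer, alpha_bar_grid,
                 schedule: AnnealSchedule = AnnealSchedule.fast(),
                 budget: int | None = None, seed=0,
                 norm: Normalization | None = None) -> ParetoResult:
    """Trace the Pareto front of the two objectives over a grid of ᾱ."""
    grid = np.asarray(alpha_bar_grid, dtype=float)
    if len(grid) < 2:
        raise ValueError("alpha_bar grid needs at least 2 points")
    results: dict[int, CostBreakdown] = {}
    if norm is None:
        # the grid extremes double as the utopia/nadir estimators: the run
        # at the largest alpha_bar optimizes C_d (utopia U_d, nadir proxy
        # N_e), the one at the smallest optimizes C_e (U_e, N_d)
        hi = annealer.anneal(alpha_bar=float(grid[-1]), schedule=schedule,
                             budget=budget, seed=seed + 10 + len(grid) - 1)
        lo = annealer.anneal(alpha_bar=float(grid[0]), schedule=schedule,
                             budget=budget, seed=seed + 10)
        norm = Normalization(u_d=hi.best.c_d, u_e=lo.best.c_e,
                             n_d=lo.best.c_d, n_e=hi.best.c_e)
        results[0], results[len(grid) - 1] = lo.best, hi.best
    cds, ces = [], []
    for k, ab in enumerate(grid):
        if k not in results:
            res = annealer.anneal(alpha_bar=float(ab), schedule=schedule,
                                  norm=norm, budget=budget, seed=seed + 10 + k)
            results[k] = res.best
        cds.append(results[k].c_d)
        ces.append(results[k].c_e)
    cds, ces = np.asarray(cds), np.asarray(ces)
    nd = np.array([norm.normalize(a, b) for a, b in zip(cds, ces)])
    return ParetoResult(grid, cds, ces, nd[:, 0], nd[:, 1], norm,
                        norm.alpha_star,
                        np.array([norm.alpha_from_alpha_bar(a) for a in grid]))
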
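"""Permeability-at-risk: resilience of spatial networks to edge removal.

A permeability-at-risk curve reports the normalized permeability K(γ)/K0
after a fraction γ of edges has been removed, under two damage scenarios:

(i)  targeted — edges are removed in descending order of the |current|
     they carried in the *unperturbed* network (the ranking is frozen, not
     recomputed between removals);
(ii) random — edges are removed in a random order sampled without
     replacement with probability proportional to their length, averaged
     over replicates.

K(γ) is nonincreasing (removing a conductor can only reduce conductance);
the percolation threshold γ* is the smallest removal fraction at which no
source-sink path survives and K drops to zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse.csgraph import connected_components

from .flow import axis_permeability, boundary_nodes
from .network import Cuboid, SpatialNetwork

SCENARIO_HIGH_CURRENT = "high_current"
SCENARIO_RANDOM_LENGTH = "random_length_weighted"


@dataclasses.dataclass
class RiskCurve:
    """Normalized permeability vs fraction of removed edges."""

    gammas: np.ndarray
    k_over_k0: np.ndarray          # mean over replicates (scenario ii)
    k_sem: np.ndarray              # standard error (zeros for scenario i)
    k0: float                      # unperturbed K (mm^-2)
    scenario: str
    gamma_star_bracket: tuple[float, float]   # [last nonzero, first zero]
    replicates: np.ndarray         # (n_rep, n_gamma) raw curves

    @property
    def gamma_star(self) -> float:
        """Grid-resolved percolation threshold (first γ with K = 0)."""
        return self.gamma_star_bracket[1]


def _removal_order_high_current(net, roi, axis, kappa, dp, boundary_tol):
    _, _, sol = axis_permeability(net, roi, axis, kappa, dp, boundary_tol)
    # descending |current|; ties broken by edge index for determinism
    order = np.lexsort((np.arange(net.n_edges), -np.abs(sol.edge_currents)))
    return order


def _removal_order_length_weighted(net, rng):
    # Efraimidis-Spirakis weighted sampling without replacement:
    # sorting by u^(1/w) descending draws each prefix with probability
    # proportional to the weights
    u = rng.random(net.n_edges)
    keys = u ** (1.0 / net.weights)
    return np.argsort(-keys)


def _k_after_removal(net, roi, axis, order, n_remove, kappa, dp, boundary_tol):
    keep = np.ones(net.n_edges, bool)
    keep[order[:n_remove]] = False
    sub = net.subnetwork_edges(keep)
    try:
        k, _, _ = axis_permeability(sub, roi, axis, kappa, dp, boundary_tol)
    except ValueError:   # a whole boundary plane lost all its nodes
        return 0.0
    return max(k, 0.0)


def permeability_at_risk(net: SpatialNetwork, roi: Cuboid, scenario: str,
                         gamma_grid=None, kappa: float = 1.0, dp: float = 1.0,
                         seed=0, axis: int = 0, boundary_tol: float = 1e-6,
                         n_replicates: int = 5,
                         recompute_ranking: bool = False) -> RiskCurve:
    """Permeability-at-risk curve for one damage scenario.

    ``recompute_ranking`` switches scenario i to an adaptive variant that
    re-solves the flow and re-ranks after every removal step of the grid
    (off by default; the reference behaviour freezes the unperturbed
    ranking).
    """
    if gamma_grid is None:
        gamma_grid = np.arange(0.0, 0.62, 0.02)
    gammas = np.asarray(gamma_grid, dtype=float)
    k0, _, sol0 = axis_permeability(net, roi, axis, kappa, dp, boundary_tol)
    if k0 <= 0 or sol0.disconnected:
        raise ValueError("unperturbed network does not percolate (K0 = 0)")
    m = net.n_edges

    if scenario == SCENARIO_HIGH_CURRENT:
        if recompute_ranking:
            curves = [_adaptive_high_current(net, roi, axis, gammas, kappa,
                                             dp, boundary_tol)]
        else:
            order = _removal_order_high_current(net, roi, axis, kappa, dp,
                                                boundary_tol)
            curves = [[_k_after_removal(net, roi, axis, order,
                                        int(round(g * m)), kappa, dp,
                                        boundary_tol) for g in gammas]]
    elif scenario == SCENARIO_RANDOM_LENGTH:
        rng = np.random.default_rng(seed)
        curves = []
        for _ in range(n_replicates):
            order = _removal_order_length_weighted(net, rng)
            curves.append([_k_after_removal(net, roi, axis, order,
                                            int(round(g * m)), kappa, dp,
                                            boundary_tol) for g in gammas])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    reps = np.asarray(curves) / k0
    mean = reps.mean(axis=0)
    sem = reps.std(axis=0, ddof=1) / np.sqrt(len(reps)) if len(reps) > 1 \
        else np.zeros_like(mean)
    zero = mean <= 0
    first_zero = float(gammas[np.argmax(zero)]) if zero.any() else float("inf")
    last_nonzero = float(gammas[~zero][-1]) if (~zero).any() else 0.0
    return RiskCurve(gammas, mean, sem, k0, scenario,
                     (last_nonzero, first_zero), reps)


def _adaptive_high_current(net, roi, axis, gammas, kappa, dp, boundary_tol):
    """Adaptive variant: re-rank by current after each removal batch."""
    cur = net.copy()
    removed_total = 0
    m0 = net.n_edges
    ks = []
    for g in gammas:
        want = int(round(g * m0))
        while removed_total < want and cur.n_edges:
            try:
                _, _, sol = axis_permeability(cur, roi, axis, kappa, dp,
                                              boundary_tol)
            except ValueError:
                sol = None
            if sol is None or sol.disconnected:
                batch = np.arange(min(want - removed_total, cur.n_edges))
            else:
                rank = np.lexsort((np.arange(cur.n_edges),
                                   -np.abs(sol.edge_currents)))
                batch = rank[: want - removed_total]
            keep = np.ones(cur.n_edges, bool)
            keep[batch] = False
            removed_total += int((~keep).sum())
            cur = cur.subnetwork_edges(keep)
        try:
            k, _, _ = axis_permeability(cur, roi, axis, kappa, dp, boundary_tol)
        except ValueError:
            k = 0.0
        ks.append(max(k, 0.0))
    return ks


# ---------------------------------------------------------------------------
# low-current pruning
# ---------------------------------------------------------------------------

def prune_low_current(net: SpatialNetwork, roi: Cuboid,
                      percentile: float = 25.0, kappa: float = 1.0,
                      dp: float = 1.0, axis: int = 0,
                      boundary_tol: float = 1e-6
                      ) -> tuple[SpatialNetwork, float]:
    """Remove interior edges below a |current| percentile.

    The percentile is taken among edges that do not touch the boundary of
    the region of interest (no endpoint within ``boundary_tol`` of any ROI
    face); edges strictly below the threshold are removed, so an all-equal
    current distribution loses nothing.  Returns the pruned network and
    the relative decrease of K along ``axis``.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    k0, _, sol = axis_permeability(net, roi, axis, kappa, dp, boundary_tol)
    near_face = np.zeros(net.n_nodes, bool)
    for ax in range(3):
        lo, hi = boundary_nodes(net, roi, ax, boundary_tol)
        near_face[lo] = near_face[hi] = True
    interior_edge = ~(near_face[net.edges[:, 0]] | near_face[net.edges[:, 1]])
    if not interior_edge.any():
        return net.copy(), 0.0
    cur = np.abs(sol.edge_currents)
    threshold = np.percentile(cur[interior_edge], percentile)
    remove = interior_edge & (cur < threshold)
    pruned = net.subnetwork_edges(~remove)
    k1, _, _ = axis_permeability(pruned, roi, axis, kappa, dp, boundary_tol)
    return pruned, float((k0 - k1) / k0)


# ---------------------------------------------------------------------------
# connectivity after damage
# ---------------------------------------------------------------------------

def disconnected_fraction(net: SpatialNetwork, removed_edges: np.ndarray,
                          sources, sinks) -> float:
    """Fraction of non-boundary nodes cut off from every source or every
    sink after removing the given edges (mask or index array)."""
    sources = np.asarray(sources, dtype=np.int64)
    sinks = np.asarray(sinks, dtype=np.int64)
    if len(sources) == 0 or len(sinks) == 0:
        raise ValueError("need nonempty source and sink sets")
    keep = np.ones(net.n_edges, bool)
    removed_edges = np.asarray(removed_edges)
    if removed_edges.dtype == bool:
        keep &= ~removed_edges
    elif removed_edges.size:
        keep[removed_edges] = False
    sub = net.subnetwork_edges(keep)
    _, labels = (connected_components(sub.adjacency(), directed=False)
                 if sub.n_nodes else (0, np.empty(0, np.int64)))
    src_labels = set(labels[sources])
    snk_labels = set(labels[sinks])
    boundary = np.zeros(net.n_nodes, bool)
    boundary[sources] = boundary[sinks] = True
    interior = np.flatnonzero(~boundary)
    if len(interior) == 0:
        return 0.0
    ok = np.array([(labels[i] in src_labels) and (labels[i] in snk_labels)
                   for i in interior])
    return float(1.0 - ok.mean())
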
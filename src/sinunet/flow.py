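"""Kirchhoff flow on spatial networks and normalized permeability.

The transport model treats every edge as a tube of constant flow
resistance per unit length, kappa (Pa m^-4 s): the pressure drop along an
edge of length l carrying volumetric current J is p_j - p_k = kappa l J
(Ohm's law), and current is conserved at every interior node.  Pressure
boundary conditions are imposed on source nodes (p0 + dp) and sink nodes
(p0); the resulting sparse symmetric linear system is solved for interior
pressures.

The normalized permeability

    K_xx = kappa * L_x / A_x * J_x / dp

is a purely geometric area density (mm^-2): J scales as 1/kappa and
linearly in dp, so K is independent of both (Darcy behaviour).  For a
bundle of straight lines spanning the box along x, K_xx equals the number
of lines per cross-sectional area.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .network import Cuboid, SpatialNetwork

UM2_TO_MM2 = 1.0e6  # 1/um^2 -> 1/mm^2


@dataclasses.dataclass
class FlowSolution:
    """Node pressures and signed edge currents for one boundary problem."""

    pressures: np.ndarray        # Pa, per node
    edge_currents: np.ndarray    # m^3/s (in kappa=1 units), signed i->j for i<j
    total_current: float         # inflow at sources = outflow at sinks
    sources: np.ndarray
    sinks: np.ndarray
    disconnected: bool           # True when no source-sink path exists

    def dissipation(self, net: SpatialNetwork, kappa: float = 1.0) -> np.ndarray:
        """Per-edge dissipated power (dp_edge * J_edge) >= 0."""
        return kappa * net.weights * self.edge_currents ** 2


def solve_kirchhoff(net: SpatialNetwork, sources, sinks, dp: float = 1.0,
                    kappa: float = 1.0, p0: float = 0.0) -> FlowSolution:
    """Solve the Kirchhoff equations with pressure boundary conditions.

    Sources are fixed at p0 + dp, sinks at p0 (the gauge choice p0 = 0 is
    the default).  Components containing no boundary node carry zero flow;
    if no component contains both a source and a sink, the solution is
    returned with zero currents and ``disconnected=True`` (not an error —
    the resilience curves rely on this to detect percolation).
    """
    sources = np.asarray(sources, dtype=np.int64)
    sinks = np.asarray(sinks, dtype=np.int64)
    if len(sources) == 0 or len(sinks) == 0:
        raise ValueError("need at least one source and one sink")
    if np.intersect1d(sources, sinks).size:
        raise ValueError("a node cannot be both source and sink")
    if dp <= 0:
        raise ValueError("dp must be positive")
    n = net.n_nodes
    cond = 1.0 / (kappa * net.weights) if net.n_edges else np.empty(0)

    # percolation check: some component must contain a source and a sink
    _, labels = net.connected_components()
    src_labels = set(labels[sources])
    snk_labels = set(labels[sinks])
    if not (src_labels & snk_labels):
        p = np.zeros(n)
        p[sources] = p0 + dp
        p[sinks] = p0
        return FlowSolution(p, np.zeros(net.n_edges), 0.0, sources, sinks, True)

    i, j = net.edges[:, 0], net.edges[:, 1]
    lap = sp.coo_matrix(
        (np.concatenate([cond, cond, -cond, -cond]),
         (np.concatenate([i, j, i, j]), np.concatenate([i, j, j, i]))),
        shape=(n, n)).tocsr()

    fixed = np.zeros(n, bool)
    fixed[sources] = fixed[sinks] = True
    p = np.zeros(n)
    p[sources] = p0 + dp
    p[sinks] = p0

    free = ~fixed
    # pin one node of every boundary-free component (otherwise singular)
    for comp in set(labels) - (src_labels | snk_labels):
        first = int(np.argmax(labels == comp))
        free[first] = False  # pressure stays at gauge 0
    if free.any():
        a = lap[np.ix_(free, free)]
        b = -lap[np.ix_(free, ~free)] @ p[~free]
        p[free] = spsolve(a.tocsc(), b)

    currents = cond * (p[i] - p[j]) if net.n_edges else np.empty(0)
    inflow = np.zeros(n)
    if net.n_edges:
        np.add.at(inflow, i, -currents)
        np.add.at(inflow, j, currents)
    total = float(-inflow[sources].sum())  # net flux out of the source set
    return FlowSolution(p, currents, total, sources, sinks, False)


def conservation_residual(net: SpatialNetwork, sol: FlowSolution) -> float:
    """Max |net flux| at interior nodes divided by the total current."""
    n = net.n_nodes
    net_flux = np.zeros(n)
    i, j = net.edges[:, 0], net.edges[:, 1]
    np.add.at(net_flux, i, -sol.edge_currents)
    np.add.at(net_flux, j, sol.edge_currents)
    interior = np.ones(n, bool)
    interior[sol.sources] = interior[sol.sinks] = False
    if sol.total_current == 0:
        return float(np.abs(net_flux[interior]).max(initial=0.0))
    return float(np.abs(net_flux[interior]).max(initial=0.0)
                 / abs(sol.total_current))


# ---------------------------------------------------------------------------
# permeability
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PermeabilityTensor:
    """Diagonal normalized permeability (mm^-2) along the box axes."""

    K: dict[str, float]            # axis name -> mm^-2
    spans: dict[str, float]        # boundary-plane separation (µm)
    roi: Cuboid
    kappa: float
    dp: float

    @property
    def anisotropy_xy(self) -> float:
        return self.K["x"] / self.K["y"]


_AXES = {"x": 0, "y": 1, "z": 2}


def boundary_nodes(net: SpatialNetwork, roi: Cuboid, axis: int,
                   tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Nodes within ``tol`` of the lower/upper ROI face normal to ``axis``."""
    c = net.positions[:, axis]
    lower = np.flatnonzero(np.abs(c - roi.lower[axis]) <= tol)
    upper = np.flatnonzero(np.abs(c - roi.upper[axis]) <= tol)
    return lower, upper


def axis_permeability(net: SpatialNetwork, roi: Cuboid, axis: int,
                      kappa: float = 1.0, dp: float = 1.0,
                      boundary_tol: float = 1e-6) -> tuple[float, float, FlowSolution]:
    """Normalized permeability along one axis, in mm^-2.

    Sources sit on the lower ROI face, sinks on the upper one; the span is
    the distance between the mean coordinates of the two boundary-node
    planes, and the cross-section is the ROI face area.  Returns
    (K_mm2, span_um, solution).
    """
    lo, hi = boundary_nodes(net, roi, axis, boundary_tol)
    name = "xyz"[axis]
    if len(lo) == 0 or len(hi) == 0:
        face = "lower" if len(lo) == 0 else "upper"
        raise ValueError(
            f"no boundary nodes within {boundary_tol} um of the {face} "
            f"{name}-face of the region of interest")
    sol = solve_kirchhoff(net, lo, hi, dp=dp, kappa=kappa)
    span = float(net.positions[hi, axis].mean() - net.positions[lo, axis].mean())
    area = roi.cross_section(axis)
    k_um2 = kappa * span * sol.total_current / (area * dp)
    return k_um2 * UM2_TO_MM2, span, sol


def permeability_tensor(net: SpatialNetwork, roi: Cuboid, kappa: float = 1.0,
                        dp: float = 1.0, boundary_tol: float = 8.0,
                        axes: str = "xyz") -> PermeabilityTensor:
    """Diagonal permeability tensor over the requested axes (default all)."""
    K, spans = {}, {}
    for name in axes:
        k, span, _ = axis_permeability(net, roi, _AXES[name], kappa, dp,
                                       boundary_tol)
        K[name], spans[name] = k, span
    return PermeabilityTensor(K, spans, roi, kappa, dp)


# ---------------------------------------------------------------------------
# Hagen-Poiseuille estimates
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PoiseuilleEstimates:
    kappa: float        # Pa m^-4 s
    current: float      # m^3/s through one tube
    v_max: float        # m/s, centreline velocity (2x mean for Poiseuille flow)
    reynolds: float     # based on v_max and the tube diameter


def poiseuille_estimates(mu: float, radius: float, dp: float, length: float,
                         blood_density: float = 1050.0) -> PoiseuilleEstimates:
    """Physical estimates for one cylindrical tube (SI units in, SI out).

    kappa = 8 mu / (pi R^4) is the Hagen-Poiseuille resistance per unit
    length; J = dp / (kappa L); v_max = 2 J / (pi R^2); Re uses v_max, the
    diameter 2R and the density of blood.
    """
    if min(mu, radius, dp, length) <= 0:
        raise ValueError("all physical parameters must be positive")
    kappa = 8.0 * mu / (np.pi * radius ** 4)
    current = dp / (kappa * length)
    v_max = 2.0 * current / (np.pi * radius ** 2)
    reynolds = blood_density * v_max * 2.0 * radius / mu
    return PoiseuilleEstimates(kappa, current, v_max, reynolds)


# ---------------------------------------------------------------------------
# current inhomogeneity
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CurrentStats:
    abs_currents: np.ndarray       # per edge
    share_by_rank: np.ndarray      # cumulative dissipation share, rank-ordered
    gini: float                    # 0 = homogeneous, ->1 = concentrated


def current_statistics(net: SpatialNetwork, sol: FlowSolution,
                       kappa: float = 1.0) -> CurrentStats:
    """Inhomogeneity of the current distribution.

    ``share_by_rank[k]`` is the fraction of total dissipated power carried
    by the k+1 highest-dissipation edges; the Gini index is computed from
    the corresponding Lorenz curve.  A zero-flow solution yields an
    all-zero summary.
    """
    diss = sol.dissipation(net, kappa)
    total = diss.sum()
    if total == 0:
        m = net.n_edges
        return CurrentStats(np.abs(sol.edge_currents), np.zeros(m), 0.0)
    desc = np.sort(diss)[::-1]
    share = np.cumsum(desc) / total
    asc = desc[::-1]
    lorenz = np.cumsum(asc) / total
    m = len(asc)
    gini = float(1.0 - 2.0 * (lorenz.sum() - lorenz[-1] / 2.0) / m)
    return CurrentStats(np.abs(sol.edge_currents), share, gini)
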
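"""Core data model for 3D spatial networks.

A spatial network is an undirected graph embedded in 3D space: node
positions in micrometres, edges between node pairs, and a per-edge weight
holding the vessel length along the edge.  Weights may exceed the straight
chord between the endpoints because tortuous degree-2 chains are collapsed
into single edges whose weight is the summed path length.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

#: slack allowed in the ``weight >= chord`` invariant (rounding, merges)
WEIGHT_CHORD_TOL = 1e-6


class NetworkFormatError(ValueError):
    """Raised when input data violate the spatial-network contract."""


@dataclasses.dataclass(frozen=True)
class Cuboid:
    """Axis-aligned cuboid region, coordinates in micrometres."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float).reshape(3)
        hi = np.asarray(self.upper, dtype=float).reshape(3)
        if not np.all(hi > lo):
            raise ValueError(f"upper corner must exceed lower corner: {lo} vs {hi}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def sides(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def volume(self) -> float:
        return float(np.prod(self.sides))

    def cross_section(self, axis: int) -> float:
        """Area of the face normal to ``axis`` (product of the other two sides)."""
        s = self.sides
        return float(np.prod(np.delete(s, axis)))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed cuboid."""
        p = np.atleast_2d(points)
        return np.all((p >= self.lower) & (p <= self.upper), axis=1)

    @classmethod
    def from_points(cls, points: np.ndarray, pad: float = 0.0) -> "Cuboid":
        p = np.atleast_2d(points)
        return cls(p.min(axis=0) - pad, p.max(axis=0) + pad)

    def shrunk(self, margin) -> "Cuboid":
        """Cuboid shrunk by ``margin`` on every face (scalar or per-axis)."""
        m = np.broadcast_to(np.asarray(margin, dtype=float), (3,))
        return Cuboid(self.lower + m, self.upper - m)


def _canonical_edges(edges) -> np.ndarray:
    e = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    return np.sort(e, axis=1)


@dataclasses.dataclass
class SpatialNetwork:
    """Undirected spatial graph with 3D node positions (µm) and edge weights (µm)."""

    positions: np.ndarray
    edges: np.ndarray
    weights: np.ndarray | None = None
    bounding_box: Cuboid | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.edges = _canonical_edges(
            self.edges if len(np.ravel(self.edges)) else np.empty((0, 2), np.int64)
        )
        if self.weights is None:
            self.weights = self.edge_chords()
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_chords(self) -> np.ndarray:
        """Euclidean (straight-line) length of each edge."""
        if self.edges.shape[0] == 0:
            return np.empty(0)
        d = self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        n = self.n_nodes
        if self.n_edges == 0:
            return sp.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        v = self.weights if weighted else np.ones(self.n_edges)
        a = sp.coo_matrix((v, (i, j)), shape=(n, n))
        return (a + a.T).tocsr()

    def connected_components(self) -> tuple[int, np.ndarray]:
        if self.n_nodes == 0:
            return 0, np.empty(0, dtype=np.int64)
        return connected_components(self.adjacency(), directed=False)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    # -- validation -------------------------------------------------------

    def validate(self, weight_tol: float = WEIGHT_CHORD_TOL) -> "SpatialNetwork":
        """Check the spatial-network invariants; raise NetworkFormatError on failure."""
        if self.n_edges:
            e = self.edges
            if e.min() < 0 or e.max() >= self.n_nodes:
                raise NetworkFormatError("edge endpoint outside node range")
            if np.any(e[:, 0] == e[:, 1]):
                raise NetworkFormatError("self-loop edge")
            if len({(int(i), int(j)) for i, j in e}) != self.n_edges:
                raise NetworkFormatError("duplicate edge")
            if np.any(self.weights <= 0):
                raise NetworkFormatError("non-positive edge weight")
            chords = self.edge_chords()
            bad = self.weights < chords * (1.0 - 1e-9) - weight_tol
            if np.any(bad):
                k = int(np.argmax(bad))
                raise NetworkFormatError(
                    f"edge {tuple(self.edges[k])}: weight {self.weights[k]:.6g} below "
                    f"chord {chords[k]:.6g}"
                )
        if self.weights.shape[0] != self.n_edges:
            raise NetworkFormatError("weight count does not match edge count")
        return self

    # -- derived networks -------------------------------------------------

    def copy(self) -> "SpatialNetwork":
        return SpatialNetwork(
            self.positions.copy(), self.edges.copy(), self.weights.copy(),
            self.bounding_box,
        )

    def subnetwork_nodes(self, node_ids: np.ndarray) -> "SpatialNetwork":
        """Induced subgraph on ``node_ids`` (re-indexed 0..k-1, order preserved)."""
        node_ids = np.asarray(node_ids, dtype=np.int64)
        remap = -np.ones(self.n_nodes, dtype=np.int64)
        remap[node_ids] = np.arange(len(node_ids))
        keep = np.zeros(self.n_nodes, bool)
        keep[node_ids] = True
        if self.n_edges:
            emask = keep[self.edges[:, 0]] & keep[self.edges[:, 1]]
            edges = remap[self.edges[emask]]
            weights = self.weights[emask]
        else:
            edges, weights = np.empty((0, 2), np.int64), np.empty(0)
        return SpatialNetwork(self.positions[node_ids], edges, weights,
                              self.bounding_box)

    def subnetwork_edges(self, edge_mask: np.ndarray) -> "SpatialNetwork":
        """Same node set, edges restricted to ``edge_mask``."""
        return SpatialNetwork(self.positions.copy(), self.edges[edge_mask],
                              self.weights[edge_mask], self.bounding_box)


def subnetwork_in_box(net: SpatialNetwork, box: Cuboid,
                      mode: str = "nodes_inside") -> SpatialNetwork:
    """Restrict a network to a cuboid region of interest.

    mode="nodes_inside": keep every node inside the box (isolated ones too)
    plus the induced edges — used for flow computations.
    mode="edges_inside": keep only edges with both endpoints inside the box,
    and only the nodes incident to those edges — used for the nematic order
    parameter, where averaging runs over fully interior edges.
    """
    inside = box.contains(net.positions)
    if mode == "nodes_inside":
        out = net.subnetwork_nodes(np.flatnonzero(inside))
    elif mode == "edges_inside":
        if net.n_edges:
            emask = inside[net.edges[:, 0]] & inside[net.edges[:, 1]]
        else:
            emask = np.zeros(0, bool)
        used = np.unique(net.edges[emask]) if emask.any() else np.empty(0, np.int64)
        out = net.subnetwork_edges(emask).subnetwork_nodes(used)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if out.n_nodes == 0:
        warnings.warn("subnetwork_in_box: empty result", stacklevel=2)
    out.bounding_box = box
    return out
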
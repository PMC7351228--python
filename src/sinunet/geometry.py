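"""Statistical geometry of 3D point sets and spatial networks.

Implements the descriptors used to characterize sinusoidal-network
geometry: the normalized radial distribution function g(r) of branch
points, degree and edge-length distributions, the nematic order parameter
S of edge orientations, the 3D Delaunay graph (with boundary mirroring),
the Euclidean minimum spanning tree, and edge-set containment fractions.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.sparse.csgraph import minimum_spanning_tree

from .network import Cuboid, SpatialNetwork

log = logging.getLogger(__name__)

#: deterministic jitter applied to degenerate point sets (µm)
_JITTER = 1e-6
_JITTER_SEED = 271828


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RDFCurve:
    """Radial distribution function g(r), normalized so a Poisson process
    gives g = 1 at all r."""

    r: np.ndarray          # bin centres (µm)
    g: np.ndarray          # dimensionless
    dr: float              # bin width (µm)
    rho0: float            # mean number density (µm^-3)

    def peak_radius(self) -> float:
        """Radius of the global maximum of g(r)."""
        return float(self.r[np.argmax(self.g)])


def radial_distribution(points: np.ndarray, box: Cuboid, r_max: float,
                        dr: float = 1.0, periodic: bool = False) -> RDFCurve:
    """g(r) of a 3D point set in a cuboid.

    Averaging runs over 'central' points.  Without periodic boundaries,
    central points are those at least ``r_max`` from every box face so
    every shell of radius <= r_max lies inside the box (unbiased, no shell
    clipping); with ``periodic=True`` every point is central and distances
    use the minimum-image convention (the box must be at least 2*r_max on
    each side).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    sides = box.sides
    if periodic:
        if np.any(sides < 2 * r_max):
            raise ValueError("periodic g(r) requires box sides >= 2*r_max")
        central_idx = np.arange(len(pts))
    else:
        inner = box.shrunk(r_max)  # raises if r_max too large for the box
        central_idx = np.flatnonzero(inner.contains(pts))
        if len(central_idx) == 0:
            raise ValueError(
                f"no central points at distance >= {r_max} from all faces; "
                "reduce r_max")
    nbins = int(np.ceil(r_max / dr))
    edges = np.arange(nbins + 1) * dr
    counts = np.zeros(nbins)

    if periodic:
        # chunked minimum-image distances
        for start in range(0, len(pts), 512):
            chunk = pts[start:start + 512]
            d = pts[None, :, :] - chunk[:, None, :]
            d -= np.round(d / sides) * sides
            dist = np.sqrt((d ** 2).sum(axis=-1))
            iself = np.arange(start, start + len(chunk))
            dist[np.arange(len(chunk)), iself] = np.inf
            counts += np.histogram(dist[dist < r_max], bins=edges)[0]
    else:
        tree = cKDTree(pts)
        for i in central_idx:
            neigh = tree.query_ball_point(pts[i], r_max)
            d = np.linalg.norm(pts[neigh] - pts[i], axis=1)
            counts += np.histogram(d[d > 0], bins=edges)[0]

    rho0 = len(pts) / box.volume
    centres = 0.5 * (edges[:-1] + edges[1:])
    shell = 4 * np.pi * centres ** 2 * dr
    g = counts / (len(central_idx) * shell * rho0)
    return RDFCurve(centres, g, dr, rho0)


# ---------------------------------------------------------------------------
# degree / edge-length distributions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NetworkStats:
    """Summary statistics of a spatial network."""

    degree_values: np.ndarray
    degree_pdf: np.ndarray
    degree_cdf: np.ndarray
    length_samples: np.ndarray   # sorted edge weights (µm)
    mean_degree: float
    std_degree: float
    mean_edge_length: float
    std_edge_length: float
    node_density: float | None   # µm^-3, None without a bounding box


def summary_stats(net: SpatialNetwork, box: Cuboid | None = None) -> NetworkStats:
    """Degree and edge-length distributions with their means.

    Edge lengths are the edge *weights* (path lengths along the vessel),
    which for cleaned networks include the tortuosity of collapsed chains.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = net.degrees()
    values, counts = np.unique(deg, return_counts=True)
    pdf = counts / counts.sum()
    lengths = np.sort(net.weights)
    box = box or net.bounding_box
    density = net.n_nodes / box.volume if box is not None else None
    return NetworkStats(
        degree_values=values, degree_pdf=pdf, degree_cdf=np.cumsum(pdf),
        length_samples=lengths,
        mean_degree=float(deg.mean()), std_degree=float(deg.std()),
        mean_edge_length=float(lengths.mean()) if len(lengths) else float("nan"),
        std_edge_length=float(lengths.std()) if len(lengths) else float("nan"),
        node_density=density,
    )


# ---------------------------------------------------------------------------
# nematic order
# ---------------------------------------------------------------------------

def nematic_order(net: SpatialNetwork, axis=(1.0, 0.0, 0.0),
                  box: Cuboid | None = None) -> float:
    """Nematic order parameter S = <3/2 (e_j . e_x)^2 - 1/2>.

    The average runs over edges fully inside ``box`` (both endpoints), each
    edge contributing equally regardless of its length.  S = 1 for perfect
    alignment with ``axis``, 0 for isotropy, -1/2 for perpendicular edges.
    """
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    if box is not None:
        inside = box.contains(net.positions)
        emask = inside[net.edges[:, 0]] & inside[net.edges[:, 1]]
    else:
        emask = np.ones(net.n_edges, bool)
    edges = net.edges[emask]
    if len(edges) == 0:
        raise ValueError("no edges fully inside the region of interest")
    vec = net.positions[edges[:, 1]] - net.positions[edges[:, 0]]
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    cos2 = (vec @ ax) ** 2
    return float(np.mean(1.5 * cos2 - 0.5))


def edge_alignment_terms(positions: np.ndarray, edges: np.ndarray,
                         axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Per-edge contribution 3/2 cos^2(theta) - 1/2 to the nematic order."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    vec = positions[edges[:, 1]] - positions[edges[:, 0]]
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return 1.5 * (vec @ ax) ** 2 - 0.5


# ---------------------------------------------------------------------------
# Delaunay graph and Euclidean MST
# ---------------------------------------------------------------------------

def _delaunay_edges_raw(points: np.ndarray) -> np.ndarray:
    try:
        tri = Delaunay(points)
    except QhullError as err:
        # deterministic jitter to break exact degeneracies (coplanarity etc.)
        warnings.warn(
            f"degenerate point set for Delaunay ({err.__class__.__name__}); "
            f"applying deterministic jitter of {_JITTER} um", stacklevel=3)
        rng = np.random.default_rng(_JITTER_SEED)
        tri = Delaunay(points + rng.normal(0.0, _JITTER, points.shape))
    s = tri.simplices
    pairs = np.vstack([s[:, [a, b]] for a in range(4) for b in range(a + 1, 4)])
    return np.unique(np.sort(pairs, axis=1), axis=0)


def delaunay_graph(points: np.ndarray, mirror_box: Cuboid | None = None
                   ) -> np.ndarray:
    """Edges of the 3D Delaunay graph (dual of the Voronoi tessellation).

    With ``mirror_box``, the point set is mirrored across the six box faces
    before tetrahedralization and only original-original edges are kept —
    this suppresses the spurious long boundary edges that a bare convex
    hull triangulation introduces at the domain surface.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise ValueError("need at least 4 points for a 3D Delaunay graph")
    if mirror_box is None:
        return _delaunay_edges_raw(pts)
    allpts = [pts]
    for axis in range(3):
        for bound in (mirror_box.lower[axis], mirror_box.upper[axis]):
            m = pts.copy()
            m[:, axis] = 2 * bound - m[:, axis]
            allpts.append(m)
    edges = _delaunay_edges_raw(np.vstack(allpts))
    n = len(pts)
    return edges[(edges[:, 0] < n) & (edges[:, 1] < n)]


def euclidean_mst(points: np.ndarray,
                  delaunay_edges: np.ndarray | None = None) -> np.ndarray:
    """Edges of the Euclidean minimum spanning tree of a 3D point set.

    Computed on the Delaunay graph, which always contains the EMST; pass
    precomputed ``delaunay_edges`` to avoid recomputation.  Edges of the
    mirrored Delaunay graph may be a strict subset of the full one, so the
    full (unmirrored) graph should be used here.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    if n == 2:
        return np.array([[0, 1]], dtype=np.int64)
    if n == 3:
        cand = np.array([[0, 1], [0, 2], [1, 2]])
    else:
        cand = delaunay_edges if delaunay_edges is not None \
            else _delaunay_edges_raw(pts)
    w = np.linalg.norm(pts[cand[:, 0]] - pts[cand[:, 1]], axis=1)
    graph = sp.coo_matrix((w, (cand[:, 0], cand[:, 1])), shape=(n, n))
    tree = minimum_spanning_tree(graph.maximum(graph.T)).tocoo()
    edges = np.sort(np.column_stack([tree.row, tree.col]), axis=1)
    if len(edges) != n - 1:
        raise ValueError("point set yields a disconnected candidate graph")
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))].astype(np.int64)


def containment_fraction(query_edges: np.ndarray,
                         reference_edges: np.ndarray) -> float:
    """|query ∩ reference| / |query| for undirected edge sets over a shared
    node labelling."""
    q = {tuple(e) for e in np.sort(np.asarray(query_edges), axis=1)}
    if not q:
        raise ValueError("empty query edge set")
    ref = {tuple(e) for e in np.sort(np.asarray(reference_edges), axis=1)}
    return len(q & ref) / len(q)
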
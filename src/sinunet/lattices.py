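"""Reference lattice networks used as flow and resilience benchmarks.

Three benchmark families: the full cubic lattice, disconnected layers of
square lattices, and random sub-lattices of a cubic lattice (bond-diluted
random resistor networks).  These double as deterministic fixtures for the
flow and resilience modules: the cubic lattice with spacing a has exact
normalized permeability K = 1/a^2 under the cell cross-section convention
(see :func:`lattice_roi`).
"""

from __future__ import annotations

import numpy as np

from .network import Cuboid, SpatialNetwork


def _grid_positions(nx: int, ny: int, nz: int, a: float) -> np.ndarray:
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    return a * np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()]).astype(float)


def _grid_index(nx, ny, nz):
    def idx(i, j, k):
        return (i * ny + j) * nz + k
    return idx


def cubic_lattice(n_per_side: int, spacing: float) -> SpatialNetwork:
    """Full cubic lattice: n^3 nodes, nearest-neighbour edges along all axes."""
    if n_per_side < 2:
        raise ValueError("n_per_side must be >= 2")
    n = n_per_side
    pos = _grid_positions(n, n, n, spacing)
    idx = _grid_index(n, n, n)
    edges = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i + 1 < n:
                    edges.append((idx(i, j, k), idx(i + 1, j, k)))
                if j + 1 < n:
                    edges.append((idx(i, j, k), idx(i, j + 1, k)))
                if k + 1 < n:
                    edges.append((idx(i, j, k), idx(i, j, k + 1)))
    net = SpatialNetwork(pos, np.array(edges), None,
                         Cuboid.from_points(pos))
    return net.validate()


def layered_square_lattices(n_layers: int, n_per_side: int,
                            spacing: float) -> SpatialNetwork:
    """Stack of disconnected square lattices.

    Each layer is an n x n square lattice lying in an x-z plane (so every
    layer spans the flow axis x); layers are stacked along y with no
    inter-layer edges.
    """
    n = n_per_side
    pos_parts, edges = [], []
    offset = 0
    for layer in range(n_layers):
        p = _grid_positions(n, 1, n, spacing)
        p[:, 1] = layer * spacing
        pos_parts.append(p)
        idx = _grid_index(n, 1, n)
        for i in range(n):
            for k in range(n):
                if i + 1 < n:
                    edges.append((offset + idx(i, 0, k), offset + idx(i + 1, 0, k)))
                if k + 1 < n:
                    edges.append((offset + idx(i, 0, k), offset + idx(i, 0, k + 1)))
        offset += n * n
    pos = np.vstack(pos_parts)
    return SpatialNetwork(pos, np.array(edges), None,
                          Cuboid.from_points(pos)).validate()


def random_sublattice(n_per_side: int, fill_fraction: float, spacing: float,
                      seed) -> SpatialNetwork:
    """Bond-diluted cubic lattice: each edge kept independently with
    probability ``fill_fraction`` (a random resistor network)."""
    if not 0 < fill_fraction <= 1:
        raise ValueError("fill_fraction must be in (0, 1]")
    full = cubic_lattice(n_per_side, spacing)
    rng = np.random.default_rng(seed)
    keep = rng.random(full.n_edges) < fill_fraction
    return full.subnetwork_edges(keep)


def lattice_roi(n_per_side: int, spacing: float, axis: int = 0) -> Cuboid:
    """Region of interest giving lattices their natural cell cross-section.

    The transverse faces are padded by half a lattice spacing so that each
    of the n^2 lattice lines owns an a x a cell of the cross-section
    (A = n^2 a^2), while the flow-axis extent stays at the node planes.
    With this convention the full cubic lattice has K = 1/a^2 along every
    axis; spacing 31.6 um gives K very close to 1e3 mm^-2.
    """
    a, n = spacing, n_per_side
    lo = np.full(3, -a / 2)
    hi = np.full(3, (n - 1) * a + a / 2)
    lo[axis], hi[axis] = 0.0, (n - 1) * a
    return Cuboid(lo, hi)
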
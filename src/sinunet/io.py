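"""ASCII I/O for spatial networks.

Reads and writes the three-file dialect used for deposited sinusoidal
network skeletons: a node-position table, an adjacency matrix and an
edge-weight matrix.  Two adjacency/weight dialects are auto-detected by
shape:

* **dense** — an N x N symmetric matrix (0/1 for adjacency, weight values
  for weights);
* **triplets** — rows ``i j`` or ``i j w``; 1-based indices are detected
  and converted (internal node ids are always 0-based).

``write_network`` emits positions (``nodes.txt``), triplet adjacency
(``adjacency.txt``), triplet weights (``weights.txt``) and a convenience
edge list CSV; ``read_network(write_network(net))`` is the identity to the
stated float precision.
"""

from __future__ import annotations

import pathlib

import numpy as np

from .network import NetworkFormatError, SpatialNetwork

_FLOAT_FMT = "%.10g"


def _load_table(path) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no data.*")
        try:
            arr = np.loadtxt(path, ndmin=2, comments="#", delimiter=None)
        except ValueError:
            # tolerate comma-separated files
            arr = np.loadtxt(path, ndmin=2, comments="#", delimiter=",")
    return arr


def _read_positions(path) -> np.ndarray:
    arr = _load_table(path)
    if arr.size == 0:
        return np.empty((0, 3))
    if arr.shape[1] == 4:  # leading node-id column
        arr = arr[:, 1:]
    if arr.shape[1] != 3:
        raise NetworkFormatError(
            f"{path}: expected 3 (or 4) columns of node coordinates, "
            f"got {arr.shape[1]}")
    return arr.astype(float)


def _as_triplets(arr: np.ndarray, n_nodes: int, what: str):
    """Interpret a 2- or 3-column table as (i, j, value) triplets."""
    ij = arr[:, :2]
    if not np.allclose(ij, np.round(ij)):
        raise NetworkFormatError(f"{what}: non-integer node indices")
    ij = np.round(ij).astype(np.int64)
    vals = arr[:, 2] if arr.shape[1] == 3 else np.ones(len(arr))
    if len(ij) and ij.min() >= 1 and ij.max() == n_nodes:
        ij = ij - 1  # 1-based file convention
    if len(ij) and (ij.min() < 0 or ij.max() >= n_nodes):
        raise NetworkFormatError(f"{what}: node index out of range")
    return ij, vals


def _dense_to_edges(mat: np.ndarray, what: str):
    if mat.shape[0] != mat.shape[1]:
        raise NetworkFormatError(f"{what}: matrix is not square")
    if not np.allclose(mat, mat.T):
        raise NetworkFormatError(f"{what}: matrix is not symmetric")
    i, j = np.nonzero(np.triu(mat, k=1))
    return np.column_stack([i, j]), mat[i, j]


def _merge_triplets(ij: np.ndarray, vals: np.ndarray, what: str):
    """Merge symmetric duplicates of undirected triplets; check consistency."""
    if len(ij) == 0:
        return np.empty((0, 2), np.int64), np.empty(0)
    und = np.sort(ij, axis=1)
    if np.any(und[:, 0] == und[:, 1]):
        raise NetworkFormatError(f"{what}: self-loop entry")
    uniq, inv = np.unique(und, axis=0, return_inverse=True)
    out = np.full(len(uniq), np.nan)
    for k, (row, v) in enumerate(zip(inv, vals)):
        if np.isnan(out[row]):
            out[row] = v
        elif not np.isclose(out[row], v):
            raise NetworkFormatError(
                f"{what}: asymmetric values for edge {tuple(uniq[row])}")
    return uniq, out


def _is_dense(arr: np.ndarray, n_nodes: int) -> bool:
    """Shape-based dialect detection.

    An N x N table is read as a dense matrix; anything else as triplets.
    For the ambiguous tiny cases (N in {2, 3} where a triplet list can also
    be N x N) a dense matrix is additionally required to be symmetric with
    a zero diagonal.
    """
    if arr.ndim != 2 or arr.shape != (n_nodes, n_nodes):
        return False
    if n_nodes <= 3 and arr.shape[1] in (2, 3):
        return np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0)
    return True


def _parse_edge_table(arr: np.ndarray, n_nodes: int, what: str):
    """Parse a dense-matrix or triplet table into (edges, values)."""
    if arr.size == 0:
        return np.empty((0, 2), np.int64), np.empty(0)
    if _is_dense(arr, n_nodes):
        return _dense_to_edges(arr, what)
    ij, vals = _as_triplets(arr, n_nodes, what)
    return _merge_triplets(ij, vals, what)


def read_network(node_file, adjacency_file, weight_file=None) -> SpatialNetwork:
    """Read a spatial network from the three-file ASCII dialect.

    ``weight_file`` may be omitted when the adjacency file carries weights
    in a third triplet column; otherwise weights default to chord lengths.
    """
    positions = _read_positions(node_file)
    n = len(positions)
    has_adj = pathlib.Path(adjacency_file).stat().st_size > 0
    adj = _load_table(adjacency_file) if has_adj else np.empty((0, 2))
    edges, vals = _parse_edge_table(adj, n, str(adjacency_file))
    weights = None if np.allclose(vals, 1) else vals  # triplets may carry weights

    if weight_file is not None:
        wtab = _load_table(weight_file)
        wedges, wvals = _parse_edge_table(wtab, n, str(weight_file))
        if len(wedges) != len(edges):
            raise NetworkFormatError(
                f"{weight_file}: {len(wedges)} weights for {len(edges)} edges")
        order = {tuple(e): k for k, e in enumerate(map(tuple, edges))}
        weights = np.empty(len(edges))
        for e, v in zip(map(tuple, wedges), wvals):
            if e not in order:
                raise NetworkFormatError(
                    f"{weight_file}: weight given for absent edge {e}")
            weights[order[e]] = v
    return SpatialNetwork(positions, edges, weights).validate()


def write_network(net: SpatialNetwork, out_dir,
                  dense_adjacency: bool = False) -> dict[str, pathlib.Path]:
    """Write the three-file ASCII dialect plus an edge-list CSV; returns paths."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": out / "nodes.txt",
        "adjacency": out / "adjacency.txt",
        "weights": out / "weights.txt",
        "edges_csv": out / "edges.csv",
    }
    np.savetxt(paths["nodes"], net.positions, fmt=_FLOAT_FMT)
    if dense_adjacency:
        n = net.n_nodes
        a = np.zeros((n, n), dtype=int)
        w = np.zeros((n, n))
        if net.n_edges:
            i, j = net.edges[:, 0], net.edges[:, 1]
            a[i, j] = a[j, i] = 1
            w[i, j] = w[j, i] = net.weights
        np.savetxt(paths["adjacency"], a, fmt="%d")
        np.savetxt(paths["weights"], w, fmt=_FLOAT_FMT)
    else:
        np.savetxt(paths["adjacency"], net.edges, fmt="%d")
        trip = np.column_stack([net.edges.astype(float), net.weights])
        np.savetxt(paths["weights"], trip, fmt=["%d", "%d", _FLOAT_FMT])
    chords = net.edge_chords()
    with open(paths["edges_csv"], "w") as fh:
        fh.write("i,j,chord_um,weight_um\n")
        for (i, j), c, w in zip(net.edges, chords, net.weights):
            fh.write(f"{i},{j},{c:.10g},{w:.10g}\n")
    return paths


def to_graphml(net: SpatialNetwork, path) -> None:
    """Export to GraphML for external viewers (positions as node attributes)."""
    import networkx as nx

    g = nx.Graph()
    for i, (x, y, z) in enumerate(net.positions):
        g.add_node(i, x=float(x), y=float(y), z=float(z))
    for (i, j), w in zip(net.edges, net.weights):
        g.add_edge(int(i), int(j), weight=float(w))
    nx.write_graphml(g, path)
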
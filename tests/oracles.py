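"""Independent brute-force oracles used by several test modules.

These are deliberately naive (exhaustive enumeration, dense linear
algebra, complete-graph MST) and only feasible at tiny n; they share no
code with the implementations they check.
"""

import itertools

import numpy as np


def circumsphere(p):
    """Centre and radius^2 of the sphere through 4 points (None if coplanar)."""
    a = 2 * (p[1:] - p[0])
    b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
    try:
        c = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return None, None
    return c, ((p[0] - c) ** 2).sum()


def brute_force_delaunay(points):
    """Delaunay edges via exhaustive empty-circumsphere tetrahedra."""
    n = len(points)
    edges = set()
    for quad in itertools.combinations(range(n), 4):
        c, r2 = circumsphere(points[list(quad)])
        if c is None:
            continue
        others = [i for i in range(n) if i not in quad]
        d2 = ((points[others] - c) ** 2).sum(axis=1)
        if np.all(d2 > r2 * (1 + 1e-9)):
            edges.update(tuple(sorted(e))
                         for e in itertools.combinations(quad, 2))
    return np.array(sorted(edges))


def brute_force_mst_length(points):
    """Total EMST length via networkx on the complete graph."""
    import networkx as nx
    g = nx.Graph()
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j,
                       weight=float(np.linalg.norm(points[i] - points[j])))
    t = nx.minimum_spanning_tree(g)
    return sum(d["weight"] for _, _, d in t.edges(data=True))


def dense_oracle_pressures(net, sources, sinks, dp, kappa):
    """Independent dense solve of the full Kirchhoff system."""
    n = net.n_nodes
    lap = np.zeros((n, n))
    for (i, j), w in zip(net.edges, net.weights):
        g = 1.0 / (kappa * w)
        lap[i, i] += g
        lap[j, j] += g
        lap[i, j] -= g
        lap[j, i] -= g
    fixed = np.zeros(n, bool)
    p = np.zeros(n)
    p[sources] = dp
    fixed[list(sources) + list(sinks)] = True
    free = ~fixed
    p[free] = np.linalg.solve(lap[np.ix_(free, free)],
                              -lap[np.ix_(free, fixed)] @ p[fixed])
    return p
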
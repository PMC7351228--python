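"""Shared fixtures.

Expensive Monte-Carlo artifacts (packings, annealed networks) are built
once per session and reused across test modules.
"""

import numpy as np
import pytest

import sinunet as sn
from sinunet.annealing import AnnealSchedule, EdgeAnnealer


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def triangle_net():
    pos = np.array([[0.0, 0, 0], [10.0, 0, 0], [5.0, 8.0, 0]])
    edges = [[0, 1], [1, 2], [0, 2]]
    return sn.SpatialNetwork(pos, edges).validate()


@pytest.fixture
def random_net(rng):
    """Random connected 30-node geometric-ish network for flow tests."""
    pos = rng.uniform(0, 100, (30, 3))
    d = sn.delaunay_graph(pos)
    mst = sn.euclidean_mst(pos, d)
    extra = d[rng.choice(len(d), 25, replace=False)]
    edges = np.unique(np.vstack([mst, extra]), axis=0)
    return sn.SpatialNetwork(pos, edges).validate()


@pytest.fixture(scope="session")
def packed_small():
    cfg = sn.PackingConfig(n=1200, radius=4.52, eta=0.2135, cycles=150, seed=7)
    return sn.pack_hard_spheres(cfg)


@pytest.fixture(scope="session")
def rdf_library():
    return sn.build_rdf_library(eta_grid=(0.15, 0.20, 0.30, 0.35), n=1200,
                                cycles=150, seed=11)


@pytest.fixture(scope="session")
def sim_chain():
    """Packing -> subsample -> annealer on a 150 um box (session-wide)."""
    target = sn.synthetic_sinusoid_target(seed=0)
    pts, acc = sn.simulate_node_positions([150.0, 150.0, 150.0], seed=3,
                                          cycles=200)
    box = sn.Cuboid(np.zeros(3), np.full(3, 150.0))
    annealer = EdgeAnnealer(pts, target, box=box)
    return {"target": target, "points": pts, "box": box,
            "annealer": annealer, "packing_acceptance": acc}


@pytest.fixture(scope="session")
def front(sim_chain):
    from sinunet.annealing import pareto_front
    return pareto_front(sim_chain["annealer"], [1e-4, 0.3, 0.5, 0.7, 1 - 1e-4],
                        schedule=AnnealSchedule.smoke(), seed=77)


@pytest.fixture(scope="session")
def annealed(sim_chain):
    res = sim_chain["annealer"].anneal(alpha_bar=0.5,
                                       schedule=AnnealSchedule.smoke(),
                                       seed=5)
    net = sn.SpatialNetwork(sim_chain["points"], res.edges, None,
                            sim_chain["box"]).validate()
    return {"result": res, "network": net, **sim_chain}
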
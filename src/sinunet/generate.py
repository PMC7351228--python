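"""End-to-end synthetic network generation.

Convenience layer chaining the two Monte-Carlo stages: hard-sphere packing
(node positions at a prescribed density with fluid-like short-range
repulsion) followed by simulated-annealing edge selection against a
degree/edge-length target, optionally with a nematic alignment field.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .annealing import AnnealResult, AnnealSchedule, EdgeAnnealer, Normalization
from .network import Cuboid, SpatialNetwork
from .packing import PackingConfig, centered_box, pack_hard_spheres, \
    subsample_to_density
from .targets import SINUSOID_DENSITY_CENTRAL, DistributionTarget


@dataclasses.dataclass
class GeneratedNetwork:
    network: SpatialNetwork
    annealer: EdgeAnnealer
    result: AnnealResult
    packing_acceptance: float


def simulate_node_positions(box_dims, node_density: float = SINUSOID_DENSITY_CENTRAL,
                            radius: float = 4.52, eta: float = 0.2135,
                            cycles: int = 400, seed=0,
                            margin_factor: float = 1.12
                            ) -> tuple[np.ndarray, float]:
    """Hard-sphere surrogate node positions in a box of ``box_dims`` (µm).

    The periodic packing domain is made ``margin_factor`` larger than the
    longest requested side so the density-matched subsample can be drawn
    from a centred interior sub-box away from periodic-image seams.
    """
    dims = np.asarray(box_dims, dtype=float)
    v_sphere = 4.0 / 3.0 * np.pi * radius ** 3
    center_density = eta / v_sphere
    if node_density > center_density:
        raise ValueError(
            f"node density {node_density:.3g} exceeds sphere-centre density "
            f"{center_density:.3g}; raise eta or shrink the radius")
    side = float(dims.max()) * margin_factor
    n = int(round(center_density * side ** 3))
    cfg = PackingConfig(n=n, radius=radius, eta=eta, cycles=cycles, seed=seed)
    res = pack_hard_spheres(cfg)
    sub_box = centered_box(res.box, dims)
    pts = subsample_to_density(res.points, sub_box, node_density, seed + 1)
    return pts, res.acceptance_rate


def generate_network(target: DistributionTarget, box_dims,
                     node_density: float = SINUSOID_DENSITY_CENTRAL,
                     alpha_bar: float = 0.5, lam: float = 0.0,
                     axis=(1.0, 0.0, 0.0),
                     schedule: AnnealSchedule = AnnealSchedule.fast(),
                     norm: Normalization = Normalization(),
                     packing_cycles: int = 400, seed=0) -> GeneratedNetwork:
    """Generate a synthetic spatial network matching a distribution target."""
    pts, acc = simulate_node_positions(box_dims, node_density,
                                       cycles=packing_cycles, seed=seed)
    box = Cuboid(np.zeros(3), np.asarray(box_dims, dtype=float))
    annealer = EdgeAnnealer(pts, target, box=box, axis=axis)
    res = annealer.anneal(alpha_bar=alpha_bar, lam=lam, schedule=schedule,
                          norm=norm, seed=seed + 7)
    net = SpatialNetwork(pts, res.edges, None, box).validate()
    return GeneratedNetwork(net, annealer, res, acc)
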
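"""Monte-Carlo hard-sphere packing: stage 1 of the network generator.

Branch points of sinusoidal networks repel each other like particles of a
simple fluid: their radial distribution function g(r) vanishes below a
characteristic exclusion distance and peaks just above it.  A packing of
equal hard spheres reproduces this with two parameters, the sphere radius
R0 and the volume fraction eta.  This module provides

* the Metropolis packing simulation itself (periodic box, Gaussian trial
  moves, cell-list neighbour search, numba-compiled inner loop),
* the scaling/fitting machinery that matches (R0, eta) to an observed
  g(r) — g scales as g(lambda r; lambda R0, eta) = g(r; R0, eta), so a
  library simulated at unit radius covers all radii,
* density-matched random subsampling of sphere centres into the node
  positions used by the edge-selection stage.

Note on conventions: R0 is the true sphere *radius*; the hard-core
exclusion (minimum centre distance) is 2 R0, and the centre number density
is eta / (4/3 pi R0^3).  Fits are commonly reported as the exclusion
diameter 2 R0, the distance where g(r) rises from zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .network import Cuboid
from .geometry import RDFCurve, radial_distribution


@dataclasses.dataclass(frozen=True)
class PackingConfig:
    """Parameters of one packing simulation."""

    n: int = 10_000            # number of spheres
    radius: float = 4.52       # R0, µm
    eta: float = 0.2135        # volume fraction (dimensionless)
    cycles: int = 2000         # MC cycles; each attempts one move per sphere
    sigma: float | None = None # trial-move std dev (µm); default radius/3
    seed: int = 0

    def __post_init__(self):
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.eta < 0.55:
            raise ValueError("eta must be a volume fraction below the "
                             "grid-start feasibility limit ~0.52")

    @property
    def move_sigma(self) -> float:
        # per-component std dev of the Gaussian trial displacement
        return self.sigma if self.sigma is not None else self.radius / 3.0

    @property
    def box_side(self) -> float:
        v_sphere = 4.0 / 3.0 * np.pi * self.radius ** 3
        return float((self.n * v_sphere / self.eta) ** (1.0 / 3.0))

    @property
    def center_density(self) -> float:
        """Number density of sphere centres (µm^-3)."""
        return self.n / self.box_side ** 3


@dataclasses.dataclass
class PackingResult:
    points: np.ndarray          # sphere centres (n, 3), µm
    box: Cuboid                 # periodic simulation box
    acceptance_rate: float
    config: PackingConfig

    def rdf(self, r_max: float | None = None, dr: float = 0.5) -> RDFCurve:
        r_max = r_max or 6.0 * self.config.radius
        return radial_distribution(self.points, self.box, r_max, dr,
                                   periodic=True)


@njit(cache=True)
def _run_packing(pos, side, min_dist2, sigma, cycles, seed):  # pragma: no cover
    """Metropolis sweep loop with a periodic cell list; returns acceptances."""
    np.random.seed(seed)
    n = pos.shape[0]
    min_dist = np.sqrt(min_dist2)
    ncell = int(side // min_dist)
    use_cells = ncell >= 3
    if not use_cells:
        ncell = 1
    cell_size = side / ncell

    # linked-list cell structure
    head = -np.ones((ncell, ncell, ncell), dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    cell_of = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        cx = min(int(pos[i, 0] / cell_size), ncell - 1)
        cy = min(int(pos[i, 1] / cell_size), ncell - 1)
        cz = min(int(pos[i, 2] / cell_size), ncell - 1)
        cell_of[i, 0], cell_of[i, 1], cell_of[i, 2] = cx, cy, cz
        nxt[i] = head[cx, cy, cz]
        head[cx, cy, cz] = i

    accepted = 0
    trial = np.empty(3)
    for _cycle in range(cycles):
        for i in range(n):
            for d in range(3):
                t = pos[i, d] + np.random.normal(0.0, sigma)
                trial[d] = t - side * np.floor(t / side)
            ok = True
            if use_cells:
                tx = min(int(trial[0] / cell_size), ncell - 1)
                ty = min(int(trial[1] / cell_size), ncell - 1)
                tz = min(int(trial[2] / cell_size), ncell - 1)
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        for oz in range(-1, 2):
                            j = head[(tx + ox) % ncell, (ty + oy) % ncell,
                                     (tz + oz) % ncell]
                            while j >= 0:
                                if j != i:
                                    d2 = 0.0
                                    for d in range(3):
                                        dd = trial[d] - pos[j, d]
                                        dd -= side * np.rint(dd / side)
                                        d2 += dd * dd
                                    if d2 < min_dist2:
                                        ok = False
                                        break
                                j = nxt[j]
                            if not ok:
                                break
                        if not ok:
                            break
                    if not ok:
                        break
            else:
                for j in range(n):
                    if j == i:
                        continue
                    d2 = 0.0
                    for d in range(3):
                        dd = trial[d] - pos[j, d]
                        dd -= side * np.rint(dd / side)
                        d2 += dd * dd
                    if d2 < min_dist2:
                        ok = False
                        break
            if ok:
                if use_cells:
                    cx, cy, cz = cell_of[i, 0], cell_of[i, 1], cell_of[i, 2]
                    tx = min(int(trial[0] / cell_size), ncell - 1)
                    ty = min(int(trial[1] / cell_size), ncell - 1)
                    tz = min(int(trial[2] / cell_size), ncell - 1)
                    if tx != cx or ty != cy or tz != cz:
                        # unlink i from its old cell
                        j = head[cx, cy, cz]
                        if j == i:
                            head[cx, cy, cz] = nxt[i]
                        else:
                            while nxt[j] != i:
                                j = nxt[j]
                            nxt[j] = nxt[i]
                        nxt[i] = head[tx, ty, tz]
                        head[tx, ty, tz] = i
                        cell_of[i, 0], cell_of[i, 1], cell_of[i, 2] = tx, ty, tz
                for d in range(3):
                    pos[i, d] = trial[d]
                accepted += 1
    return accepted


def pack_hard_spheres(cfg: PackingConfig) -> PackingResult:
    """Equilibrate a periodic hard-sphere packing from a grid start.

    Raises before simulating when the volume fraction is too high for a
    non-overlapping cubic grid start.
    """
    side = cfg.box_side
    m = int(np.ceil(cfg.n ** (1.0 / 3.0)))
    if side / m < 2.0 * cfg.radius:
        raise ValueError(
            f"eta={cfg.eta} infeasible: grid spacing {side / m:.3g} um is "
            f"below the exclusion distance {2 * cfg.radius:.3g} um")
    # cubic grid start, first n sites
    grid = (np.arange(m) + 0.5) * (side / m)
    gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])[: cfg.n]
    pos = np.ascontiguousarray(pos, dtype=np.float64)

    seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2 ** 31))
    accepted = _run_packing(pos, side, (2.0 * cfg.radius) ** 2,
                            cfg.move_sigma, cfg.cycles, seed)
    rate = accepted / (cfg.cycles * cfg.n)
    box = Cuboid(np.zeros(3), np.full(3, side))
    return PackingResult(pos, box, float(rate), cfg)


def min_pair_distance(points: np.ndarray, side: float) -> float:
    """Minimum-image minimum pairwise distance (debug check of the hard core)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(np.mod(points, side), boxsize=side)
    d, _ = tree.query(np.mod(points, side), k=2)
    return float(d[:, 1].min())


# ---------------------------------------------------------------------------
# g(r) library and parameter fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RDFLibrary:
    """g(s; eta) simulated at unit radius, on a dimensionless grid s = r/R0."""

    s: np.ndarray               # r in units of R0
    eta_grid: np.ndarray
    g: np.ndarray               # shape (len(s), len(eta_grid))


def build_rdf_library(eta_grid=(0.15, 0.20, 0.30, 0.35), n: int = 2000,
                      cycles: int = 300, s_max: float = 9.0, ds: float = 0.25,
                      seed: int = 0) -> RDFLibrary:
    """Simulate the reference g(r) curves at unit sphere radius.

    The scaling identity g(lambda r; lambda R0, eta) = g(r; R0, eta) makes
    a unit-radius library sufficient for every R0.
    """
    curves = []
    for k, eta in enumerate(eta_grid):
        cfg = PackingConfig(n=n, radius=1.0, eta=float(eta), cycles=cycles,
                            seed=seed + k)
        res = pack_hard_spheres(cfg)
        curves.append(res.rdf(r_max=s_max, dr=ds))
    s = curves[0].r
    g = np.column_stack([c.g for c in curves])
    return RDFLibrary(s, np.asarray(eta_grid, dtype=float), g)


def _model_g(r: np.ndarray, r0: float, eta: float, lib: RDFLibrary) -> np.ndarray:
    """Interpolated model g(r; R0, eta): spline in eta, scaling in R0."""
    from scipy.interpolate import CubicSpline, interp1d

    ky = min(3, len(lib.eta_grid) - 1)
    if ky >= 2:
        eta_spline = CubicSpline(lib.eta_grid, lib.g, axis=1)
        g_eta = eta_spline(eta)
    else:
        g_eta = interp1d(lib.eta_grid, lib.g, axis=1,
                         fill_value="extrapolate")(eta)
    s = r / r0
    return np.interp(s, lib.s, g_eta, left=0.0, right=1.0)


def fit_packing_parameters(g_target: RDFCurve, lib: RDFLibrary,
                           r_fit_max: float = 40.0) -> tuple[float, float]:
    """Least-squares fit of (R0, eta) to an observed g(r).

    Unweighted least squares over r in [0, r_fit_max] µm; the model curve
    comes from the unit-radius library via radial scaling and spline
    interpolation in eta.  Returns (R0, eta) with R0 the sphere radius.
    """
    from scipy.optimize import minimize

    mask = g_target.r <= r_fit_max
    r, g = g_target.r[mask], g_target.g[mask]
    if len(r) < 5:
        raise ValueError("g_target too short for the requested fit range")

    def loss(theta):
        r0, eta = theta
        if r0 <= 0 or not lib.eta_grid[0] <= eta <= lib.eta_grid[-1]:
            return 1e6
        return float(np.sum((g - _model_g(r, r0, eta, lib)) ** 2))

    # coarse grid start, then simplex refinement
    r0_grid = np.linspace(0.3 * r_fit_max / 6, r_fit_max / 3, 24)
    eta_grid = np.linspace(lib.eta_grid[0], lib.eta_grid[-1], 9)
    best = min(((loss((a, b)), a, b) for a in r0_grid for b in eta_grid))
    res = minimize(loss, x0=[best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-8})
    r0, eta = res.x
    return float(r0), float(eta)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_to_density(points: np.ndarray, box: Cuboid,
                         target_density: float, seed) -> np.ndarray:
    """Uniform random subset of points in ``box`` matching a target density.

    The number of retained points is round(target_density * box volume);
    for sinusoidal-network densities this selects about 20% of the sphere
    centres.  ``box`` should be an interior sub-box of the periodic packing
    domain so that periodic-image seams do not enter the sample.
    """
    pts = np.asarray(points)
    inside = np.flatnonzero(box.contains(pts))
    count = int(round(target_density * box.volume))
    if count > len(inside):
        raise ValueError(
            f"target density {target_density:.4g} /um^3 needs {count} points "
            f"but only {len(inside)} lie in the box")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(inside, size=count, replace=False)
    return pts[np.sort(chosen)] - box.lower  # re-origin to the sub-box corner


def centered_box(outer: Cuboid, dims) -> Cuboid:
    """Axis-aligned sub-box of given dimensions centred in ``outer``."""
    dims = np.asarray(dims, dtype=float)
    if np.any(dims > outer.sides):
        raise ValueError("requested sub-box exceeds the outer box")
    lo = outer.lower + (outer.sides - dims) / 2
    return Cuboid(lo, lo + dims)
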
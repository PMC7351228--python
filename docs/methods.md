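# Methods

This note documents the models implemented in `sinunet`, the choices made
where the procedures were genuinely open, the defaults and their units,
and what the synthetic-data generator does and does not emulate.

## Spatial networks and units

All coordinates and lengths are micrometres throughout; permeabilities
alone are reported in mm⁻² (1 µm⁻² = 10⁶ mm⁻²).  An edge weight is the
vessel path length along the edge and may exceed the straight chord
between its endpoints, because cleaning collapses tortuous degree-2
chains into single edges carrying the summed length.  Validation enforces
weight ≥ chord (up to a tolerance), symmetry, no self-loops and no
duplicate edges.

## Skeleton cleaning

Order of operations: keep the largest connected component; merge
connected nodes closer than the cut-off R_c = 8 µm (the outer vessel
diameter — such pairs are segmentation artifacts, not branch points);
prune dead ends (degree < 2) to a fixed point; collapse maximal chains of
degree-2 nodes into single edges conserving total length; remove
triangles left dangling at chain-collapse sites.  The whole sequence is
iterated to a global fixed point, making the operation idempotent.

Open choices, resolved as follows:

* **Merged node position** — the midpoint of the pair (neither original
  is privileged); distances are re-examined after every merge, shortest
  pairs first.
* **Parallel edges** created by merges/collapses consolidate onto the
  smaller weight: of two tubes joining the same nodes the shorter
  dominates the conductance.
* **"Dangling triangle"** is interpreted as a triangle attached to the
  rest of the network through a single vertex (i.e. at least two of its
  vertices have degree 2); those degree-2 vertices are deleted and the
  pruning pass cleans up.  This is an interpretation — other readings of
  "triangles at the extremities" are possible.
* A component that is a pure degree-2 cycle has no branch points at all
  and is dropped; an input with no cycle-containing component yields an
  empty network with a warning.

## Statistical geometry

**g(r).**  The radial distribution function is normalized by the mean
density ρ₀ = N/V so a Poisson process gives g = 1.  Boundary handling:
central points are restricted to those at least r_max from every box face
(simple and unbiased; no shell-clipping corrections), with a
minimum-image periodic variant for packing boxes.  Default bin width
1 µm.

**Nematic order.**  S = ⟨3/2 (e·e_x)² − 1/2⟩ over edges with *both*
endpoints in the region of interest, each edge weighted equally
regardless of length (length weighting would bias anisotropic networks
toward their long edges).  S ∈ [−1/2, 1].

**Delaunay graph.**  scipy's Qhull tetrahedralization; edges are simplex
edges.  Near-degenerate inputs (coplanar points) receive a deterministic
jitter of 10⁻⁶ µm (fixed seed) with a warning.  For bounded samples the
point set is first mirrored across the six box faces and only
original–original edges kept, which suppresses the spurious long edges a
convex-hull triangulation creates at the surface.  The Euclidean MST is
computed on the (unmirrored) Delaunay graph, which always contains it.

## Hard-sphere packing (generator stage 1)

Metropolis Monte Carlo of n equal hard spheres in a periodic cubic box:
grid start, isotropic Gaussian trial moves (per-component σ, default
R₀/3), cell-list neighbour search, numba-compiled inner loop.  The box
side follows from (n, R₀, η); infeasible volume fractions are rejected
before simulating.  Defaults: n = 10⁴ spheres, 2000 cycles (one
attempted move per sphere per cycle); desk-scale runs in tests and the
acceptance script use n ≈ 1200–4000 and 150–250 cycles, which is
sufficient because g(r) equilibrates within tens of cycles at η ≈ 0.21.

**Radius convention.**  `radius` is the true sphere radius; the hard-core
exclusion (minimum centre distance) is 2·radius and the centre density is
η/(4πR₀³/3).  Observed sinusoidal branch-point statistics correspond to
an exclusion distance of ≈ 9.04 µm — i.e. radius 4.52 µm — at η = 0.2135:
with these values the centre density is 5.5·10⁻⁴ µm⁻³ and the
density-matched subsample keeps about 20% of centres (17.5% for the
whole-sample density 0.9659·10⁻⁴ µm⁻³, 22.8% for the central-region
density 1.2571·10⁻⁴ µm⁻³).  Fit results are therefore reported as the
exclusion diameter 2R̂₀.  η is dimensionless (a volume fraction).

**Fitting.**  A library of g(s; η) curves is simulated once at unit
radius (η ∈ {0.15, 0.20, 0.30, 0.35}); the scaling identity
g(λr; λR₀, η) = g(r; R₀, η) turns it into a two-parameter model with a
cubic spline across η.  The fit is unweighted least squares over
r ∈ [0, 40] µm (coarse grid search, then Nelder–Mead); range and
weighting are package choices.  Parameter recovery on self-generated
targets is within 5% in R₀ and 0.03 in η at n ≈ 10³.

**Acceptance rate.**  At η = 0.2135 the measured Metropolis acceptance is
≈ 55% for σ = radius/3 and ≈ 33% for σ = exclusion/3 — acceptance depends
only on σ/R₀ and η, so these are properties of the model, not tuning
targets.  Tests assert the monotone decrease of acceptance with σ, not a
specific rate.

**Subsampling.**  round(ρ·V) points drawn uniformly inside a centred
sub-box of the periodic domain (away from image seams).  Subsampling
leaves g(r) unchanged — numerator and denominator of g scale together.

## Edge annealing (generator stage 2)

State: a boolean selection over the candidate edge list (the mirrored
Delaunay graph, union the MST so the tree is always available).  Moves
swap one selected non-tree edge against one unselected candidate,
accepted with probability exp(−ΔC/T) (probability 1 when ΔC < 0).
Because tree edges are never removed, M(P) ⊆ E_sim ⊆ D(P) and the edge
count are invariants of every step — this resolves in favour of the
containment constraint an ambiguity about whether swaps may touch tree
edges, and guarantees connectivity throughout.

Costs: C_d sums squared CDF differences over integer degrees; C_e
integrates the squared difference of the two piecewise-constant empirical
length CDFs *exactly* on the merged breakpoint grid (no histogram
binning) and divides by R_c = 8 µm.  The annealer maintains the degree
histogram, the cumulative length counts and the alignment sum
incrementally; a from-scratch recomputation is kept as the test oracle.
The optional nematic field subtracts λ·S_sim from the normalized cost
(the ν normalization of the raw-cost formulation is absorbed by working
with normalized costs).

Schedules (attempted moves): production T₀ = 1, melt 10⁴ steps, ×0.998
every 10³ steps down to 10⁻¹⁰ (≈ 1.2·10⁷ steps); `fast` shortens the
cooling blocks 100× (≈ 1.2·10⁵ steps) and `smoke` further coarsens the
cooling factor (≈ 7·10³ steps) for tests.  The returned edge set is the
best seen during the run (elitist bookkeeping), so its cost equals the
minimum encountered by construction; the end-of-schedule cost is also
reported.

**Utopia/nadir and the Pareto front.**  Single-objective optima are
approximated by endpoint runs at ᾱ = 10⁻⁴ and 1 − 10⁻⁴ (finite proxies
for the α limits).  In `pareto_front` the grid extremes themselves serve
as those estimators, which pins the normalized endpoint costs to exactly
0 and 1; interior points can stray outside [0, 1] by a few percent at
reduced schedules because finite annealing is stochastic — the property
is exact only for exact optima.  ᾱ = 1/2 maps exactly to
α\* = (N_e−U_e)/(N_d−U_d+N_e−U_e).

**Edge budget.**  |E_sim| defaults to round(N·⟨d⟩_target/2); a helper
matches a target edge count per volume instead.  Both modes leave the
budget fixed for the whole run.

## Flow and permeability

Sparse Dirichlet solve of the weighted graph Laplacian (conductance
1/(κl) per edge, SciPy spsolve); sinks are gauged to p = 0.  Components
without boundary nodes are pinned to the gauge and carry no flow; if no
component contains both a source and a sink the solution is returned
flagged `disconnected` with zero current — resilience curves rely on
this rather than an exception.  Conservation residuals are below 10⁻⁹ of
the total current; the dense full-system solve is retained as a test
oracle.

Normalization convention (pinned by the cubic-lattice anchor): the span
L is the distance between the mean planes of the two boundary-node sets;
the cross-section A is the ROI face area.  For lattices the natural ROI
(`lattice_roi`) pads the transverse faces by half a spacing so each of
the n² lattice lines owns an a×a cell — then the full cubic lattice gives
exactly K = 1/a², i.e. 10³ mm⁻² at a = 31.6 µm.  For biological-scale
networks the default boundary tolerance is one merge radius (8 µm);
lattices use exact-face matching.

## Resilience

Scenario i freezes the removal ranking on the unperturbed currents (ties
broken by edge index); an adaptive re-ranking variant exists behind a
flag, off by default.  Scenario ii samples removal orders without
replacement with probability ∝ edge length (Efraimidis–Spirakis keys),
averaged over seeded replicates (default 5).  γ counts edges by number;
K(γ) is recomputed per grid point (default step 0.02, tests use coarser
grids) and γ\* is reported as the bracket [last nonzero γ, first zero γ].
Low-current pruning removes interior edges (no endpoint within the
boundary tolerance of any ROI face) strictly below the |current|
percentile, so all-equal currents lose nothing.

## The synthetic reference target

The deposited experimental skeletons are not shipped with the package.
The synthetic target reproduces their published summary statistics —
degree PMF {3: 0.75, 4: 0.20, 5: 0.05} (mean 3.30, s.d. 0.56, matching
3.3 ± 0.6), gamma-distributed edge lengths with mean 17 µm and s.d. 8 µm,
node densities 0.9659·10⁻⁴ µm⁻³ (whole sample) and 1.2571·10⁻⁴ µm⁻³
(central region) — and nothing more.  It does **not** emulate
degree–length correlations, orientation-dependent edge lengths, the
lobule-scale curvature of the nematic director, or large-vessel voids.
Consequently, tests passing against this target show that the pipeline
reproduces prescribed marginals and the qualitative flow/resilience
signatures (fluid-like g(r), anisotropy growing with S, steeper targeted
than random risk curves); they do not certify agreement with any
particular tissue sample.  Quantities tied to the specific experimental
geometry (e.g. the ~11% permeability drop under 25th-percentile pruning
reported for real samples) come out smaller on the synthetic networks at
desk scale, as the acceptance script's output shows.

## Problem sizes

Defaults used by the test suite and the acceptance script: packings of
1.2–4·10³ spheres (6·10⁴ briefly equilibrated for the subsample-count
check), generated networks of ~420 nodes (tests, 150 µm box) and 1964
nodes (acceptance, 250 µm box at central density), `fast`/`smoke`
annealing schedules, risk grids of 20–30 γ points with 3–5 replicates.
These sizes were chosen so the whole pipeline reruns in minutes while
keeping every qualitative result stable across seeds; production-scale
runs use the same code paths with the production schedule and larger n.

## Known limitations

* Constant, equal resistance per unit length: no tube radii, no
  non-Newtonian rheology, no diameter-dependent apparent viscosity, no
  hematocrit phase separation.
* A single straight nematic reference axis (central-lobule
  approximation); curved director fields are out of scope.
* The annealer prescribes marginal distributions only.
* Cleaning interprets two under-specified details (merge placement,
  triangle extremity) as documented above.
* scipy's Qhull is the single source of Delaunay truth at production
  sizes; the exhaustive circumsphere oracle checks it only at small n.
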
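# Methods

## The model

`aratile` simulates a nonlocal aggregation–diffusion description of
multicellular column patterning. A single cell population with density
u(x, t) on the periodic square (−L, L)², L = 2.8, evolves by

    ∂u/∂t = ∇·(u ∇u) − ∇·(u (1 − u) K(u)),
    K(u)(x) = ∫_{|y|≤1} u(x + y) ω(|y|) (y/|y|) dy.

The first term is population pressure (nonlinear degenerate diffusion,
which keeps interfaces sharp); the second is directed motion driven by the
net pairwise force each cell senses within its sensing radius (normalised
to 1); the (1 − u) factor saturates motion in packed regions. The
interaction kernel is piecewise constant in distance:

    ω(r) = F0 on [0, R0)      short-range adhesion   (F0 > 0)
           Fr on [R0, R1)     medium-range repulsion (Fr ≤ 0)
           0  on [R1, R2)     the "terrace"
           Fa on [R2, 1)      long-range attraction  (Fa ≥ 0)
           0  on [1, ∞)

with all bands half-open — a radius exactly at a breakpoint takes the
right-hand band's value. The induced potential U (with U′ = ω, U(0) = 0)
is piecewise linear and flat over the terrace. The width of that flat
stretch is the control knob for lattice type: a negligible terrace favours
triangular packings of the emergent cell clusters, a wide terrace square
packings.

The three-species extension models the R7/R8/Mi1 columnar neurons of the
fly medulla as densities u, v, w with total σ = u + v + w:

    ∂u_i/∂t = ∇·(u_i ∇σ) − ∇·(u_i (1 − σ) K_i),
    K_i = Σ_j (ω_ij applied to u_j as above).

Only the R7–R7 pair carries the full four-band kernel; every other pair is
pure adhesion (Fr = Fa = 0, stored with R1 = R2 = R0 so one code path
serves both shapes). The interaction matrix is symmetric (action–reaction)
and the adhesion strengths are ordered F0_11 > F0_12 > F0_22 > F0_23 >
F0_33, which keeps R7 at the column core, R8 in a surrounding annulus and
Mi1 as the background. Defaults: F0_11 = 2000, Fr_11 = −2000, R0_11 =
0.14, R1_11 = 0.55; F0_22 = 25, F0_12 = 50, F0_33 = 10, F0_13 = 20,
F0_23 = 15; R0_12 = 0.3 and all other R0_ij = 0.14. The attraction pair
(Fa_11, R2_11) is the primary experimental dial (N-cadherin manipulation
in R7); its neutral setting in sweeps is Fa_11 = 300, R2_11 = 0.64.

## Discretisation

Cell-centred finite volumes, N×N with N even, Δx = 2L/N. Face fluxes
combine a two-point central gradient of the (total) density with the
nonlocal drift averaged to the face; the donor cell is chosen by the sign
of the face velocity V = −∇σ + (1 − σ)_+ K (the saturation factor is
clamped at zero from below so rough initial data cannot reverse the drift).
The update is in conservation form, so each species' mass is conserved to
round-off, and the donor-cell construction keeps densities nonnegative
under the step-size restriction.

The nonlocal integral is evaluated as a fixed Cartesian stencil: weights
w(y) = ω(|y|) ŷ Δx² at every cell-centre offset inside the unit disk,
applied by periodic FFT convolution. A direct shift-and-accumulate
evaluation of the same sum (`method="direct"`) and an independent
polar-node quadrature with bilinear interpolation (in the test suite)
cross-validate it: the former to round-off, the latter to discretisation
error, which is O(Δx) because the kernel jumps at the band radii.

Time step: Δt = 0.9·min(Δx²/(4 max σ), Δx/(2 max(|Vx| + |Vy|))),
recomputed every step. The second bound uses the per-cell sum of face
speeds, which makes the donor-cell update provably nonnegativity
preserving (total outflow factor ≤ 0.9 < 1).

Steady state is declared when the l²(Ω) distance between solutions one
time unit apart falls below 10⁻⁵ (the residual log is returned); a hard
cap (default t = 2000) flags non-convergence. Grid resolution must satisfy
Δx ≤ R0/3 so the adhesion band spans at least three cells; N = 128 on the
full domain is the working resolution, N = 256 for presentation-quality
single-species patterns.

## Symmetry indices

Cluster centres are extracted from a density snapshot as connected
components of {u ≥ 0.01} under periodic 8-connectivity; each component
contributes its density-weighted centroid, computed with a circular mean
per axis so boundary-straddling clusters land correctly. A pattern is
flagged "disrupted" when the cluster count drifts more than 20% from the
initial column count or any component covers more than 10% of the domain;
disrupted patterns get no indices.

For a point set, three neighbourhood rules collect angles around each
home particle; the recorded angles are the gaps between azimuthally
consecutive neighbour directions (summing to 360° per home):

- NBH-1: 4 nearest neighbours (perturbed triangular: 60/120/180°;
  square: 90°),
- NBH-2: 6 nearest neighbours (triangular: 60°; square: 45/90°),
- NBH-3: all particles within d_ave·√2·α₁ of the home, where d_ave is the
  mean distance to its 4 nearest neighbours and α₁ = 1.1 (triangular: 6
  neighbours, 60°; square: 8 neighbours, 45°).

The gap definition is the one that reproduces all six of those canonical
concentration sets; pairwise-angle definitions fail the square NBH-1
case. Exact nearest-neighbour ties (perfect lattices) are broken by point
index, which is deterministic and leaves the gap multiset invariant for
the square-lattice diagonal tie.

Edge handling: with d_med the median nearest-neighbour distance, a
particle is a home only if at least 6 others lie within d_med·√2·α₂,
α₂ = 1.2; torus point sets have no edges. Angles above π (possible under
heavy perturbation) stay in the pooled sample; both data and reference
CDFs are evaluated on (0, π) only, so their treatment cancels in the
error norm.

The pooled empirical CDF F_k^data is fitted against a library of
reference CDFs F_k(θ; h, p) built from the one-parameter
centred-rectangular lattice family — rows at vertical pitch h·spacing,
alternate rows offset half a spacing; h = 1/2 is the square lattice,
h = √3/2 the triangular one — perturbed by displacing each point
independently, uniformly on the disk of radius (p/100)·spacing.
References use a 64×64 torus (4096 particles) and a fixed seed.
Index-k is the h* minimising the L2(0, π) distance over
0.5 ≤ h ≤ 1, 0 ≤ p ≤ pmax (exhaustive grid argmin; ties broken by
smaller p, then smaller h). Defaults: h step 0.005, p step 1 point,
pmax = 40 for observed point sets and 30 inside sweeps. The L2 norm is
evaluated by trapezoidal quadrature on 2048 uniform θ nodes, which
resolves unit steps to well below the fit noise.

### Precision of the fit, and the replicate knob

Reference CDFs default to a single fixed-seed realisation per (h, p)
node. That is fully reproducible, but near the hexagonal end of the
family (h ≳ 0.85, p ≳ 10) the E(h, p) valley is extremely shallow:
neighbouring h nodes differ by ~2·10⁻⁴ in E while a single 4096-particle
ECDF carries sampling noise of ~10⁻³. Fitted h values there scatter over
±0.02–0.07 between realisations — the same "significantly large" noise
the sweep analysis exhibits. For quantitative parameter recovery the
`replicates` option pools several independent realisations per node
(and, symmetrically, per data ECDF); with 24 replicates the recovery of
(h, p) over the whole family is reliable to |Δh| ≤ 0.015 and |Δp| ≤ 2.5.
Tetragonal-to-intermediate patterns (h ≤ 0.7, the regime the biological
data occupies) recover sharply even without averaging.

## Synthetic data: what it emulates and what it does not

The experimental column coordinates behind the original analyses are not
publicly deposited, so the package generates its own stand-ins:

- Perturbed-lattice point sets emulate column patterns of known symmetry
  (h) and disorder (p). They reproduce the angle statistics of real
  patterns but are statistically homogeneous and isotropic; real medulla
  images carry curvature, gradients, imaging edge effects and
  segmentation noise that the generator does not model. Passing the
  parameter-recovery tests therefore certifies the estimator on clean,
  well-specified input, not robustness to imaging artefacts.
- The default sweep initial condition is ~90 points of an h = 0.65,
  p = 15% lattice rescaled to mean nearest-neighbour distance 0.61 —
  an intermediate-symmetry pattern mimicking the observed control state.
  It is a finite cloud in the periodic domain, like the original image
  coordinates. For the scaled-down terrace comparison in the test suite
  the initial columns instead tile the torus exactly (60 points, 6×10,
  h = 0.6, spacing 0.78): a partially empty domain leaves cloud-edge
  clusters with vacuum on one side, and with few columns their
  contaminated angles dominate the pooled statistics.

## Symmetry breaking in the single-species patterns

The artificial single-species initial condition (u = 0.1 on a disk of
radius 0.2) is invariant under quarter-turn rotations, and the scheme is
equivariant under that symmetry to round-off. A triangular cluster
lattice is incompatible with four-fold symmetry, so from the exact disk
the narrow-terrace parameter set relaxes into symmetric ring/square
configurations instead — a degenerate, non-generic outcome. Quadratures
that are not exactly symmetric (e.g. polar-node rules) break this
degeneracy intrinsically. The package exposes `init_noise`: a small
multiplicative perturbation of the disk (default off, fixed seed) that
plays the same role explicitly. With 2% noise at N = 256 the
narrow-terrace run forms locally triangular order (Index-3 ≈ 0.75–0.98)
while the wide-terrace run forms a square lattice (Index-3 ≈ 0.5) with or
without noise — the terrace mechanism, recovered as soon as the
degeneracy is lifted. At N = 128 the narrow-terrace clusters are only 2–4
cells wide and the triangular ordering does not develop regardless of
noise; lattice-type discrimination of this initial condition needs the
finer grid.

## Problem sizes used by the test suite

Chosen so the full suite runs comfortably on one CPU:

- quadrature cross-checks on 32²–96² grids;
- parameter recovery: k = 2 library on h ∈ {0.50, 0.51, …, 1.00} ∪ {√3/2},
  p ∈ {0, 5, …, 30}, n = 4096, 24 replicates; data at the same size;
- narrow-terrace vs wide-terrace single-species discrimination: A at
  N = 256 with 2% initial noise evolved to t = 12 (the classification is
  stable from t = 5 on); B at N = 128 to the 10⁻⁵ steady state;
- terrace comparison: torus-tiling 60-column initial state, N = 108,
  L = 2.34, both runs to a fixed evolution time;
- sweep machinery: single-node sweeps on N = 88, L = 1.9 grids.

## Known limitations

- The Cartesian stencil quadrature is first-order accurate at the kernel
  band jumps; band radii are effectively quantised to the grid. Index
  values from solver output at N = 128 carry a few-percent bias relative
  to finer grids.
- Steady-state detection by the t vs t−1 criterion can fire during slow
  coarsening (it measures rate of change, not distance to the attractor);
  conversely some three-species runs keep creeping below the cap without
  formally converging. Residual logs are always returned so callers can
  inspect the approach.
- Disruption flagging (cluster-count drift / giant component) is an
  operational definition; borderline patterns near the flag thresholds
  should be inspected visually.
- The index fit reports the grid argmin; no uncertainty is attached. Near
  the hexagonal end the likelihood surface is intrinsically flat and
  single-realisation indices there should be read as ±0.05.
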
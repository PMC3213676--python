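# Methods

## Model and scope

The package models circuits of two mutually repressive genes, optionally
with positive autoregulation, as the planar dynamical system

    dx/dt = f(x, y) = B_X + fold_XX·H⁺(x; K_DXX) + fold_YX·H⁻(y; K_DYX) − deg_X·x
    dy/dt = g(x, y) = B_Y + fold_YY·H⁺(y; K_DYY) + fold_XY·H⁻(x; K_DXY) − deg_Y·y

with Hill terms `H⁺(v; K) = vⁿ/(Kⁿ + vⁿ)` and `H⁻(v; K) = Kⁿ/(Kⁿ + vⁿ)`, a
shared Hill coefficient `n = n_H ≥ 1`, and powers of zero defined as 0 for
n > 0. This additive activation/repression form is the standard one for
cross-antagonistic lineage-regulator pairs (PU.1/GATA1-type motifs). All
quantities are dimensionless. The bistable preset is the toggle switch
(fold_XX = fold_YY = 0; fold_YX = fold_XY = 2, K_DYX = 0.7, K_DXY = 0.5,
B = 0.2, deg = 1, n_H = 4); its unused autoregulation affinities are stored
as 1.0, a placeholder without dynamical effect. The tristable preset sets
all folds to 10, all affinities to 4, B = 0, deg = 1, n_H = 4.

Out of scope: circuits of more than two genes, transcription/translation
splitting, delays, adaptive or implicit integrators, Langevin dynamics,
least-action path computation, and probabilistic (master-equation-derived)
pseudo-potentials.

## Quasi-potential

For a gradient system one could write the rates as `−∇V`; these circuits
fail the cross-partial condition `∂f/∂y = ∂g/∂x` (exposed as
`gradient_condition_residual`), so no closed-form potential exists. The
quasi-potential is instead accumulated along trajectories: with explicit
Euler steps `Δx = f Δt`, `Δy = g Δt`,

    ΔV_q = −(f Δx + g Δy) = −(f² + g²) Δt.

`V_q` is therefore non-increasing along every trajectory, stationary exactly
at fixed points, and acts as a Lyapunov function. The integrator is
deliberately the plain Euler scheme that defines the increment — a
higher-order solver would compute a different path integral than the
defining sum.

Integrator parameters (`IntegratorConfig`):

* `dt = 0.01` time units. Halving it changes accumulated drops by < 1% for
  both presets (checked in tests), and never changes basin assignment.
* convergence: `|ΔV_q| < v_tol = 1e-12` per step, with a secondary stop at
  rate norm `< 1e-6`. With the defaults the v_tol stop triggers first, at a
  rate norm ≈ 1e-5, leaving endpoints within ~1e-5 of the attractor.
* `max_steps = 5e6` budget; a state norm above 1e6 aborts with an error
  (production is bounded, so the presets cannot actually diverge; the guard
  protects user-supplied parameter sets).
* `V_q` is accumulated every step regardless of sample recording; recording
  may be strided and/or decimated to a minimum spacing in state space.

## Fixed points and basins

Roots of `(f, g)` are located by scipy's hybrid Newton method (analytic
Jacobian) from a seeded uniform scatter of 300 starts over a 10%-margin
superset of the forward-invariant box `[0, (B + Σfold)/deg]²`, then polished
by plain Newton iteration to machine precision, deduplicated with a merge
radius of 1e-4, and classified by Jacobian eigenvalues (threshold 1e-8 on
real parts; nearer-zero cases are reported as `degenerate`, not guessed).
Stable points get integer labels in lexicographic (x, y) order; the
lineage aliases A (y-dominant), B (x-dominant) and C (progenitor, most
diagonal) are assigned in the experiments layer. Basin assignment
integrates the deterministic flow and matches the endpoint to a stable
point within 1e-3; anything else returns an explicit `UNASSIGNED` sentinel.

A noteworthy property of the symmetric tristable preset: summing the two
rate equations gives `d(x+y)/dt = 20 − (x+y)` exactly, so the dynamics
collapse onto the line x + y = 20, and n_H = 2 is *exactly* the fold
bifurcation of the two off-diagonal attractors. At n_H = 2 the side states
are degenerate ghosts: their classification is at the numerical threshold,
trajectories approach them only algebraically, and analyses treat "basin
retention" there as zero. The Hill-coefficient trend analyses therefore
quantify barriers over n_H ∈ {3, 4, 10} while occupancy trends span
{2, 3, 4, 10}.

## Landscape construction

One trajectory is launched from each node of a regular start grid (default
41×41 over `[0, 1.2·(B + Σfold)/deg]` per axis). Recorded samples are
decimated to half a start-grid cell of minimum spacing to condition the
triangulation. Each converged trajectory carries the drop still remaining
to its attractor as a relative elevation. Basin offsets `c_b` come from two
continuity rules: (i) trajectories of one basin share their terminal level
(satisfied by construction); (ii) 4-neighbor start pairs straddling a
separatrix share their initial level — one linear constraint per pair,
solved in least squares over *all* such pairs, with offsets then shifted so
the deepest attractor sits at elevation 0. Residuals of rule (ii) scale
with local speed × grid spacing and shrink under grid refinement (checked:
median residual at 81×81 < at 41×41 < at 21×21 for the tristable preset).
A disconnected basin adjacency graph is an error, not a silent guess.

The surface is a piecewise-linear interpolation (Delaunay triangulation of
all decimated trajectory points) sampled on a regular grid (default
201×201); nodes outside the convex hull of the data are masked invalid.
Each valid node also carries the basin of its nearest trajectory point,
defining discrete basin boundaries.

* **Barriers**: for basins a, b, every 4-neighbor node pair with labels
  {a, b} is a boundary crossing at the midpoint elevation of the two nodes;
  the barrier a→b is the minimal crossing level minus attractor a's
  elevation, floored at 0 (interpolation noise can push the ridge a hair
  below a near-zero-depth attractor). If a and b share no boundary the
  error names the intervening basin(s) — e.g. the two differentiated basins
  of the tristable circuit touch only through the progenitor basin.
* **Minima detection**: strict grid minima of a piecewise-linear surface
  include shallow sawtooth pits along slow-manifold grooves. Minima are
  therefore ranked by topological persistence (merge depth under an
  ascending sweep with union-find); measured on both presets, genuine
  attractor valleys persist ≥ 3.4% of the elevation range while artifacts
  stay ≤ 1.0%, so a 2% relative threshold separates them with margin.
* **Cell overlay** (`elevation_at`): elevation at an arbitrary point is the
  inverse-distance interpolation between the two nearest trajectory
  samples — the rule used to place stochastic cells on the surface. It is
  coarser than the triangulated surface (cross-method agreement: median
  within 1%, 95th percentile within 3% of the elevation range), so
  monotonicity checks along trajectories allow it 2% transient slack where
  the surface gets 1%.

## Stochastic simulations

Each circuit doubles as a four-channel jump process on molecule counts:
per gene, one lumped production channel with propensity
`Ω · production_rate(counts/Ω)` and one degradation channel with propensity
`deg · count`. The direct-method SSA kernel draws exponential waiting times
from the total propensity and picks channels proportionally; an
all-zero-propensity state returns early with an `absorbed` flag. The system
size defaults to Ω = 1 — dimensionless concentrations read directly as copy
numbers, the regime in which intrinsic noise drives fate switching — and is
exposed for thermodynamic-limit checks (at Ω = 100 final states concentrate
at the deterministic attractors).

Populations run `n_cells` independent realizations with per-cell seeds
derived from the master seed via `numpy.random.SeedSequence`, so results
are independent of execution order. Final counts are basin-labeled by
integrating the deterministic flow from the scaled counts. Display jitter
(uniform on [0, 0.5) per coordinate by default, with a centered (−0.5, 0.5)
alternative) is applied only to exported copies; it exists because counts
are integers and co-located cells would otherwise overprint.

Exactness oracles: the one-gene reduction with constitutive production
matches its Poisson stationary law (χ² at 1e5 spaced samples), and a pure
death process matches the exponential decay of its expectation.

## Experiments and study conditions

Sweep experiments share one master seed across all sweep points (common
random numbers), start populations at attractor B, and default to the
scaled-down profile of 200 cells to t = 1000 — chosen to keep the full
analysis on a laptop-scale budget while leaving all trends far from their
decision boundaries; the full-scale profile (1000 cells to t = 10,000) is a
flag away.

* **Hill sweep** (n_H ∈ {2, 3, 4, 10}): retention of the initial basin is
  monotone non-decreasing (measured 0 → 0.46 → 0.88 → 0.995 at seed 1) while
  the escape barrier from B grows 10.2 → 15.1 → 31.1 over {3, 4, 10};
  attractor positions meanwhile move by < 10% of their separation.
* **Basal shift** (B_Y: 0 → 4 at n_H = 10): basal input 4 alone reaches
  gene y's autoregulation threshold (K_D = 4), which not merely
  destabilizes but annihilates the x-dominant attractor; the y-dominant
  attractor A deepens by ≈ 36 quasi-potential units relative to the
  surviving alternative, and the whole population rolls into A.
* **Occupancy–elevation rank**: the symmetric preset ties A and B, so the
  long-run inverse rank between elevation and occupancy is demonstrated on
  a mildly fed circuit (B_Y = 0.5, n_H = 3, t = 2000), whose three
  attractors have strictly distinct elevations and moderate barriers that
  allow equilibration within the simulated horizon.

## What the synthetic conditions do and do not show

All inputs are the circuit presets themselves; there is no external data.
The SSA populations emulate intrinsic expression noise only — no extrinsic
noise, cell division, or parameter heterogeneity — and Ω = 1 makes that
noise large by construction. Passing tests therefore demonstrate the
internal consistency of the landscape construction and its predicted
elevation/occupancy relationships for these circuit models, not the
calibration of any particular biological system.

## Known limitations

* The landscape is defined per circuit parameterization; it is a family of
  surfaces, not a static object, and comparisons across parameter sets rely
  on the shared pinning convention (deepest attractor at 0).
* The quasi-potential is a Lyapunov function, not a physical potential or
  a large-deviation action; barrier heights rank transition difficulty but
  do not by themselves give Kramers-type rates.
* Rule-(ii) alignment is least-squares at finite grid spacing; residuals
  vanish only in the refinement limit.
* Near degenerate (fold) parameter values, stability classification and
  basin assignment are intrinsically ill-posed; the package reports
  degenerate/unassigned rather than guessing.
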
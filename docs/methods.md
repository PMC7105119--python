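# Methods

`hybridgrid` is a desk-scale library for hybrid models: discrete agents
(cells) coupled to continuous concentration fields (drugs, nutrients) on a
shared lattice. This note documents the models and numerics behind each
component, the choices made where the design was genuinely open, and what
the shipped tests do and do not establish.

## Lattice conventions

Every spatial container shares one flattened-index convention,
`i = x * yDim + y` (C-order of an `(xDim, yDim)` array), declared once in
`hybridgrid.lattice` and tested by exhaustive round trips. Wrapping
(periodicity) is per-axis and off by default; the worked tumor model lives
on a bounded domain.

Neighborhoods are ordered offset sets plus a reusable output buffer:
`map_hood` writes the flattened indices of in-bounds (or wrapped) offsets
and returns the count, preserving offset order. `circle_hood(r)` uses the
inclusive comparison `dx^2 + dy^2 <= r^2`; at `r = 10` it contains 317
lattice points, which is also the seed population of the worked tumor.
Hex neighborhoods use offset coordinates with even rows shifted half a
cell left of odd rows; triangular cells alternate up/down by parity of
`x + y`. Both conventions are arbitrary but documented and fixed; parity
is resolved at mapping time from the center coordinates.

## Random source

All stochasticity flows through `RandomSource`, a seeded PCG64 generator
(numpy) with the samplers spatial models need. The reproducibility
contract is: one seed fixes the entire draw stream for a given library
version — not any particular bit pattern. Scalar uniforms are served from
pre-drawn blocks of 4096 for speed; the stream remains a pure function of
the seed.

`binomial(n, p)` must stay correct up to populations of ~9e18 (the
population lattices store int64 counts). Below `2^40` trials it delegates
to the exact generator; above, it uses a rounded normal approximation
(mean `np`, variance `np(1-p)`, clipped to `[0, n]`), falling back to a
Poisson limit when `np(1-p) < 1e6` because `p` is extreme. At the
threshold the skewness correction term is of order `1/sqrt(npq) ~ 1e-6`,
far below anything a simulation can resolve. `multinomial` is implemented
as sequential conditional binomials; probabilities may sum to less than
one, with the remainder an implicit "stay" category — the convention the
population lattice wants, where unmoved individuals simply remain.

## Agent containers

An `AgentGrid` is two coupled structures: an ordered agent list (drives
iteration) and a per-position occupancy index (drives spatial queries).
Key behaviors, all enforced by tests:

* **Snapshot (birth-exclusion) iteration.** A sweep visits exactly the
  agents alive at sweep start, minus any disposed before being reached;
  agents born mid-sweep wait for the next sweep. Implemented by freezing
  the list length when iteration begins. This is what makes
  `for cell in grid: cell.divide_maybe()` safe against runaway
  proliferation loops.
* **O(1) disposal with slot tombstones.** Each agent records the index of
  its list entry; disposal nulls that slot. Tombstones are compacted
  outside active sweeps. (Tombstoning by a liveness flag alone is wrong:
  a recycled object is alive again while its old entry still sits in the
  list, and gets visited twice.)
* **Object recycling.** Disposed agents go to a pool and are returned by
  the next creation call, so objects ever constructed never exceeds the
  peak population. Recycled agents keep stale user-defined fields — the
  caller re-initializes what it uses. This mirrors how object-pooling
  agent frameworks behave and is deliberately not hidden.
* **Occupancy discipline.** Unstackable grids refuse a second occupant
  (defensive `OccupancyError`); stackable positions keep first-in order.
  Moves update agent coordinates and the occupancy index atomically, and
  an illegal move leaves the state untouched.

Off-lattice agents (`PointAgent`, `SphericalAgent`) live at continuous
coordinates but are indexed by the unit cell containing them, so radius
queries scan only the `ceil(r)`-neighborhood of buckets (wrap-aware).
Spherical agents implement overdamped adhesion-repulsion mechanics:
`sum_forces` accumulates `forceLaw(overlap)` along center-to-center unit
vectors (coincident centers get a random direction), and
`integrate_motion` scales velocity by a friction factor and advances one
unit step, clamping at non-wrapping walls with the wall-normal velocity
zeroed. The force law is caller-supplied; the shipped default is a linear
spring with an optional constant adhesion offset, because only the
qualitative relax-to-contact behavior is contractual. Tests assert
Newton's third law on pairs and relaxation of an overlapping colony to
pairwise contact within tolerance.

## PDE fields

`PDEField` holds committed values plus a pending-delta lattice. All
operators (point reactions, diffusion, advection) schedule deltas;
`update()` commits everything simultaneously, with point `set` overriding
accumulated adds at the same position (applied last). This is what lets
hundreds of agents take up drug "at the same time" without order effects.
Scheduled `mul(i, v)` deltas are computed from the committed value, so two
muls in one tick scale by `(1 + v + w)`, not `(1+v)(1+w)`.

Rates are dimensionless per step per lattice-unit²; callers do physical
scaling (the tumor model converts 0.02 um²/s to 0.36 per tick).

* **Explicit diffusion**: forward Euler, 2nd-order central stencil;
  stability bound `rate <= 1/(2*ndim)` enforced with a `StabilityError`
  (0.25 in 2D). Boundary families: zero-flux (mirror ghost), Dirichlet
  (constant ghost), periodic (wrap ghost).
* **ADI diffusion**: Peaceman–Rachford in 2D — half-step implicit in x
  with y explicit, then the reverse — unconditionally stable, so it
  carries the tumor model's rate 0.36 (above the explicit bound).
  One-argument form uses reflective borders (or periodic when the field
  itself is periodic); the two-argument form uses a Dirichlet border
  value that diffuses in from the domain edge. Tridiagonal systems have
  constant coefficients and are solved by a Thomas sweep vectorized
  across rows; periodic systems via Sherman–Morrison. The solver is
  cross-checked in tests against an independent banded LU
  (`scipy.linalg.solve_banded`) and a dense solve. In 1D the "ADI" step
  degenerates to two implicit half-steps (backward Euler), which keeps
  the unconditional-stability and conservation contracts. Reaction
  deltas accumulated by agents commit only at `update()`, between full
  ADI steps, never inside a half-step.
* **Advection**: first-order upwind with cell-centered velocities
  (incompressible form; CFL bound `max|vx| + max|vy| <= 1`), and a
  flux-form finite-volume upwind scheme with face-centered velocities
  (compressible form). The flux form telescopes, so mass conservation is
  exact to rounding under periodic or closed (zero-normal-flux) borders;
  with uniform velocities it reduces algebraically to the incompressible
  scheme, and both facts are tested. At CFL = 1 with uniform velocity
  under periodic borders the upwind update is an exact lattice shift.

Conservation under zero-flux/periodic holds to ~1e-14 relative per step
for both diffusion schemes because the discrete operators have zero
column sums; the suite checks drift below 1e-10 over 1000 steps.

## Population lattices

`PopulationField` stores an int64 count per position — homogeneous
populations instead of agent objects, usable up to ~9e18 individuals per
cell. Events are binomial draws over the *committed* counts (never over
freshly arrived individuals — the population analogue of birth-exclusion),
scheduled as signed integer deltas and committed transactionally:
a commit that would drive any count negative is rejected whole. Because
deltas are integers and transactional, simultaneous emigration between two
positions is well-defined.

`distribute` multinomially scatters one position's count over a mapped
neighborhood (remainder stays); `distribute_all` is the vectorized
whole-lattice version (one multinomial array draw per call) used for
migration dynamics at scale; `shift_state` moves a binomial draw between
two parallel fields at one position (mutation, phenotype switching).

**The PDE bridge.** Symmetric von-Neumann migration with per-neighbor
probability `q` has ensemble mean exactly equal to the explicit diffusion
scheme at rate `q` — the bridge between stochastic populations and PDE
densities. The shipped check runs 100 replicates of 1e6 individuals on a
51x51 lattice for 100 steps (migration probability q = 0.2 per neighbor,
a strong-migration setting chosen once) and compares the ensemble mean to
`diffusion_explicit(q)` position by position. Two statistical points
matter and are handled explicitly rather than hidden in a loose
tolerance: the sample standard error degenerates to exactly zero wherever
no replicate ever held an individual (while the PDE predicts a small
positive number), so the SE used is the sample SE with a model-based
Poisson floor `sqrt(pde/reps)`; and with 2601 positions a correct sampler
exceeds 3 SE at ~7 of them by order statistics, so the everywhere-bound
is placed at 5 SE plus a two-individual discreteness allowance
(family-wise alpha ~ 0.001) with the 3-SE exceedance fraction checked in
aggregate (expected 0.27%, asserted <= 1%).

A worked population-lattice tumor with carrying capacity 100,000 per
position, turnover, migration and two driver mutations at 2e-6 per
division ships as `examples/population_tumor.py`. Its per-step event
order is: deaths, then divisions capped by the local carrying capacity,
then mutation shifts drawn from this step's divisions, then migration.
Growth and turnover rates there (division 0.10-0.17/step by genotype,
death 0.05, migration 0.05) are illustrative: the example demonstrates
rare-event dynamics and sector formation, and only conservation and
qualitative properties are asserted about it.

## Toolkit

* `prob_scale(p, d) = 1 - (1-p)^d` converts a per-unit-time event
  probability to the probability of at least one event in duration `d`;
  it satisfies the composition law
  `prob_scale(p, a+b) = 1 - (1-prob_scale(p,a))(1-prob_scale(p,b))`
  (property-tested to 1e-12), which is why per-day rates can be rescaled
  to per-tick probabilities without changing daily expectations.
* Colors pack as 24-bit `0xRRGGBB` integers with clamping; the heat
  colormap ramps black → red → yellow → white in thirds (one channel per
  third). Only the endpoints and monotone luminance are contractual; the
  stops are this library's choice.
* ODE integrators: forward Euler, classic RK4, and embedded
  Runge–Kutta–Fehlberg 4(5). RKF45 keeps the per-step 4th/5th-order error
  estimate (max norm) below `tol` using the standard controller
  `dt_new = 0.9 dt (tol/err)^(1/5)` clamped to `[dt/4, 4dt]`, raising on
  step underflow below 1e-14. Accepted states use the 5th-order value.
  Tests pin RK4's observed global order (>= 3.8 on `y' = y`) and RKF45's
  efficiency at matched accuracy.
* `LineageTracker` records clonal phylogenies for branching processes:
  nodes carry live-population counters; pruning removes extinct nodes
  with no living descendants (iterating until a fixed point, so extinct
  chains collapse); the surviving tree exports as Newick with quoted
  integer ids and branch lengths in generations. The pruning rule is this
  library's declaration, chosen so that the retained tree is exactly the
  genealogy of the living.

## Output and rendering

`DelimitedWriter` is a thin line writer (closed writers reject writes).
`Raster` is a logical grid of packed colors with integer magnification at
export; the origin convention — fixed once for the whole library — is
top-left with y increasing downward. PNG and animated GIF are written via
Pillow and round-trip pixel-exactly (both formats are lossless here).
`tick_pause` provides wall-clock pacing for a live view and is a no-op in
headless mode (the default); pacing never enters numerical results.

## The competitive-release experiment

The worked model couples an unstackable 100x100 cell lattice to a drug
PDE field. Constants (quoted per day, rescaled to two-hour ticks with
`prob_scale`): sensitive division 0.5, resistant division 0.2, baseline
death 0.02, drug-induced death 0.8 at unit concentration (sensitive cells
only), drug uptake 0.03/day of local concentration per occupied cell,
drug diffusivity 0.02 um²/s → dimensionless ADI rate 0.36 with the 20 um
spacing, boundary value 1.0. Treatment starts at day 20 with a 15-day
cycle; the window length distinguishes the arms: 0 (no drug), 200 ticks >
180-tick period (constant), 24 ticks = 2 days (pulsed).

Each tick: shuffle iteration order; every cell takes up drug, draws death
(baseline, plus `drug * drug_death` if sensitive), then division
(phenotype-specific), placing one daughter of inherited type on a
uniformly chosen empty Moore neighbor (mother stays put); then the drug
field takes one ADI step — Dirichlet borders while the treatment window
is open, reflective otherwise — and commits together with the uptake
deltas. The window test uses the truncated remainder of
`tick - drug_start` by the period, strictly inside `(0, duration)`, with
an explicit `tick > drug_start` guard so no dosing can occur before day
20 regardless of remainder semantics. The rng draw order (death draw,
division draw, neighbor choice; one uniform per seeded cell at
initialization) is pinned so a seed fixes the trajectory byte-for-byte.

`model_step` contains an inlined copy of the per-cell logic with lookups
hoisted out of the loop (~4x faster); a regression test holds it and the
public `cell_step` path to identical trajectories from one seed.
`run_experiment` renders the side-by-side raster only on snapshot ticks
(every 10 simulated days by default, named `ModelsDay<d>.png` with the
day from the floor of `tick * timestep`); a per-tick live view is a GUI
concern this headless library does not have.

**Observed dynamics.** From 317 seeded cells (each resistant with
probability 0.5), the untreated arm fills 90% of the lattice around day
43. Constant dosing crashes the sensitive population toward a nadir
around day 200 (total ~2300 of 10⁴, resistant fraction ~0.40) and then
regrows as pure resistant disease, overtaking the pulsed arm near day
270-300 and saturating the domain by ~day 350. Pulsed dosing holds the
tumor near ~6500-7000 cells with a resistant fraction of only ~0.02 at
day 200 — the sensitive population is repeatedly knocked down but kept
alive to suppress the resistant clone spatially, so from roughly day 300
onward the pulsed arm carries the lowest burden of the three: competitive
release under constant therapy, suppression under pulsed therapy. Note
the ordering at the day-200 snapshot specifically: the constant arm is at
its nadir there and is briefly the *smallest* arm; pulsed superiority is
a long-horizon statement, and the test suite asserts both the day-200
state and the day-400 crossing explicitly.

**Problem sizes in the suite.** The test and acceptance runs execute the
experiment at full spatial scale (100x100) to day 200 (2400 of the 10000
ticks) over five seeds, plus one seed to day 400/500 for the long-term
ordering; the full 10000-tick run is the default of `run_experiment` and
the CLI. A spatially scaled 50x50 variant was evaluated and rejected: at
that size the tumor reaches the boundary before treatment begins (day
~18), all arms tie on occupancy, and the treatment contrasts collapse, so
it does not reproduce the experiment's qualitative structure.

## Known limitations

* 3D lattices are supported by the index arithmetic (`GridShape`), but
  neighborhood generators and PDE operators ship in 1D/2D form only.
* Point/sphere mechanics are overdamped and first-order; there is no
  collision resolution beyond pairwise springs, no Voronoi or Potts
  representation.
* Advection is first-order upwind and therefore diffusive near sharp
  fronts; no higher-order limiters.
* The population lattice has no tau-leaping error control and no
  continuous-time (Gillespie) mode; events are per-step binomials.
* `binomial` above 2^40 trials returns a normal (or Poisson-tail)
  approximation; individual-level exactness at that scale is neither
  needed nor resolvable by the models this library targets.
* The synthetic tumor experiment inherits the idealizations of its
  parameterization — immutable phenotypes, space as the only resource,
  drug as the only interaction — so passing tests demonstrate fidelity of
  the simulation machinery, not clinical realism.
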
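# Methods

## Overview

`polariscape` models how tumor-microenvironment (TME) fluctuations drive
macrophage phenotype switching.  The pipeline has three stages:

1. **Boolean regulatory network.**  The molecular basis of polarization is a
   logical network over transcription factors and extracellular signals.
   Synchronous updating makes the dynamics a deterministic map on
   `{0,1}^n`; attractors (fixed points and cycles) are macrophage
   phenotypes and their basins of attraction measure phenotype stability.
2. **Epigenetic (Waddington) landscape.**  Attractors are embedded in the
   plane and aggregated into a potential
   `F(u,v) = min_i a_i [(u-u_i)^2 + (v-v_i)^2]` — one paraboloid well per
   phenotype, its steepness derived from the phenotype's basin size.
3. **Stochastic dynamics.**  The epigenetic state evolves by a stochastic
   reaction–diffusion system whose drift is the (mollified) negative
   gradient of `F` and whose additive noise of magnitude `σ` represents
   the TME.  Basin-to-basin transitions of this process are
   *noise-induced polarization* events.

## Boolean stage

Update rules are AND/OR/NOT expressions over node identifiers, parsed by a
small recursive-descent parser and compiled to bit operations on a packed
state integer.  Updating is synchronous: attractors and basin sizes are
well defined and exact.  Exhaustive enumeration iterates all `2^f` states
of the free (non-clamped) nodes with memoization and is capped at 24 nodes;
beyond that a seeded sampling mode estimates basin fractions as sample
proportions.  Clamps (overexpression = 1, knockout = 0) override a node's
rule at every step; perturbation scans recompute attractors per clamp and
classify each phenotype's basin change as increased / decreased / minimal
(default threshold 5% of the wild-type fraction) / disappeared / novel.

Cycle attractors are canonicalized by rotating the lexicographically
smallest state first.  For phenotype labeling, a node in a cycle counts as
active if it is ON in **all** cycle states (default) or in **any** state
(option); the compartment conditions (M1, M2a, M2b, M2c, M2d) are logical
expressions over node activities, and a label is the concatenation of all
active compartments in fixed order, `M0` if none.  In the default
compartment table, M1 is `NFKB OR STAT1 OR (TNFA AND AP1)` and M2d is
`(TLR4 AND A2A) OR HIF1A`; both readings resolve an ambiguity in the
prose-style phrasing of the conditions in favor of the mechanistic
descriptions (either STAT1 or NFκB suffices for M1; M2d needs the
adenosine/TLR4 co-stimulus or HIF1-α).

A note on the ring fixture: a one-negation ring under synchronous update
is a *bijection*, so its state space decomposes into disjoint cycles, each
equal to its own basin; there is no single attractor covering all states
and no fixed point.  Tests assert exactly that.

## Landscape stage

Attractors are embedded with t-SNE (cycles enter as their mean bit
vector), per-phenotype centers are the centroids of that phenotype's
attractor coordinates, and steepness comes from a registered depth rule
applied to the phenotype's basin fraction: `proportional` (a_i ∝ f_i,
default for user-built landscapes), `inverse` (a_i ∝ min f / f_i) and
`log`.  Coordinates are dimensionless.

The argmin structure of `F` partitions the plane into a multiplicatively
weighted Voronoi diagram; ties classify to the lowest basin index.  The
*mountain pass* of an adjacent pair (i, j) is the minimizer of `F` on
their shared boundary.  For `a_i = a_j` the boundary is the perpendicular
bisector; otherwise it is an Apollonius-type circle of center
`(a_i c_i − a_j c_j)/(a_i − a_j)` and radius `√(a_i a_j) D / |a_i − a_j|`.
The pass is located by dense sampling of the analytic boundary curve,
restricted to the region where i and j are jointly minimal, followed by
successive constrained zooms (the constrained minimum can sit on a triple
point where a third well ties, which an unconstrained polish would miss).
Pass heights increase monotonically in either steepness, since
`h = a_i a_j D^2 / (√a_i + √a_j)^2` on an unobstructed pair.

Spatial clusters of basin centers are found by single-linkage
agglomeration cut at the largest gap of the merge-height sequence — a
parameter-free rule that recovers well-separated groups.

### A consequence of depth-free wells

All wells of `F` bottom out at 0, so the barrier between two basins is the
same seen from either side.  Escape-rate asymmetry between phenotypes
therefore comes from the *prefactor* of the Kramers rate
(`rate ∝ ω_well ω_saddle exp(−2ΔF/σ²)`, `ω_well = 2a`): shallow wide wells
(small `a`) are exited slowly and hold the bulk of the stationary mass
(occupancy ∝ 1/a for wells that contain their Gaussian spread).  For the
packaged reference landscape this motivates the `inverse` depth rule:
phenotypes with the largest Boolean basins get the widest, most retentive
wells, which realizes the intended behavior — macrophages captured by the
large pro-tumoral basins — in the actual stochastic dynamics.

## Mollification

The drift uses `F_ε = F * k_ε`, the convolution of `F` with a gaussian (or
bump) kernel of radius ε, which removes the gradient kinks on basin
boundaries.  Evaluation combines three routes that agree on their
overlaps:

* **Closed form** wherever the kernel ball around the query point stays in
  one basin (checked by a sufficient inequality per well): gaussian
  smoothing of a paraboloid is exact, `F_ε = a r² + 2a ε²`, `∇F_ε = ∇F`.
* **Grid + bicubic spline** near boundaries: `F` sampled at spacing
  `h ≤ ε/4`, convolved (`scipy.ndimage.gaussian_filter`, or an explicit
  bump kernel), interpolated with a C² spline whose partial derivatives
  give the drift.  The grid covers the centers' bounding box plus a
  margin; keeping it tight keeps the spline cheap.
* **Gauss–Hermite quadrature** (12² nodes) as a mesh-free fallback for
  queries outside the grid — far afield every point is deep inside one
  basin anyway, so this path is rarely exercised and exact when the ball
  test passes.

Defaults: gaussian kernel; for stand-alone use ε = 0.05 × bounding-box
diagonal; all reference-landscape dynamics use ε = 0.05 landscape units so
that the smallest barriers (≈ 0.03–0.09) are perturbed by ≪ their height
(the kink dip is O(ε·|∇F jump|), the interior lift 2aε²).

## Stochastic integration

The spatially extended model evolves a two-component field
(u(t,ξ), v(t,ξ)) on [0, L] with per-component diffusivities d₁, d₂, the
pointwise drift −∇F_ε, and additive noise of magnitude σ per channel.
Discretization is semi-implicit Euler–Maruyama: explicit drift and noise,
implicit diffusion (tridiagonal solve under Neumann zero-flux boundaries,
FFT solve under periodic ones) — unconditionally stable in the stiff
diffusion part; the explicit drift substep requires
`dt ≤ 0.25 / max_i a_i`, enforced at configuration time.  White noise uses
the standard grid scaling Normal(0, σ²Δt/Δξ) per point per channel;
colored noise is a truncated expansion σ√Δt Σ_k w_k η_k φ_k(ξ) over
orthonormal cosine (Neumann) or Fourier (periodic) modes with configurable
weights, independent across the two channels.

The 0-D reduction (one grid point, no diffusion) is the plain gradient SDE
d(u,v) = −∇F_ε dt + σ dW, used for all ensemble studies.  In a single well
it is an Ornstein–Uhlenbeck process with stationary variance σ²/(4a) per
coordinate — the main integrator oracle.

## Transition observables

Occupancy classifies every grid point of every snapshot into its basin
(the 0-D reduction yields an indicator).  The dominant basin at a time is
the one above a 0.5 occupancy threshold ("mixed" otherwise, emitting no
events); polarization events are changes of the dominant basin between
consecutive dominant snapshots, with the spatial mean field at the flip as
the crossing point.  First-exit times are measured on the dominant-basin
process; censored replicates (no exit by the horizon) are excluded from
means and reported separately.  Crossing points are matched to the
mountain pass of their (source, target) pair; events between basins with
no shared boundary count as unmatched.

## Reference studies (frozen protocol)

* **Stability scan**: start at the M1 center, σ ∈ {0.05, 0.1, 0.15, 0.2},
  200 replicates, horizon 150, dt 0.01.  The exit probability is
  monotone in σ, and at σ = 0.05 the trajectory stays in the M1 basin in
  ≥ 95% of runs (in practice: all of them).
* **Exit-time scaling**: symmetric double well (a = 1, separation 1, pass
  height 0.25), ε = 0.01, σ ∈ {0.30, 0.34, 0.38, 0.42}, 200 replicates,
  dt 0.008, horizon 6000 (no censoring).  The regression slope of
  log(mean exit) on 1/σ² matches 2ΔF = 0.5 within 25%; the residual bias
  is the finite-σ correction to the Freidlin–Wentzell limit plus the
  mollification's small reduction of the effective barrier.
* **Pass localization**: one long double-well trajectory per
  σ ∈ {0.65, 0.5, 0.4}; median crossing-to-saddle distance decreases as σ
  decreases.
* **Itineraries**: σ = 0.27 from M1 (horizon 600) — first event M1→M1M2d
  and M2aM2d visited, majority of 50 replicates; σ = 0.20 from M0
  (horizon 400) — itinerary ends in M2bM2d, majority of 50 replicates.
  Horizons are chosen at the transient sweet spot: long enough for the
  characteristic transitions, short enough that slow leakage toward the
  remaining clusters has not equilibrated.

## The synthetic reference landscape

The packaged 13-phenotype landscape emulates the *topology* of the
macrophage system — 13 named phenotypes in 5 spatial clusters, exactly one
of which ({M1, M1M2d}) is anti-tumoral, with the deep pro-tumoral sink
M2bM2d nearest to the monocyte (M0) valley and the M2aM2d group adjacent
to the M1 valley — and the *asymmetry of stability*: pro-tumoral
phenotypes carry the largest basin fractions, hence (inverse rule) the
widest wells.  Its geometry is a package design artifact: real attractor
coordinates and basin sizes of the published network are not printed in
any source available offline, so passing the itinerary tests demonstrates
that the machinery produces the documented qualitative phenomenology on a
landscape with these topological properties, not that it reproduces the
authors' exact figures.  The two hybrid labels beyond the named eleven are
taken as M2cM2d and M2bM2c and are configurable.

What the generator does not emulate: real attractor geometry from t-SNE of
the published network, state-dependent or multiplicative TME noise,
controls (drugs) acting on drift or diffusion, and spatial heterogeneity
of the noise field.

## Numerical choices and degenerate inputs

* Tie-breaking in basin classification: lowest index.  Coincident centers
  are rejected at landscape construction.
* Exhaustive Boolean enumeration cap: 24 free nodes.
* Mollifier grid spacing ε/4, gaussian truncation 6ε; interior-ball test
  uses the same support radius.
* Stability bound for the explicit drift substep: `dt·2·max(a) ≤ 0.5`.
* Non-finite field values abort a simulation with a step report.
* Zero basin fractions are rejected when sizing wells; empty class sets
  are rejected in perturbation scans.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  trajectory and CLI run stores its full configuration and seed.

## Known limitations

* Synchronous Boolean updating only; asynchronous/probabilistic schemes
  are out of scope.
* The spatial domain is one-dimensional; 2-D/3-D fields are not supported.
* Exit-time asymptotics are validated at the scaling level (slope of the
  exponential), not at the level of absolute Eyring–Kramers prefactors.
* The t-SNE embedding is stochastic-algorithmic: coordinates are
  reproducible per seed but not canonical across seeds; downstream
  statements therefore never depend on absolute coordinates.
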
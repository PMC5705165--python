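# Methods

`actomotion` simulates a minimal mechanical model of lamellipodial cell
motility: a flat cell is a moving 2D domain ω(t) filled with a contractile
actomyosin gel.  This note records the model as implemented, the numerical
scheme, the parameters and defaults, and the design choices made where the
design was genuinely open.

## Model

Inside ω(t), the actin flow **u** and myosin density m obey (dimensionless)

    α Δu + β ∇m − u = 0                        (force balance)
    ∂t m = ∇·( d_eff ∇m − u_eff m )            (myosin transport)

The force balance sets viscous stresses (componentwise Laplacian — the
bulk/shear split is deliberately ignored), the myosin contractile stress
(isotropic, proportional to m), and adhesive drag (linear in **u**) in
equilibrium at every instant.  Myosin is advected by the flow and diffuses;
molecular crowding caps the transport coefficients:

    u_eff = u (1 − m/m_max,u)  for m < m_max,u, and exactly 0 otherwise
    d_eff = max(1 − m/m_max,d, 10⁻⁶)

The diffusivity floor (10⁻⁶) is a robustness guard only: m_max,d exceeds any
density a valid run reaches, and a warning is logged if the floor ever
fires.  Both factors are evaluated per control volume from the cell-average
m, which keeps the hard advection cutoff unambiguous.

Two boundary conditions for the flow define the model variants:

* **ZV** (zero velocity): u = 0 on ∂ω — a narrow band of strong adhesions
  pins the network at the edge.
* **ZS** (zero stress): n·(α∇u + βm Î) = 0 — no sticky band; membrane
  tension is neglected against the contractile and viscous stresses.

Myosin satisfies the no-flux Rankine–Hugoniot condition on the moving edge,
n·(−d_eff ∇m + (u_eff − v_f) m) = 0, so total myosin μ_tot = ∬ m is an
invariant of the dynamics.

The edge moves with v_f = v_p n + u|_∂ω, where the protrusion speed is

    ZS:  v_p = v0·a0/a − k (a − a0 (a0/a)²)          (uniform on ∂ω)
    ZV:  v_p = v0·a0 / (a (1 + m|_∂ω)) − k (a − a0)  (local myosin inhibits
                                                      actin growth; u|_∂ω = 0)

The (a0/a)² term is cytoplasmic resistance: it prevents collapse of the ZS
cell when v0 is small.

### Governing parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | viscosity-adhesion length², η/(L²ξ) | 0.5 | scanned: 0.5, 1 |
| β | contractility constant, σM0/(Dξ) | 5 | fixed; only βm matters, so β can be traded against μ_tot |
| μ_tot | total dimensionless myosin | 1.5π | scanned |
| v0 | actin polymerization constant | 2.5 | scanned |
| k | area-preservation strength | 1.5 | fixed |
| a0 | target area | π | unit circle initial cell |
| g | initial myosin-gradient steepness | 0.2 | any value in (0,1] seeds symmetry breaking; 0.2 is a mild nudge |
| m_max,u / m_max,d | crowding cutoffs | 15 / 125 | fixed |

Lengths are in units of L = √(A0/π) (the radius of the resting cell), time
in L²/D, myosin in M0.  `nondimensionalize` maps dimensional constants to
this set.

Initial condition: unit circle, u = 0, m = (μ_tot/a)(1 − g·x), with the
discrete total rescaled to μ_tot exactly.

### Linear stability (1D ZV reduction)

On a fixed unit segment with crowding disabled, the uniform state
(u = 0, m = μ_tot) admits perturbations ~exp(λt + iqx), q = π, 2π, …, with

    λ(q) = q² ( βμ_tot / (1 + αq²) − 1 ),

so the symmetric state destabilizes when βμ_tot > 1 + π²α, through the
longest admissible wavelength q = π (at extreme βμ_tot the argmax can move
to higher q; `fastest_mode` scans for it).  `stability_1d` also integrates
the nonlinear 1D system and measures mode growth by cosine projection —
cosine rather than complex exponentials because the no-flux walls select
cos(qx) as the real eigenbasis.

## Numerics

### Mesh

A fixed Cartesian background grid (spacing h, lines at integer multiples of
h, lab frame) is cut by the marker polygon of the cell edge.  The polyline
is split at grid lines; face apertures come from the crossing points plus
node in/out parity, and cut-cell volumes and centroids from Green's theorem
over the boundary pieces and face portions.  Everything derives from the
same polygon, so per-cell closure (∮ n ds = 0) holds to round-off — a
uniform myosin field exerts exactly zero net force, and the mesh volume
equals the polygon area to round-off.  Degenerate crossings (curve through
a grid node) are detected by parity/closure checks; the affected cells fall
back to robust polygon clipping.

Cut cells with volume fraction < 0.3 are merged with their best-covered
active neighbour, so implicit solves never see arbitrarily small control
volumes.  Unknowns are cell-averages on these merged groups, collocated at
the volume-weighted centroid of the clipped region — with box-center
collocation the manufactured-solution order measured ≈ 1.5; centroid
collocation restores ≈ 2.

### Spatial discretization

Two-point fluxes between collocation points on shared faces (aperture-
weighted).  Diffusion uses the arithmetic face mean of d_eff; advection is
first-order upwind — robust for the near-singular myosin aggregates the
model produces in low-α regimes; together with implicit time stepping the
transport matrix is an M-matrix and m stays non-negative for any dt.  The
convergence benchmark is therefore run in the diffusion-dominated regime
(advection off), where the scheme's second-order claim applies.

Force balance: each velocity component is a Helmholtz-type problem; the
components couple only through the ZS boundary condition.  ZS is a natural
condition here — the zero-stress identity makes the combined boundary terms
(α ∂u/∂n + βm n) vanish, so boundary segments simply drop out of the
surface integrals.  ZV imposes u = 0 through a ghost flux using the
collocation-to-wall distance projected on the segment normal.  On a 1D slab
oracle this converges with error ratio ≈ 3 per mesh halving (order ≈ 1.6,
2.7% max-norm error at h = 0.1); cut-cell Dirichlet fluxes, not the
interior scheme, are the limiting piece.

Boundary values of m (for the ZV protrusion law and contraction term) and
u (for the ZS edge velocity) are extrapolated by a bilinear fit through the
nearest fully interior 2×2 cell block, evaluated at the boundary point,
using the actual collocation points of the four groups (exact for affine
fields); points with no complete block within 3h fall back to the nearest
cell value with a logged warning.

### Mass transfer between meshes

When the front moves, the new mesh receives the old cell masses unchanged
where cells stay wet; dried cells donate their entire mass to adjacent wet
cells (volume-weighted) and newly wetted cells draw donor-concentration
mass from their best-covered neighbour.  Total myosin is conserved to
round-off for arbitrary motion.  This keep-mass rule *is* the
Rankine–Hugoniot sweeping term realized geometrically: an advancing edge
dilutes the cut cells it expands, a retreating edge concentrates them, and
no myosin ever crosses the boundary.  The price is that a uniform field
acquires O(front displacement) perturbations in the swept band (smoothed
away by diffusion within a step or two); away from the band uniformity is
preserved exactly.

### Time stepping

Implicit backward Euler with Δt = c·h.  Each step runs the segregated
fixed-point loop: (1) solve the force balance with the previous iterate's
myosin (one factorization per step — the matrix depends only on the mesh
and α; the myosin enters the right-hand side); (2) evaluate u_eff, d_eff
from that myosin and the new flow; (3) one linear transport solve whose
time-derivative anchor is the previous *time step's* myosin; (4) stop when
both sup-norm iterate differences fall below 10⁻¹⁰ (default), cap 35
iterations; hitting the cap raises a stagnation error naming both
residuals.  Typical counts are 6–9 iterations per step at tolerance 10⁻¹⁰.
Only after convergence does the boundary move: v_p from the converged area
and myosin, edge flow by extrapolation (ZS) or zero (ZV), markers advanced
by Δt·v_f, curve reparameterized, mesh rebuilt, mass transferred.

Δt is reduced below c·h when the converged boundary velocity violates
either kinematic limit — at most half a background cell of front motion per
step, and at most half a marker spacing of *relative* motion between
neighbouring markers (velocity shear) — and a trial front move that still
self-intersects is rejected and retried at Δt/2.  Fast or violently
polarizing cells therefore take smaller steps automatically.

A monolithic reference solver advances the same one-step nonlinear system
by solving the fully coupled (u_x, u_y, m) linear system per outer
iteration, with crowding and upwind coefficients frozen at the current
iterate, to residual 10⁻¹².  It shares the discretization but not the
linearization or linear algebra, and is used to validate the segregated
loop (observed agreement ~10⁻¹⁰ %, far inside the 0.3% acceptance band).

### Front tracking

The edge is a closed counterclockwise marker polyline (256 markers on the
initial unit circle, spacing ≈ 0.0245 ≲ h/4 for the meshes used).  After
each move the curve is reparameterized to uniform arclength with a periodic
cubic spline; the marker count tracks the perimeter so spacing stays near
target.  Resampling is idempotent on an equispaced curve to round-off and
the area drift per call is far below the 10⁻³·a budget.

Normal-speed protrusion amplifies marker-scale zigzags (wavelength = one
marker spacing, far below h) into folds that the continuous model does not
have — the model itself has no short-wavelength shape instability.  Markers
whose discrete turning angle exceeds 45° (resolved shapes stay below
~15–30°/marker even in high-curvature rotating states) are locally averaged
with their neighbours before resampling.  The trigger is event-based:
smooth stretches of the curve are never touched, so no cumulative smoothing
of resolved shapes occurs.  Self-intersection that survives the Δt control
is a hard topology error — the model has no splitting/merging rule.

## Trajectory analysis

The per-step record (centroid, area, aspect ratio = max/min
centroid-to-boundary distance, total myosin, iteration counts) is
downsampled to 0.1-time-unit strides for speed estimates.  A run is
*steady* from the earliest time after which the trailing 5-unit-window
**means** of centroid speed and aspect ratio stay within 2% of their
end-of-record values, continuously through the end of the record (and for
at least 1.5 windows).  Window means rather than pointwise values are
compared because steadily rotating cells carry a few-percent periodic
speed wobble as their shape re-discretizes on the fixed grid; means
average it out while still catching genuine reorganization, and a
transiently quiet phase that later destabilizes (straight motion before
rotation locks in) does not count.  Speeds carry an absolute resolution
floor of 5×10⁻³ cell radii per time unit: below it, centroid creep is
indistinguishable from rest at these resolutions (marker jitter plus
exponentially slow settling), and motile speeds are two orders larger.

Steady runs are classified: *stationary* if the trailing speed is below
max(10⁻² of the historical maximum, twice the floor) and the trailing net
displacement is below 0.1; otherwise *rotation* if an algebraic (Kåsa)
circle fit of the trailing track has radius ≤ 1.5·√(a/π) — the operational
reading of "radius comparable to, or less than, the cell size" — with a
straight-line fit preferred when its residual is smaller (radius = ∞);
otherwise *translation*, flagged ambiguous when the fitted radius is within
3 cell sizes (slow turning and straight motion genuinely blur there, as the
phase diagrams' caveat notes).  The 1.5 factor and 5-unit window are config
knobs recorded in every run manifest.

## Verification

* Force balance: closed-form 1D slab solution (hyperbolic cosines) for ZV;
  modified-Bessel radial solution for the ZS disk with uniform myosin
  (inward rim flow); linearity, β-rescaling invariance, exact quarter-turn
  equivariance.
* Transport: exact mass conservation and positivity under random fields;
  convergence to an independent axisymmetric radial solver; uniform-state
  equilibrium; relaxation to the uniform steady state.
* Manufactured solution m = 1 + e⁻ᵗ(1 − r²)² on the disk (no-flux
  compatible): observed L² spatial order ≈ 2.0 over h = 0.16/0.08/0.04,
  with dt = c·h² so the backward-Euler error stays subdominant (halving dt
  moves the order estimate by < 0.1).
* Coupled stepping: segregated vs monolithic agreement; exact preservation
  of the below-threshold symmetric fixed point (v0 = 0, a0 set to the
  discrete polygon area so v_p vanishes identically); bitwise determinism;
  mirror-symmetry equivariance to ~10⁻⁵ (round-off asymmetry amplified by
  the physical instability); myosin conservation to 10⁻¹⁰ relative over
  full runs.
* 1D stability: dispersion relation against a finite-difference
  linearization eigenvalue (1%), nonlinear growth/decay rates against λ(q)
  (5%), threshold sign flips on a parameter grid.

## Problem sizes and study conditions

Default production resolution is h = 0.16, c = 0.01 (Δt = 1.6×10⁻³), the
coarse end of the supported range h ∈ [0.05, 0.16], c ∈ [0.0002, 0.025];
fast-moving or rotating cells need h = 0.10–0.12 because their myosin
aggregates and high-curvature edge segments are under-resolved at h = 0.16
(at the coarse mesh the rotation-range cell meanders as a "piecewise
unidirectional" state instead of locking into a circle).  The test suite
runs the coarse resolutions with early stopping once steadiness has
persisted for a margin; the acceptance script uses the per-quantity setups
documented in its header.

## Known limitations

* The ZV Dirichlet flux on cut cells limits the force-balance convergence
  to order ≈ 1.6 in the max norm (the transport scheme is the one with the
  order-2 contract, and meets it).
* First-order upwinding smears sharp myosin aggregates at coarse h; regimes
  whose classification depends on aggregate sharpness (rotation near the
  translation boundary) shift at h = 0.16.
* The heading of a translating cell is marginal (any direction solves the
  equations), so round-off asymmetry, amplified through the transient,
  eventually steers fast cells off their initial axis, and the coarse
  background lattice weakly prefers grid-aligned/diagonal headings.
  Mirror-symmetry equivariance therefore holds pointwise only until noise
  amplification (a few time units at h = 0.16); speeds and shape metrics
  are unaffected.
* The synthetic trajectory generators used in classifier tests emulate
  clean kinematics (exact circles/lines plus Gaussian noise); real
  trajectories wobble coherently, which the steadiness window handles but
  the noise-model tests do not probe.
* No topology changes, no 3D, no membrane-tension term in the ZS stress
  balance, no stress-attenuation crowding variant, single-state myosin
  kinetics only.
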
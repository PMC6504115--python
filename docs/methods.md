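# Methods

`ibmem` simulates the fluid-filled gap between two nearly-touching cell
membranes — the geometry of a nascent cell–cell contact, tens of
nanometers thick and hundreds of nanometers to microns wide — and asks
how long it takes the two surfaces to come within receptor–ligand
binding range. Because the gap is so much thinner than it is wide,
squeezing it shut requires evacuating incompressible fluid sideways
through a thin film: the lubrication (thin-layer) effect. The package
has two layers: a stochastic immersed-boundary simulator of the coupled
membrane–fluid system, and a reduced Ornstein–Uhlenbeck (OU) layer that
turns simulated receptor-site fluctuations into mean first-passage
times (MFPTs) to proximity via Weighted Ensemble (WE) rare-event
sampling.

All internal arithmetic is in nm / µs / pN. In these units
η_water = 10⁻³ Pa·s is 10⁻³ pN·µs/nm², ρ_water is 10⁻⁹ pN·µs²/nm⁴, and
a permeability quoted in nm/(s·Pa) is numerically equal to its internal
value. kBT defaults to 4.1 pN·nm.

## Membrane model

Each cell surface is an elastic disk of radius `r_cell`, triangulated
on concentric rings with near-uniform edge length, carrying:

* **Bending energy** Φ_bend = (κ_B/2) Σᵢ Hᵢ² Aᵢ with the convention
  H = κ₁ + κ₂ (so H = 2/R on a sphere and the closed-sphere energy is
  8πκ_B). H is discretized by the cotangent Laplacian. We use lumped
  (one-third barycentric) vertex areas rather than mixed Voronoi areas:
  the two agree at the mesh sizes used, and the lumped form admits a
  tractable *exact* analytic gradient. Boundary-loop vertices carry no
  bending term; the rim is controlled by tension, tethers and soft
  rim anchors (below).
* **Tension energy** Φ_tension = σ₀ Σ_f ((A_f − A₀_f)/A₀_f)² A₀_f — a
  per-face area penalty with the surface-tension constant σ₀.
* **Shear regularizer** — harmonic springs on mesh edges at their rest
  lengths with small stiffness `k_shear` (default 0.02 pN/nm). This is
  a numerical device that keeps the triangulation well-shaped without
  remeshing, not a physical in-plane elasticity; the default keeps its
  energy far below the bending energy for the deformations we observe.
* **Nonspecific adhesion tethers** — Hookean springs of stiffness
  `k_adh` and rest length `dz_inf` on every vertex with in-plane radius
  greater than `r_free`, the adhesion-free zone around the receptor.
  The tethers act in full 3D (the molecules they idealize resist
  stretching in any direction); their anchors are fixed "ghost" points
  for single-membrane runs and the paired vertex of the opposing
  membrane for interface runs. `k_adh` defaults to 1 pN/nm: stiff
  enough that tether extension stays ≪ dz_inf under the forces studied,
  soft enough not to dominate the explicit-coupling stability limit.
  For thermal-undulation studies the `inextensible_tethers` option
  instead immobilizes the tethered vertices outright — the idealization
  of the adhesion molecules as rigid spacers. This matters twice over:
  finite-stiffness tethers soft enough to be affordable add a spurious
  slow collective mode to the receptor spectrum (the whole tethered
  annulus breathes), and a vertex held *statically* while its elastic
  force is spread into the fluid would stir the fluid with energy from
  nowhere — so immobilized vertices are also made phantom to the fluid
  (neither spread nor advected).
* **Rim anchors** — the boundary loop is tied to its initial position
  by soft springs (`k_rim`, default 2 pN/nm) standing for the
  continuation of the cell surface beyond the simulated patch; for the
  interface pair these are what fix the system in the lab frame. They
  enter the energy like any other spring (a hard positional clamp is
  *not* used: resetting advected vertices each step does work on the
  fluid and was observed to pump energy steadily).
* **Active force** — a total force `F_active` split equally over the
  vertices within radius `a_force` of the center, directed at the
  opposing membrane. The loaded set always includes at least the
  receptor's one-ring (7 vertices on the ring mesh), so a force disk
  smaller than one edge length is still resolved.

Forces are the exact negative gradient of the total discrete energy
(discretize-then-differentiate), assembled analytically and verified by
central differences at 10⁻⁵ relative tolerance in the tests. Exactness
matters: it guarantees monotone energy decay in deterministic runs and
a well-defined equilibrium shared by the dynamic and static solvers.

The receptor observable is the z-distance between the central
(receptor) vertices of the two membranes — or the receptor height
relative to its start, for single-membrane runs. Proximity means
separation ≤ `dz_star` (default 20 nm; 13 nm configurable).

## Fluid and coupling

The fluid is incompressible, Newtonian and periodic, solved on a
collocated Fourier grid where the Leray projection and the viscous
operator are diagonal. The Nyquist planes of even-sized axes are
truncated (the projector cannot be made Hermitian-symmetric across
them), and the k = 0 mode is pinned: tether anchors exert a net force
that would otherwise uniformly accelerate the periodic frame.

Thermal forcing is balanced per mode against the discrete viscous
operator so that every retained divergence-free degree of freedom
carries kBT/2 at equilibrium; the tests verify a flat spectrum on 8³
and 16³ grids. Time stepping is a per-mode exact OU ("stochastic
exponential") update. Its essential feature is that the step returns
the pair (u(t+Δt), w = ∫ u dt) sampled *jointly* with the exact Gaussian
statistics of the OU bridge; structures are advected by the
interpolated w. This keeps both equipartition and the structure's
long-time diffusion exact at any Δt, far beyond the fluid's own
relaxation time ρΔx²/η (~10⁻⁴ µs at the default grids) — the property
that makes desk-scale thermal runs feasible at all. A literal
Euler–Maruyama stepper and an inertia-free steady-Stokes
("overdamped") mode exist as a cross-check and as the fast path for
deterministic runs; the low-Reynolds regime makes the overdamped and
inertial deterministic responses indistinguishable.

Membrane–fluid exchange uses the classic 4-point kernel: spreading Λ
(vertex forces → force density) and interpolation Γ (grid fields →
vertex values) are exact adjoints, verified to 10⁻¹². With thermal
forcing on, the kernel-divergence drift term kBT (∇_X·Λ) is included,
computed from the analytic kernel derivative.

**Permeability.** A membrane with surface permeability ψ lets fluid
through at a velocity proportional to the local pressure difference.
In the structure update this appears as a slip velocity
ψ · (F_v / A_v), where F_v/A_v (vertex force over lumped vertex area)
is the discrete pressure difference, plus — when thermal forcing is on
— a slip noise of variance 2 kBT ψ Δt / A_v per component, the
fluctuation–dissipation partner of the slip mobility. ψ = 0 recovers
the no-slip immersed boundary exactly, with no slip noise. (The
printed covariances for both noise terms in the source literature are
typographically garbled; both are fixed here by requiring detailed
balance and verified by equipartition tests, including a tethered
vertex with ψ > 0.)

## Scenarios, scale, and what the desk-scale runs show

The reference ("cluster") configuration — Δx = 5 nm over a 2 µm
domain, Δt = 10⁻¹⁰ s, 1 s of simulated time, r_cell = 1 µm,
r_free = 150 nm, dz_inf = 60 nm, σ₀ = 100 pN/µm, κ_B = 50 pN·nm —
is shipped as config files but is far beyond a desktop. The reduced
test conditions shrink the *aspect ratio* rather than the
amplitude-to-gap ratio: r_cell = 170 nm, r_free = 85 nm,
dz_inf = 40 nm, Δx = 13.3 nm on a 30×30×16 grid, with κ_B scaled to
preserve the tension-to-bending ratio σ₀ r_free²/κ_B of the reference
set (the tension-dominated regime). The gap stays large compared to
the ~6 nm thermal receptor fluctuation, as at the published scale —
shrinking the gap itself instead produces tether-rectification
artifacts with no published counterpart. The tests assert *qualitative
orderings* at this scale, never the published absolute numbers:

* thermal interface separation blisters above dz_inf (entropic
  repulsion) while athermal runs do not;
* the interface autocorrelation needs two exponential timescales while
  the single membrane needs one;
* under an active force the passive membrane is first pushed away
  (incompressibility) and then recovers on the slow drainage timescale;
* the marginal time-to-proximity per nm of extra far-field separation
  falls steeply with dz_inf (the reduced-scale face of the "optimal
  attack distance": full non-monotonicity needs the published aspect
  ratio);
* raising ψ toward the critical scale dz_inf³/(η r_free²) collapses
  interface dynamics toward the single-membrane response.

Equilibrium properties (displacement vs force, tension, adhesion
density) are computed by direct energy minimization (L-BFGS with the
exact gradient): a constant-force equilibrium involves no fluid, and
the tests confirm the dynamic steady state matches the static minimum.

The synthetic geometry omits, deliberately: cortex–membrane adhesion,
electrostatics/van der Waals, osmotic and hydrostatic offsets,
receptor–ligand binding kinetics, remeshing and membrane reservoirs.
Passing tests therefore demonstrate the hydrodynamic mechanism, not a
complete quantitative model of any particular cell pair.

## Reduced OU layer

Receptor-site motion from the fluid simulations is summarized by OU
processes. One component describes the single membrane:
dZ = −Z/τ dt + σ√(2/τ) dW, with stationary SD σ and autocorrelation
e^{−δt/τ}. (The noise amplitude σ√(2/τ) is the unique choice
consistent with both.) The interface needs two timescales: hidden
components X, Y with common variance σ² and times τ_slow, τ_fast
combine as Z = cX + √(1−c²)Y, giving autocorrelation
c² e^{−δt/τ_slow} + (1−c²) e^{−δt/τ_fast}; the slow fraction is c²
(we report both c and c², as the two conventions coexist in the
literature). Reference fitted values from the published-scale runs:
σ₁ = 3.12 nm, τ = 1.05×10⁻⁶ s (single); σ₂ = 4.6 nm,
τ_slow = 8.2×10⁻⁵ s, τ_fast = 5.3×10⁻⁷ s, c² = 0.48 (interface).
Two membranes fluctuating independently with σ₁ each would have
separation SD √2·σ₁ ≈ 4.4 nm — nearly the interface value: confinement
leaves amplitudes almost unchanged and instead slows timescales ~80×.

Simulation uses the exact discretization (stationary variance right at
any Δt). Autocorrelations are computed spectrally; single- and
double-exponential fits use nonlinear least squares with multistart
over log-spaced timescale seeds, a fit window ending where the
autocorrelation first drops below 0.02 (noise-floor guard), a
τ_slow/τ_fast < 3 identifiability fallback, and moving-block bootstrap
CIs (block = 10 fitted slow timescales).

## First-passage estimation

Displacement is measured from the stationary mean toward contact, with
an absorbing boundary at the threshold; no lower boundary is needed
(the OU potential confines). The passage event is one-sided — the
membranes must approach, not merely deviate.

* **Analytic (one-component)**: the standard double-integral mean exit
  time, T = τ√(2π) ∫ e^{u²/2}Φ(u) du, evaluated by log-rescaled
  adaptive quadrature (stable to ≥ 8σ thresholds).
* **Brute force**: vectorized exact-step Monte Carlo, feasible to
  ~2.5σ.
* **Weighted Ensemble**: 30 uniform bins over [start, threshold], 4
  walkers per bin, split/merge resampling every τ_fast conserving total
  weight to 10⁻¹², absorbed weight recycled at the start, MFPT =
  1/(steady-state flux) with the first half of each flux record
  discarded as burn-in, and 10 independent runs for the replicate
  spread (rates are averaged across runs, then inverted).

All discrete-time passage estimators apply the Brownian-bridge
crossing correction exp(−2(b−z₀)(b−z₁)/s²) between samples; without
it, coarse sampling systematically overestimates MFPTs. WE default
Δt = τ_fast/20; replicate MFPTs are combined by averaging *rates*
(1/mean flux), since fluxes average unbiasedly while inverse times
overweight quiet runs. The three routes agree within replicate error
for 1–2.5σ thresholds. For the two-component process no closed form
exists, so the test suite solves the 2D backward (mean-exit-time)
equation by finite differences as an independent oracle; it gives
1.47 s for the reference interface process reaching 25 nm (5.4σ) —
the regime only WE can sample (τ_fast is ~0.5 µs, so this is a
genuinely rare event).

## Numerical choices and limitations

* Time step: deterministic/thermal coupled runs use an explicit
  structure update; the auto-chosen Δt sits a factor ~2 below the
  measured stability boundary of the stiffest vertex mode (springs +
  bending + tension + permeable slip), and thermal runs additionally
  cap the per-step thermal kick at a tenth of a mesh edge. The fluid
  itself is unconditionally stable (exact per-mode updates). Overdamped
  runs are verified to decay the total energy monotonically — the
  property that exposed both the rim-clamp and static-vertex energy
  pumps during development.
* Mesh: one boundary loop, consistent winding, positive face areas are
  enforced; degenerate faces raise errors naming the face.
* Rim clamping idealizes the continuation of the cell surface beyond
  the simulated patch; together with boundary tension it sets the
  far-field boundary condition. Displacements comparable to the patch
  radius would feel this clamp, so scans stay in the regime where the
  displacement ≪ r_cell.
* The fit window and bootstrap parameters matter for noisy, short
  traces; the defaults target traces a few thousand correlation times
  long. Desk-scale fluid traces are shorter than the published-scale
  ones, so fitted c² at desk scale carries wide CIs — the tests assert
  two-timescale *identifiability* and orderings, not the published
  c² value.
* WE flux estimates for very deep thresholds (≫ 5σ) converge slowly in
  run-to-run spread; the shipped defaults target the 4–5.5σ range used
  by the acceptance script (order-of-magnitude agreement).
* Problem sizes used by the test suite and acceptance script (grids
  ≤ ~40³ equivalent, meshes ≤ ~600 vertices, WE budgets of a few
  10⁻² s of reduced-process time) are the package's desk-scale
  defaults; the cluster configs document the published scale.
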
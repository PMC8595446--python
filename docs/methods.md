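# Methods

`fistulaflow` simulates macroscopic blood flow in coupled arterial and
venous vessel networks with the lattice Boltzmann method (LBM), joined by a
0D resistor–capacitor surrogate for the capillary beds that lattice-scale
simulations cannot resolve.  This note records the model, the numerical
choices, what the synthetic fixtures do and do not represent, and the known
limitations.

## Lattice Boltzmann core

**Stencil and collision.**  The solver uses the D3Q19 velocity set with the
standard second-order polynomial equilibrium and a two-relaxation-time
(TRT) collision operator.  Even and odd parts of the non-equilibrium
populations relax with rates `1/τ⁺` and `1/τ⁻`; the rest population relaxes
with `1/τ⁺`.  The two times are linked through the magic parameter
`Λ = (τ⁺ − ½)(τ⁻ − ½)`.  The default is `Λ = 1/12`, which optimises bulk
advection accuracy; `Λ = 3/16` (exact half-way wall placement in straight
channels) is used by the viscosity-recovery test and is selectable in every
run configuration.

**Units.**  A `UnitSystem` carries `Δx` (m), `Δt` (s), the blood density
`ρ = 1000 kg/m³` and kinematic viscosity `ν = 4.0×10⁻⁶ m²/s` (Newtonian;
non-Newtonian rheology is out of scope).  The relaxation time follows as
`τ = ½ + 3νΔt/Δx²`; at the reference discretisation `Δx = 50 μm`,
`Δt = 3 μs` this gives `τ = 0.5144`.  Pressure uses the quasi-incompressible
interpretation `p = c_s²(ρ_lat − 1)·ρ·Δx²/Δt²`.

**Time loop.**  One canonical order, fixed everywhere:
macroscopics → collide → force → stream → boundaries.  Two code paths
produce identical numbers: a plain NumPy reference and a fused
numba kernel used automatically when numba imports (a test asserts
agreement to 1e-15 per population).

**Walls.**  Rigid, no-slip, via the two-population Bouzidi interpolated
bounce-back.  The sub-voxel wall distance fraction `q ∈ [0,1]` is computed
against the *analytic* vessel surface (never the voxelization) by bisection
on the inside/outside predicate of the capped-cone union — 45 iterations,
i.e. ~3×10⁻¹⁴ of the link length.  Bisection was chosen over closed forms
because it handles cone junctions and cap planes uniformly; a unit test
cross-checks it against the closed-form ray–cylinder intersection.  Links
that graze a surface tangency (e.g. along a segment end-cap plane at a
junction) resolve to `q ≈ 1`; a link whose far end is robustly interior to
the analytic surface is a classification error and aborts the run.

**Openings.**  Velocity inlets and pressure outlets are imposed by local
non-equilibrium extrapolation: the full population set at an opening site
is rebuilt as the equilibrium of the imposed quantity plus the
non-equilibrium part of the interior neighbour.  Inlet profiles use a
parabolic weight map `w(r) = 2(1 − (r/R)²)` renormalised to unit mean over
the discrete patch, so the patch mean velocity equals the waveform value
exactly.  The default inlet waveform is a raised-cosine systolic pulse
calibrated to a 28.6 cm/s peak and 4.2 cm/s period mean with a brief
retrograde phase, preceded by a 0.8 s linear warm-up ramp.

**Outlet forcing.**  Bed feedback reaches arterial outlets as a Guo-style
body force along the outlet normal, applied over the `force_depth = 3`
voxel layers behind the cap (the cap layer itself is owned by the pressure
outlet).  The force magnitude is the signed lattice dynamic-pressure
deficit `½(v_t|v_t| − v_c|v_c|)` treated as a pressure-gradient equivalent
over one voxel; the conversion gain is configurable (default 1).  For TRT
the Guo source term is split by parity — the odd part `(c·F)` relaxes with
`τ⁻`, the even part with `τ⁺` — which keeps the injected momentum exactly
`F` per site per step.  (An earlier single-prefactor variant produced a
~4% bias in resistive flows; the plane-channel viscosity test catches
this.)

## Capillary-bed model

Each bed joins `n` arterial outlets to `m` venous inlets and carries a
resistance `R` (Pa·s/m³) and capacitance `C̄` (m³/Pa).  Per exchange:

1. **Aggregate**: the flow-weighted velocity over the feeding side,
   `v_D = Σ A_j v_j² / Σ A_j v_j`, scaled by the total member area gives the
   feeding flow `Q`.  (A termwise-simplified `Σ v_j` variant is selectable
   as `plain_sum` for comparison; it is not a flow-weighted mean and is not
   the default.)  Note `v_D·ΣA ≥ ΣA_j v_j` with equality iff all member
   velocities agree — the aggregation overestimates total flow by
   (variance/mean) when members are unbalanced, which is why the healthy
   synthetic fixture uses resistance-matched arterial branches.
2. **Bed update**: `Q_out = Q_in + ½ C̄ R dQ_B/dt`, with the bed flow `Q_B`
   identified with the flow currently entering the bed (the only flow both
   sides can observe) and `dQ_B/dt` a first-order backward difference over
   the coupling interval.  The pressure drop over the bed is `ΔP = R Q_B`.
   With `C̄ = 0` the bed is purely resistive and `Q_out = Q_in` identically.
3. **Distribute**: opening `j` receives `Q_j = Q·c_j A_j / Σ c_k A_k`
   (transfer coefficient × area), i.e. a target mean velocity `Q_j/A_j`.

Exchanges fire every `interval` steps and alternate direction, starting
artery→vein (the venous instance starts from rest).  The artery→vein half
sets venous inlet velocity targets; the vein→artery half passes the venous
feed through the same bed update and converts the per-outlet target to the
dynamic-pressure force above.  Applying the RC update symmetrically in both
directions is a design choice; only the artery→vein direction is forced by
the model structure.  Default interval is 500 steps; the desk fixtures use
the interval that matches the same physical cadence (1.5 ms) at their
coarser `Δt`.

`R` and `C̄` have no universal defaults — they are properties of the
modelled vascular territory.  The shipped fixtures use `C̄ = 0` (pure
resistor) and a placeholder `R = 10⁹ Pa·s/m³`; science runs must set both.

**Fistula pairing.**  A fistula pair bypasses the bed: each venous inlet
target is the arterial partner's mean outlet velocity times a transfer
coefficient.  Post-maturation (dilated vein) the coefficient defaults to
the area ratio `A_art/A_ven`, conserving volumetric flow across the
junction.  Paired openings are excluded from any bed.

## Synthetic geometry

Vessels are chains of capped cones (linear radius taper).  A voxel is fluid
iff its centre (at `origin + (i+½)Δx`, 0-based) lies inside the union —
centre-inclusion classification, as in standard LBM segmentation.  Vessels
with radius under `3Δx` are refused as under-resolved.  Opening caps must
be axis-aligned; the materialised patch is the fluid voxel layer just
inside the cap.  A connectivity audit rejects fluid regions unreachable
from any opening, except stumps deliberately sealed by the fistula
modifier, which are recorded.

**The forearm fixture** emulates the structure, not the anatomy, of a
forearm vasculature: one brachial-like inlet (2.2 mm diameter) feeding
mirror-symmetric radial/ulnar-like branches with 1.6 mm terminal outlets;
a venous tree of four parallel trunks — cephalic and basilic analogues plus
two minor veins — drained proximally and fed by twelve 1.2 mm capillary
inlets near the wrist (2 cephalic, 2 basilic, 4 per minor vein).  Lengths
are desk-scale (24 mm) rather than anatomical.  The inlet split was chosen
so the majors carry a modest share of the bed flow (2/12 each), as in a
real hand where most wrist-level veins do not drain into either major
trunk; an anastomosis carrying ≳15% of arterial flow then redistributes
outflow in the clinically expected direction (cephalic up, basilic down)
without any parameter tuning.  The mirror-symmetric arterial branches keep
healthy outlet velocities equal so the `v_D` aggregation is exact for the
baseline.

**Fistula modifier.**  The end-to-side anastomosis is realised as a short
perpendicular stub of the requested diameter (1.2 mm default, bounded by
the local artery diameter) cut into the artery wall, with its far cap as
the new arterial outlet; a matching inlet stub attaches to the vein.  The
distal cephalic feeders are sealed, leaving the vein's distal volume as a
closed stump attached to the main vessel — the recirculation feature seen
downstream of real anastomoses.  A planar circular opening at a
configurable stub direction is a modelling choice; the true lofted junction
geometry is not specified by any data available here.  Applying the
modifier twice is rejected; maturation is modelled only as a static
dilation of the vein (factor ≈ 2.7) with area-ratio transfer coefficients —
the remodelling *transition* is out of scope.

## What the fixtures do and do not show

Passing tests on these fixtures demonstrate: the collision/streaming/wall
stack reproduces analytic Poiseuille flow with second-order wall accuracy;
the coupling conserves flow across the pair; the bed update converges to
its continuous limit; and the fistula modifier redistributes venous outflow
in the physiologically expected direction.  They do not demonstrate
patient-level accuracy: the fixtures have simplified straight/diagonal
tubes, no elastic walls, no anatomical tortuosity or calibre variation, a
steady inlet in the coupled tests, and desk-scale lengths.

## Numerical choices and problem sizes

- **Desk discretisations.**  The coupled fixtures run at `Δx = 0.2 mm`,
  `Δt = 60 μs` (τ = 0.518, mean inlet lattice speed 0.013), 20 000 steps
  with a 0.2 s warm-up and coupling every 25 steps (the same 1.5 ms
  physical cadence as a 500-step interval at the reference `Δt`); the
  Poiseuille benchmark uses τ = 0.8 at 20 and 40 sites across the bore
  (4000/9000 steps).  These sizes resolve steady state on a single CPU
  core in a few minutes each.
- **Pseudo-compressibility.**  A coarse `Δt` lowers the lattice sound
  speed, so the density (pressure) gradient along narrow vessels scales as
  `Δρ ∝ νu L/R² · Δt²` and the *volumetric* flux visibly grows downstream
  even when mass is conserved to round-off (measured drift ~10⁻¹¹ per
  step).  The fixture `Δt` and vessel calibres were sized so the total
  density variation across the coupled chain stays near half a percent,
  keeping volumetric flux a faithful conservation measure; probes
  additionally report the reference-density mass flow `Σ ρu·n̂ Δx²/ρ₀` as
  a diagnostic of this assumption.
- **Stability.**  Boundary velocities ≥ 0.1 lattice units warn; ≥ `c_s`
  error out.  A run halts with step number and max lattice speed when any
  site exceeds 0.3.
- **Determinism.**  No randomness enters a run; identical configurations
  give byte-identical probe CSVs.  The configuration seed exists for
  randomized fixture generation and interface parity.
- **Degenerate inputs.**  Zero-radius segments, under-resolved vessels,
  openings that materialise no sites, beds with empty sides, all-zero
  distribution weights and non-increasing waveforms are rejected with
  specific errors; a vanishing `Σ A_j v_j` with non-zero member velocities
  (counterflow) yields `v_D = 0` with a logged warning.

## Known limitations

- Rigid walls; no elastic response or remodelling dynamics.
- Newtonian rheology.
- Single capillary-bed topology per run pair; exactly two coupled
  instances, advanced in lockstep in one process (the exchange is an
  interface so a distributed backend could substitute).
- Oblique opening caps and oblique flow probes are not supported; fixtures
  are built with axis-aligned terminals.
- MRT/cumulant collision kernels, grid refinement and wall-shear-stress
  post-processing are out of scope.
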
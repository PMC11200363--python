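# Methods

`sinuflow` models the mechanical chain behind venous pulsatile tinnitus
(VPT): pulsatile blood flow through a stenosed transverse sinus (TS) drives
pressure loads on the sigmoid-sinus (SS) wall at the TS–SS junction; the
wall vibrates; where the bony cover is dehiscent (SSWD), that vibration
radiates into a temporal-bone air cell (TBAC) and raises the sound pressure
level (SPL) at the tympanum.  The package compares this chain before and
after virtual stenting of the stenosis, for two stenosis classes: a short
(5–7 mm) single indentation in the middle of the TS ("group 1") and a long
(>10 mm) multi-lobed indentation extending from the middle into the
proximal TS ("group 2").

## Geometry and its idealization

The model is a 2D planar slice.  The centerline is a straight TS segment
(40 mm), a tight circular junction bend (radius 8 mm, 90° — the TS–SS
turn is abrupt at vessel scale, which is what makes the junction an
impingement site), and a straight SS segment (22 mm); the lumen lies
between a rigid lateral wall and an elastic medial wall, both at a nominal
3.5 mm half-width.  The stenosis is a smooth cosine indentation of the
lateral wall whose depth realizes a prescribed residual-lumen rate (the
quotient convention: 100 × most-stenosed width / nominal width, so 100%
means no stenosis); multiple contiguous arachnoid granulations are
represented as a multi-lobed indentation with partial relief between
lobes.  The "middle-and-proximal" class extends from the mid-TS *toward*
the junction ("proximal" in the flow-referenced venous sense, toward the
heart), so its jet discharges close to the junction; the "middle" class
is centred at mid-TS.  A diverticulum is a cosine bulge of the medial
wall at mid-bend (depth 1 mm, extent 8 mm).  The elastic wall is a 0.5 mm
strip along the whole medial boundary; behind it lies a 1.5 mm
temporal-bone strip and a 14 × 12 mm air cell on the proximal SS, except
over the 5 mm SSWD patch (54.5–59.5 mm arclength, just distal to the bend
exit — the measured jet-impingement zone) where the wall faces air
directly.  The tympanum is a 4 mm segment of the cavity's far boundary.
Virtual stenting restores the nominal lateral wall over the recorded
stenosis extent and changes nothing else.

Preset rates use the group means of the reported patient cohort
(group 1: 61.33%, group 2: 64.13%), both inside the reported moderate band
(57.93–67.62%).  One-sided indentation limits representable rates to >50%.

Because the slice is 2D, "areas" of the published cohort become lengths
here, a mass flow is per unit out-of-plane depth, and absolute metric
magnitudes are not comparable with 3D patient-specific values; the intended
use is the pre/post and group-1/group-2 *contrast* under matched inflow and
materials.

## Governing physics

* **Blood** (ρ=1050 kg/m³, μ=3.5 mPa·s): incompressible Newtonian
  Navier–Stokes, laminar (peak Reynolds number < 2300 by construction of
  the inflow).  Arbitrary Lagrangian–Eulerian wall motion reduces, for the
  micrometre wall displacements here, to imposing the wall velocity as the
  no-slip value on a fixed mesh.
* **Vessel wall** (ρ=1050 kg/m³, E=1.26 MPa, ν=0.3): linear elastodynamics
  in plane strain, Lamé parameters λ = νE/((1+ν)(1−2ν)), μ = E/(2(1+ν)).
  The wall ends (inlet/outlet sections) are fixed.  The temporal bone
  (E=12 GPa, ~10⁴ × stiffer) is not meshed as an elastic body; it acts on
  the wall as stiff springs (k=10¹⁰ Pa/m) on the bone-backed medial
  surface and through its acoustic impedance.
* **Interface**: traction equilibrium and kinematic continuity are enforced
  by subiteration to a relative residual below 10⁻³ (cap 50 iterations per
  step, accepted with a warning at the cap).
* **Air** (ρ=1.139 kg/m³, c₀=340 m/s): Helmholtz equation at a single
  frequency, driven one-way by the SSWD wall motion as a normal-acceleration
  boundary source (n·∇p = ρ_air ω² u_n).  Bone-facing boundaries and the
  tympanum are impedance (Robin) surfaces n·∇p = −(iωρ/Z)p with
  Z = 5.57 MPa·s/m (the tympanum impedance is configurable separately).
  SPL = 20 log₁₀(|p|/20 µPa).

## Discretization

* **Meshing.**  The parametric geometry admits a mapped structured
  triangulation: shared arclength columns cross every region, and each
  region stacks rows (lumen → wall → bone/dehiscence notch → air), so
  interface nodes are shared by construction and uniform midpoint
  refinement nests exactly.  In-plane spacing is h/√2 so element
  circumdiameters stay below the requested h; two boundary-layer rows
  (h/4, h/2) line the lumen walls; column spacing adapts to the junction
  curvature and to the wall-profile slope, with the shorter quad diagonal
  chosen under shear.  Generation refuses meshes whose minimum angle would
  fall below 15° (for the default geometry this means h ≲ 2.2 mm).
* **Fluid.**  Equal-order P1–P1 velocity–pressure elements with SUPG/PSPG
  stabilization, implicit backward-Euler stepping and Picard linearization
  of convection (residual tolerance 10⁻³, tightened inside FSI
  subiterations).  The inlet carries a parabolic profile scaled to the
  prescribed pulsatile mass flow; the outlet is traction-free (reference
  pressure 0); walls are no-slip.
* **Solid.**  Quadratic (P2) triangles built on the geometric mesh, which
  resolve the bending of the 0.5 mm wall with one or two element rows
  through the thickness.  Implicit Newmark integration: the
  energy-conserving average-acceleration rule (γ=1/2, β=1/4) is the solver
  default and is what the energy oracle verifies; coupled runs use γ=0.8
  (β=(γ+½)²/4), whose algorithmic dissipation is confined to modes near
  the step Nyquist frequency — at the cardiac band (ω·dt ≈ 5·10⁻³) the
  effective damping ratio is ~10⁻⁴, while the wall's free flutter at a few
  hundred Hz (2–5 steps per period at the CFL time step) is suppressed.
  No physical structural damping is applied anywhere.
* **Acoustics.**  P1 triangles on the air region; complex direct solve.

## Coupling scheme

Within each time step the fluid and solid exchange interface data in a
strongly coupled fixed-point loop: fluid solve with the current interface
velocity → wall traction (−σ_f·n, n outward of the lumen) transferred as a
consistent edge load → Newmark solid step → interface displacement back.
A thin wall of blood-like density in an incompressible liquid makes the
bare map amplifying (added-mass effect), so the update uses interface
quasi-Newton relaxation (IQN-ILS: least-squares secants from the current
step plus up to four recent steps) with a second-order predictor,
trust-region limiting, divergence backoff to the best iterate, a fallback
to fixed under-relaxation when the secant model stalls, and a cap on the
interface velocity handed to the fluid at ~5% of the peak mean flow speed
(physical wall speeds are three orders of magnitude smaller, so the cap
only clips divergent subiterates).  Typical cost is 4–7 subiterations per
step.  Convergence requires both the relative interface-displacement
change and the relative traction change to fall below 10⁻³.

The wall–bone springs act bilaterally (a tie) in coupled runs: the medial
surface is anatomically attached to the bone, the compressive state (where
unilateral and bilateral coincide — penetrations are ~20 nm) dominates,
and a unilateral spring set would release wholesale during suction phases,
leaving a 77 mm end-clamped strip with no inward support.  The unilateral
penalty law (traction k·max(0, penetration)) is implemented and tested as
an operator, and quasi-static solves support active-set contact.

## Run protocol and metrics

A scenario runs four 0.8 s cardiac cycles from rest (reduced cycle counts
are available for scaled-down studies), with a smooth inflow ramp over the
first quarter cycle, at a fixed automatic time step chosen so the CFL
number stays below 1 at estimated peak flow (clamped to [T/2000, T/100]).
The synthesized inflow is Q(t) = Q̄(1 + 0.3 sin 2πt/T + 0.1 sin 4πt/T)
with Q̄ = 1.617 kg s⁻¹ m⁻¹ (a 0.22 m/s mean velocity in the nominal
channel), calibrated so the peak Reynolds number in a stenosed scenario
lands in the 1000–1500 band — the upper laminar range, where the
post-stenotic jet persists to the junction — while staying below the
2300 laminar limit everywhere.  The published inflow trace is not printed
in the source literature, so absolute velocity levels are representative,
not reproduced.

Metrics come from the last cycle: at its maximum-velocity moment,
``Pavg`` (edge-length-weighted fluid pressure on the wall under the SSWD
patch) and ``Davg`` (weighted displacement magnitude of the SSWD outer
surface, in µm); ``SPLavg`` (weighted SPL along the tympanum) from a
Helmholtz solve whose source is the Fourier amplitude of the SSWD normal
displacement over the last cycle.  The default analysis frequency is the
**dominant harmonic** of each scenario's own SSWD motion spectrum,
mirroring a per-model-frequency SPL evaluation.  This matters because the
pre-stent impingement load varies quadratically with the pulsatile jet
speed, concentrating wall motion at the *second* cardiac harmonic
(2.5 Hz), whereas the stented response is linear and
fundamental-dominated; evaluating both states at one fixed frequency
misranks them.  Two alternatives are selectable: the cardiac fundamental
1/T, and the first structural mode frequency of the constrained wall
(always computed and reported).  In a smooth laminar 2D run without
structural damping the wall carries no resolvable energy at the
structural mode frequency — that bin sits at or above the Nyquist
frequency of the CFL step and contains only solver noise — so it is not
the default here, although the corresponding eigenvalue analysis itself
is oracle-verified.

Stent effect is reported as pre − post for all three metrics (positive =
improvement) and as a percent reduction of Pavg; this follows the
convention of every difference cell in the reference cohort bundled for
arithmetic verification.

## Mesh convergence protocol

`mesh_convergence_study` reruns a scenario on nested uniform refinements
and reports the relative change of the two monitored quantities between
levels; a pair of levels is accepted when both change by less than 5%.
Three aspects of the protocol matter for a fair comparison:

* all levels advance with a **common time step** (the finest level's
  automatic CFL step), so the inter-level change isolates the spatial
  error;
* the displacement monitor is the **cycle-averaged** Davg over the last
  cycle — the peak-moment sample used for outcome reporting is a
  single-instant probe of an unsteady flow and is far noisier (it is
  reported alongside);
* the solid solver internally subdivides the wall strip so that at least
  two P2 element rows always span the 0.5 mm wall (a one-row wall is
  ~19% too stiff in bending); this also makes the wall discretization
  identical across a nested pair, so the monitored change reflects the
  fluid.

The bundled reproduction run uses the group-2 preset with a 1.6 mm base
mesh (which carries boundary-layer rows) refined once to 0.8 mm
(~2.4k → ~9.7k triangles) and a reduced two-cycle protocol with a
one-eighth-cycle inflow ramp; it finishes in about a quarter hour on one
core.  Coarser pairs do not yet reach the 5% band for the displacement
monitor (e.g. 2.2 → 1.1 mm changes by ~11%), which is what the reduced
suite-scale test reports.

## Problem sizes and defaults

Preset production runs default to h = 0.8 mm (~12k triangles) and four
cycles (minutes to tens of minutes per scenario on one core).  The test
suite and the acceptance script use 2.2 mm meshes and one or two cycles so
a full four-scenario comparison plus a convergence study completes within
a coffee break; the methods and contracts are identical at every size.

## What the synthetic generator does and does not emulate

It reproduces the study conditions structurally: two stenosis classes with
cohort-mean rates, a junction diverticulum, a dehiscence patch with an air
cell and tympanum receiver, matched materials and inflow across scenarios,
and deterministic geometry given a config.  It does not reproduce
patient-specific 3D lumens, out-of-plane curvature and torsion, CTA-derived
wall thickness variation, the unpublished inflow trace, or
transitional/turbulent flow features; consequently absolute Pavg/Davg/SPL
magnitudes are desk-scale, and conclusions should be drawn from the
relative pre/post and between-group structure, which is what the tests
assert.

## Numerical choices and degenerate inputs

Geometry generation validates stenosis class bounds (middle: 5–7 mm;
middle-and-proximal: >10 mm; residual rate in (50, 100]), rejects
stenoses overlapping the end sections, diverticula deeper than the bone
strip, and dehiscence patches not strictly inside the cavity footprint.
Zero-width throats raise; a 100% rate is the exact identity geometry.
The SPL of a zero pressure field clamps to 0 dB with a warning.  Picard
and subiteration divergence raise with step context after safeguarded
retries.  All randomness-free: reruns are bitwise identical.

## Known limitations

* 2D laminar flow underestimates jet break-up; the group contrast relies
  on jet impingement geometry rather than turbulent dissipation.
* The acoustic stage is single-frequency and one-way; transient acoustics
  and middle-ear transmission are out of scope.
* The solid is linear (small strain); wall displacements are monitored and
  stay well below the 10% of thickness where that assumption would warn.
* Partitioned coupling accepts (and logs) occasional steps at the
  50-iteration cap during violent transients instead of aborting.
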
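# Methods

## Scope and frame

`kneesim` models quasi-static tibiofemoral contact of a right knee during
the stance phase of gait.  The tibia is fixed; the femur is a rigid body
with three translations and three Cardan rotations (flexion-extension
about +z, then varus-valgus about the rotated +x, then internal-external
about the doubly rotated +y) taken about the femoral reference point
RP_Femur, the midpoint of the epicondyles.  The frame is tibia-fixed and
right-handed: +x anterior, +y proximal, +z lateral; units are N, mm, MPa,
s; forces are reported normalized to body weight (BW, default 700 N).

The packaged study compares four ways of driving the joint through
stance: kinetic (Model A: translational forces, half-scaled
internal-external and varus-valgus moments, flexion prescribed, patella
and tendons included), kinetic-kinematic with the full geometry (Model B:
forces plus prescribed flexion and internal-external rotation), and
kinetic-kinematic with a reduced geometry lacking the patellar mechanism
(Model C), optionally augmented by adding the anterior-posterior
quadriceps component to the applied force (Model D, scale `s`, default 1).
Varus-valgus is always solved as a free degree of freedom; in Model A a
half-scaled varus-valgus moment is additionally applied, reflecting the
assumption that musculature absorbs half of the measured moments.
Whether Model B also applies the varus-valgus moment is configurable
(`solver.mode_b_vv_moment`); the default is no moment, reading the
kinetic-kinematic prescription as replacing moments entirely.

## Cartilage and meniscus constitutive models

Cartilage is transversely isotropic poroelastic (TIPE).  The drained
skeleton compliance uses the plane of isotropy as the local articular
tangent plane and the out-of-plane axis as the surface normal, with
`S13 = -nu_tp / E_t` and the closure `G_p = E_p / (2 (1 + nu_p))`.
Admissibility is enforced on construction (`E_p, E_t, G_t > 0`,
`|nu_p| < 1`, `(1 - nu_p) E_t > 2 nu_tp^2 E_p`); violations raise with
the violated bound named.  The default parameters (`E_p = 24`,
`E_t = 0.46 MPa`, `nu_p = 0.42`, `nu_tp = 0.06`, `G_t = 12 MPa`,
`k = 1e-15 m^4/(N s)`, `e_0 = 4`) give a positive-definite operator with
out-of-plane aggregate modulus `H_A = C33 ≈ 1.31 MPa` and axial-lateral
coupling `C13 ≈ 7.05 MPa`.  Menisci are transversely isotropic elastic
(TIE, `E_p = 20`, `E_t = 159.6 MPa`, `nu_p = 0.3`, `nu_tp = 0.01`,
`G_t = 50 MPa`); no meniscal fluid phase is modeled because only the
load-carrying role of the tissue is of interest here.  Permeability is
carried in the conventional `1e-15 m^4/(N s)` and converted once
(`1e-3 mm^4/(N s)`) inside the consolidation code.

## Contact: a field of 1-D poroelastic columns

Instead of a 3-D hexahedral discretization, the tibial and meniscal
contact surfaces are tessellated into independent through-thickness
columns (elastic-foundation / discrete-element style), preserving the
constitutive law, the three-layer depth discretization and the
consolidation time-dependence at a fraction of the cost.  Each column
deforms in confined compression (zero lateral strain), drains at the
articular surface and is sealed at the bone interface.  Nodal unknowns
are the pore pressures and the uniform total axial stress; implicit Euler
in time with the settlement constraint (or prescribed traction) gives a
small linear system per column per step.  Validation: the step-load pore
pressure profile matches the classical consolidation series to < 0.03%
RMS at 32 layers, and the drained limit matches `H_A / h` exactly.

Within one stance step of duration `dt` the column response is *affine*
in the surface overlap, `sigma = alpha + beta * d`, with `alpha`, `beta`
from two linear solves against the previous pressure state.  The
equilibrium solver consumes this law clamped at zero (tension never
transmitted); columns that lose contact relax under zero traction and
recover.  Complementarity therefore holds exactly at every column, and
tangential traction is identically zero (frictionless contact; forces act
along the local surface normal from the dish gradient, a small-slope
approximation).

Two discretization notes.  First, with three depth layers the implicit
step is numerically softer than the continuum instantaneous response
(the drained surface node compresses within one step); this acts as the
effective foundation compliance standing in for the lateral load
spreading that independent 1-D columns cannot represent, and it is
identical across driving modes, so inter-model comparisons are not
biased by it.  Second, the same coarse depth grid accelerates early-time
creep, so heavily loaded columns can reach large compressions late in
stance; reported logarithmic strains are clamped below 100% compression.

Meniscal columns stack an elastic TIE spacer in series with the cartilage
column (wedge-shaped, conforming to the condyle so the reference pose is
penetration-free by construction) and add a parallel vertical stiffness
distributing the horn-spring constant (2 x 350 N/mm per meniscus) over
that meniscus's columns — a deliberate lumping of horn anchorage and hoop
restraint behind one interface.

## Ligaments, tendons and the patellar mechanism

Cruciates, collaterals and the two patellar tendons are bilinear springs:
tension `k * max(0, L - L_slack)`, slack length `L_ref / (1 + prestrain)`
with the reference pose being the initial (imaging) pose of the synthetic
geometry.  MPFL and LPFL are linear trusses with no compressive
stiffness; their Poisson's ratio is recorded but unused by the 1-D force
law, and the cross-section (10 mm² each) is a configurable
order-of-magnitude choice.

The patella is a point body in its own 3-DOF force balance: the
quadriceps pull (magnitude QF, direction patella → RP_Quad) is applied to
it; the QT spring anchors it to RP_Quad on the femur; the PT spring runs
to its fixed tibial insertion; MPFL/LPFL truss to the femur; and a single
elastic patch (stiffness 200 N/mm) presses it against a spherical
trochlea.  The patellar equilibrium is solved to 1e-7 N with a Powell
hybrid root-finder warm-started from the previous step (deterministic
reference-point fallback).  The femur receives the QT reaction at
RP_Quad, the truss reactions and the patellofemoral contact force; the PT
carries load directly into the tibia.  Net effect: quadriceps action
compresses the tibiofemoral joint, so the full-geometry models carry a
higher axial reaction than Model C — the contrast the Model-D surrogate
is designed to close.

Quadriceps decomposition: the force is projected on the line from
RP_Quad (rotated with flexion about RP_Femur) to the patellar reference;
QF_ap is anterior-positive, QF_dp distal-positive, and the medial-lateral
remainder is discarded.  Beyond 15 degrees of flexion the anchor rotation
saturates, emulating the tendon wrapping on the trochlea; without this
the pull direction eventually passes the tangent of the frictionless
trochlea sphere and the patella has no equilibrium on it.

## Synthetic geometry and gait

The geometry generator stands in for image segmentation.  Femoral
condyles are ellipsoidal patches (default 26/24/21 mm semi-axes, centers
±22 mm medial-lateral); tibial plateaus are shallow spherical dishes
(radius 28 mm) tessellated at 1 mm (2 mm coarse preset); cartilage
thickness is a smooth seeded field clipped to [1.5, 4.0] mm; menisci
occupy the outer annulus (elliptical radius > 0.62) and close 85% of the
local condyle-dish gap.  Ligament insertions sit at anatomically
plausible coordinates jittered ±0.8 mm per seed; cruciate femoral
insertions are placed near the flexion axis so ligament lengths stay
near-isometric over the stance flexion range — with distal insertions the
cruciates went slack in terminal stance, collapsing anterior-posterior
stiffness and making the equilibrium non-unique.  The plateau half-length
(20 mm, anatomic order) must accommodate the ~5 mm physiological anterior
femoral excursion without contact running off the tessellated edge.  A
symmetry flag mirrors the medial compartment exactly.  One build returns
the full (A) and reduced (B) variants sharing the tibiofemoral arrays, so
patella-related contrasts are attributable solely to the mechanism.

Gait inputs are sums of Gaussian bumps on a 101-point stance grid with
optional smooth seeded noise (3% default): double-peaked axial force
(peaks 1.05/1.00 BW at 20%/80% stance), braking/propulsion AP force
(±0.12-0.14 BW), small ML force, double-peaked adduction moment (peak 40
N·mm/BW, inside the physiological corridor of ~2-4 %BW·height),
internal-external moment (peak 15 N·mm/BW), flexion from ~10 degrees at
heel strike to ~38 degrees at toe-off, internal-external rotation within
±4 degrees, and a quadriceps force peaking at 1 BW at 18% stance.  These
are *structural* stand-ins: they reproduce waveform shape, timing and
physiological magnitude ranges, not any subject's measurements — so tests
against them validate procedures and qualitative contrasts, not
subject-specific values.

## Equilibrium solution

Each stance step imposes the prescribed rotations, assembles the mode's
loads, and solves the free DOFs (translations + varus-valgus, plus
internal-external in Model A) by damped Newton iteration with
finite-difference Jacobians: convergence at residual < 1e-8 BW (forces)
and 1e-8 BW·mm (moments), per-iteration updates capped at 2 mm / 0.1 rad
so the quasi-static march follows the continuous equilibrium branch, and
generalized moments projected on the Cardan axes conjugate to the free
rotations.  The three-step protocol is: (1) settle — translate the femur
distally to exact first touch; (2) initial state — rotate to the t = 0
orientation, apply the t = 0 loads and equilibrate (ligament slack
lengths stay frozen at reference); (3) march t = 0 → 1 in 100 steps with
consolidation time step `stance_duration / n_steps` (0.6 s stance).  A
state already in equilibrium is accepted with zero iterations; a step
failure returns a partial result carrying the failing index.

## Outputs and comparison metrics

The tibial-surface reaction is the resultant of the column forces
(cartilage traction × area plus the meniscal horn share), reported in BW.
Compartment responses average over the *contacting, cartilage-cartilage*
columns only (meniscus-covered columns excluded): maximum principal
stress is the largest eigenvalue of the tensor assembled from the
confined-compression state (total axial `-sigma`; effective axial
`-sigma + p`; lateral `C13/C33` times the effective axial, minus `p`),
logarithmic strain is `ln(h/h0)`, pore pressure is the thickness average.
Steps with an empty contact set propagate NaN, never zero.  Contact area
is reported as a column count (mirroring a node count) and in mm².
Model comparisons report mean and max absolute differences over the
stance grid plus traction snapshot maps at 20/50/80% stance.  The
quadriceps-scale sweep scores each Model-D run by an equal-weighted sum
of the mean absolute differences in the three translations and three
reaction components — the norm is a declared choice, configurable by
weight.

## Problem sizes and determinism

Default runs use 1 mm columns (~1750 columns) and 100 stance steps
(about one second per mode); the test suite and the acceptance script
use the 2 mm coarse preset (~440 columns), where a full four-mode
comparison takes a few seconds.  All randomness flows through explicit
seeds; identical configuration and seed give byte-identical artifacts
(no timestamps are written).

## Known limitations

* Columns are mechanically independent: no in-plane stress transfer or
  lateral fluid flow; the instantaneous foundation stiffness is partly a
  discretization property (see above).
* Surface tensile stresses from in-plane sheet stretching are not
  represented; reported maximum principal stresses derive from the
  confined-compression state only.
* The patella is a point body on a spherical trochlea with a saturating
  quadriceps direction — no trochlear groove, tilt or spin.
* Menisci do not translate or extrude; hoop mechanics are lumped into a
  vertical stiffness.
* The prestrained QT/PT chain produces a standing tibiofemoral
  compression in the full geometry, so the Model A/C axial-reaction gap
  has a constant offset in addition to the quadriceps-driven transient;
  inter-model *contrasts* (sign and localization) are the meaningful
  outputs, not absolute gaps.
* Quasi-static only: no inertia, no friction, rigid bones.
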
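# Methods

`archwalk` is a planar (sagittal-plane) predictive neuromuscular walking
simulator whose purpose is to compare foot models of increasing mechanical
complexity inside an otherwise identical body and controller.  This note
documents the model, the numerical choices, and what the bundled synthetic
fixtures do and do not represent.

## Body model

The skeleton is a seven-plus-body kinematic tree: a head-arms-trunk (HAT)
segment floating in the plane (x, y, pitch), and two legs of thigh, shank
and hindfoot connected by revolute hips, knees and ankles.  Depending on
the foot variant, each foot adds a forefoot segment (midtarsal joint, MTJ)
and/or a toe segment (toe joint, TJ).  Segment parameters (HAT 53.5 kg /
0.35 m CoM height / 3 kg m²; thigh 8.5 kg, 0.5 m; shank 3.5 kg, 0.5 m;
foot 1.160 kg, 0.005 kg m²) follow the generic reflex-walking model family
this simulator extends; they live in one `companion` defaults block
(`archwalk.params.COMPANION`) so that every assumption not specific to the
foot is auditable in one place.

Forefoot and toe segments are dynamically massless by design, so all six
variants share identical inertial properties.  Numerically they carry 3% of
the foot's mass and inertia (about 35 g): with literally (or nearly) zero
mass, the plantar-ligament damping acting through the ball contact produces
eigenvalues beyond what double-precision implicit integration can
meaningfully resolve.  At 3% the distortion of whole-body dynamics is at
the tenth-of-percent level, and the fraction is a single config field
(`FootInertia.light_mass_fraction`).

Equations of motion are assembled Jacobian-wise (mass matrix from CoM
Jacobians, bias terms from an acceleration recursion) and validated against
a symbolically derived Lagrangian model and an energy-conservation property
in the test suite.

## Foot variants

Six feet, named `#segments-feature`: `1s-lA` (flat rigid foot, ankle at
sole level), `1s-hA` (rigid arch, ankle 8 cm above the sole), `2s-TJ`
(rigid arch + toe), `2s-MTJ` (mobile arch, no toe), `3s-nW` (mobile arch +
toe, decoupled), `3s-W` (mobile arch + toe coupled through the plantar
fascia — the windlass foot).  All variants share the same contact-element
geometry; the undeformed heel-ball contact spacing is 17 cm everywhere and
is enforced at model construction (±1 mm).

Two ligaments span the arch: the plantar fascia (PF, A = 50 mm², damping
d = 3 s) and the plantar ligament (PL, A = 120 mm², d = 30 s), both with
collagen stiffness k = 340 MPa, resting length l0 = 15 cm and exponent
α = 9.  Tension follows the exponential constitutive law
F = A λ² (k/2α)(e^{α(λ²−1)} − 1)(1 + d λ̇), tension-only, with the damping
factor clamped slack when the relaxation-rate bound d λ̇ ≤ −1 is violated.

The PF path length is variant-specific: chord between the heel and ball
attachments (2s-MTJ); l0 + φ_TJ·R_PF for the wrap around the 1 cm
metatarsal head (2s-TJ); both, evaluated independently (3s-nW, the
"no-windlass" control model); their sum through one ligament (3s-W), which
couples toe dorsiflexion to arch shortening.  Strain is referenced to the
neutral pose, λ = 1 + (l − l_neutral)/l0: the printed attachment
coordinates give a neutral chord much shorter than l0, so using l0 as the
strain denominator with a neutral-pose offset keeps strain zero at neutral
and gives every variant the same stiffness per unit elongation.  The wrap
is the ideal arc term only — no geometric wrap/unwrap detection.

MTJ and TJ carry small linear return spring-dampers (0.01 Nm/deg,
0.001 Nm s/deg) that restore the neutral pose during swing.

## Ground contact

Circular heel/ball elements (R = 5 / 5.73 cm) and a point toe.  The force
acts at the lowest point of the circle, which rolls along the circumference
as the element rotates; a rolling element therefore produces no friction
(the material slip velocity v_center + ωR vanishes).  Vertical force is
Hunt-Crossley, F_v = −k_y Δy (1 − v_y/v_max) with k_y = 78.3 kN/m and
v_max = 0.03 m/s (releasing to zero when the foot retracts faster than
v_max); horizontal force is a continuous velocity-based friction curve
with μ_d = 0.8, μ_s = 0.9 and transition velocity v_t = 0.01 m/s, applied
opposing sliding so contact can only dissipate.  The ground is flat at
y = 0.

## Muscles and reflex control

Seven Hill-type muscle groups per leg (SOL, TA, GAS, VAS, HAM, GLU, HFL)
with first-order excitation-activation dynamics (τ = 10 ms), exponential
force-length, Hill force-velocity (K = 5, eccentric plateau N = 1.5),
quadratic series elasticity (ε_ref = 4%), parallel and buffer elasticity.
The CE length is the muscle state; its rate comes from inverting the
force-velocity relation.  When the tendon is slack the fiber simply tracks
the path length with a 20 ms time constant — inverting the force-velocity
relation there would drive the fiber at v_max into the buffer elasticity
and contributes nothing but numerical stiffness.

The controller is phase-based and local, with delayed feedback (20/10/5 ms
for ankle/knee/hip pathways) through a fixed-step history buffer sampled at
the 1 ms control interval.  Stance: SOL, GAS, VAS on positive force
feedback (gains normalized to F_max); TA on length feedback with SOL force
inhibition; VAS knee-overextension protection (gain k_φ); hip muscles
balance the trunk with a PD law on forward lean, blended by the leg's load
share.  Double support: the trailing leg's VAS is inhibited and its HFL
excited (GLU/HAM inhibited) in proportion to the contralateral load —
swing preparation.  Swing: HFL length feedback minus HAM-stretch
inhibition plus a lean-proportional placement term sampled at toe-off;
HAM and GLU force feedback brake the swinging leg.  All stimuli are
clipped to [0, 1].  The ten gains (k_φ and nine G's) are the per-variant
optimized values; everything else is a shared companion constant.

## Numerics

The coupled ODE (13–26 skeleton states + 28 muscle states) is integrated
with an L-stable one-step TR-BDF2 scheme compiled with numba: nominal step
100 µs (tied to the configured tolerance as h ∝ √rel_tol so tightening the
tolerance refines the step), Newton iterations with a cached
finite-difference Jacobian that is refreshed on slow convergence, and
local step halving (to h/4096) through contact transients.  Stimuli ramp
linearly across each 1 ms control interval so the vector field stays
continuous.  Trajectories are recorded at 1 kHz.  The integrator survives
the dominant stiffness sources — Hunt-Crossley damping, the
near-stiction region of the friction law, plantar-ligament damping on the
light forefoot — which defeat off-the-shelf variable-step BDF through
constant micro-stepping.

Falls are detected when the HAT CoM drops below half its standing height
or trunk pitch exceeds 60°; both thresholds are configuration fields since
no canonical values exist.  Initial conditions are a mid-swing posture
(leading leg loaded, trailing leg mid-swing with a forward push) stored
per variant; the model settles into its gait within two to three strides,
and all analysis uses the last full left-leg cycle.

## Gait analysis

Cycles are segmented heel-strike to heel-strike on the leg-total vertical
GRF, low-pass filtered (zero-phase 2nd-order Butterworth, 50 Hz) with a
1 N onset / 0.5 N release hysteresis; heel-off uses the heel element and
opposite touch-down the contralateral leg.  Work integrals use the raw
(unfiltered) forces and point-of-action velocities.  Global measures
follow the standard definitions: duty factor DF = t_stance/t_stride, cost
of transport CoT = E_metab/(m l_s), power amplification
P_amp = |max P_ank>0| / |min P_ank<0| over the stride.

The metabolic model (not prescribed by the reflex-walking literature this
builds on) is a Margaria-efficiency accounting: positive fiber work / 0.25
plus |negative fiber work| / 1.20, an activation-squared maintenance heat
(0.01·a²·F_max·l_opt per muscle) and an 80 W basal rate.  It is monotone in
activation, non-negative, and places the cost of transport in the
3–5 J/(kg m) range typical of these models; it is deliberately simple and
swappable (`COMPANION["metabolic"]`).

## Cost and gain optimization

The gait cost integrates, from the third step onward and per metre walked,
weighted metabolic rate, summed squared activations, rectified GRF rate,
HAT acceleration magnitude, and knee/ankle stop moments, plus a quadratic
early-fall penalty (weights w1..w7 = 535, 1e3, 3, 1e4, 15, 20, 1e5).  The
gain optimizer is a seeded real-coded evolutionary search (scipy's
differential evolution) over a box around a seed gain set, with the seed
injected into the initial population so elitism guarantees monotone
improvement.  Full-scale optimization (population 200) is out of desk
scope; the bundled settings are a scaled-down smoke configuration
(population 20, 5 generations).

## Static test bench

An independent pure-numpy quasi-static model of the isolated foot: heel
and ball rest on the ground (horizontal pinning by stiff springs emulates
static friction), a vertical load ramps up at the ankle, and equilibrium is
solved per load level by damped least-squares on the generalized force
residual.  It reports arch compression and MTJ/TJ angles versus load and
backs the least-squares calibration of the PL cross-section A_PL; the
calibration targets bundled with the tests are generated by the forward
bench itself (round-trip recovery), standing in for experimental
compression data which can be pasted into the same interface.

## Synthetic fixtures and their limits

The bundled reference kinematics (`reference_gait_synthetic.csv`) are
smooth low-harmonic curves with the gross shape of averaged human sagittal
hip/knee/ankle trajectories — explicitly synthetic.  Cross-correlations
against them exercise the analysis pipeline but say nothing about
agreement with real human data; supplying a real dataset in the same
stride-normalized CSV layout replaces them transparently.

## Problem sizes

The bundled protocol simulates 15 s per variant (the first two to three
strides are settling; analysis uses the last full left-leg cycle), records
at 1 kHz, and runs in roughly 0.5–5 minutes per variant on one CPU.  The
bundled gain-optimization configuration is a scaled-down smoke run
(population 20, 5 generations, 3 s evaluations at a coarsened step); a
publication-scale optimization would use a population of order 200 with
long-horizon evaluations.

## Known limitations

- The companion-model constants (muscle parameters, delays, balance and
  swing-preparation gains, initial poses) are this package's own
  calibration of the generic reflex-walking architecture; the emergent
  gait reproduces part of the foot-model contrasts, but individual
  quantitative measures inherit the uncertainty of that calibration.
- **Variant coverage**: with the bundled calibration, the published
  per-variant gain columns produce a full 15 s steady walk for `1s-hA`,
  `2s-TJ` and (11.5 of 15 s) `2s-MTJ`.  `1s-lA` (ankle at sole level —
  a markedly different ground-reaction lever geometry) and the
  three-segment feet (whose passively hanging toe consumes the model's
  slender swing-foot clearance) take only a few steps before falling.
  Those gain columns were optimized by the original study against its own
  surrounding model; a calibration of this package's companion constants
  that stabilizes all six columns simultaneously was not found within the
  search budget, and quantities that require the missing variants' steady
  cycles are reported from the strides they do produce.
- Gait quality varies across the walking variants: `1s-hA` and `2s-TJ`
  walk with human-like duty factors (~0.6) and stride times (~1.3 s),
  while the `2s-MTJ` solution is a faster, shorter-stride gait.
- The cost of transport (~8 J kg⁻¹ m⁻¹) is above the 3–5 band typical of
  optimized models of this family — the bundled gaits are calibrated for
  stability, not energetic optimality, and the metabolic model is a
  deliberately simple Margaria accounting.
- 2D only; no mediolateral balance, no terrain.
- No active intrinsic foot muscles; the toe rests at 0° in swing.
- The friction law is continuous (no true sticking); standing indefinitely
  produces a slow millimetre-scale drift.
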
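# Methods

This document records the model definition, the conventions, and the
numerical/design decisions, so that every number in the code has a
stated origin.

## Coordinate frame and kinematic chain

The origin sits at the right shoulder; +x points right (away from the
body midline), +y up, +z forward.  With all joint angles at zero the
arm hangs straight down along −y.  The chain, in order, with rotation
axes expressed in each joint's parent frame:

| # | joint                     | axis | range (deg) | torque scale g (Nm) |
|---|---------------------------|------|-------------|---------------------|
| 1 | elevation-plane angle     | +y   | −90 … 130   | 36.01 |
| 2 | shoulder elevation        | −x   |   0 … 180   | 60.97 |
| 3 | humeral rotation          | −y   | −90 … 20    | 19.37 |
| 4 | elbow flexion             | −x   |   0 … 130   | 12.57 |
| 5 | pronation/supination      | −y   | −90 … 90    |  1.03 |
| 6 | wrist deviation           | +z   | −10 … 25    |  2.14 |
| 7 | wrist flexion             | +x   | −70 … 70    |  1.53 |

The −x sign on elevation and elbow flexion makes positive elevation
sweep the hanging arm toward +z (forward) when the elevation-plane
angle is zero, and positive elbow flexion curl the hand upward — the
anatomically natural directions.  Anchor poses used as kinematic
tests: elevation 90° puts the fingertip at (0, 0, 0.82); adding 90°
elbow flexion moves it to (0, 0.48, 0.34).

Segments: upper arm 0.34 m / 2.0 kg, forearm 0.28 m / 1.2 kg, hand
0.20 m / 0.5 kg (shoulder→elbow, elbow→wrist, wrist→fingertip).  Each
segment is a thin rod (transverse inertia m l²/12 about the centre of
mass) with a small explicit long-axis inertia (2·10⁻³, 1·10⁻³,
5·10⁻⁴ kg m²) so axial rotations are well defined.

### Joint armature

A constant reflected inertia of 10⁻⁴ kg m² is added to every diagonal
entry of the mass matrix.  At the hanging posture the elevation-plane
axis and the humeral-rotation axis become collinear and every segment
lies distal to both joints, so the rigid chain's mass matrix is
*exactly* singular (a gimbal-lock-type degeneracy of the
parameterization, confirmed numerically: smallest eigenvalue ~10⁻¹⁷
at zero elevation vs ~6·10⁻⁴ at 5°).  The armature term — physically
the rotor/soft-tissue inertia that a real joint always carries —
bounds the condition number near 10⁴ while perturbing even the
fastest distal modes by under ~15 %.  It is applied identically in
the compiled path, the reference path, and the energy accounting.

## Dynamics integration

Semi-implicit (symplectic) Euler at 2 ms substeps: solve
`M(q) qddot = tau − Q(q, qdot)` (Q = Coriolis/centrifugal + gravity,
assembled by a recursive Newton–Euler pass), update velocity first,
then position.  Joint limits are enforced by clipping the angle and
zeroing that joint's velocity.  The scheme is first-order in the
configuration-dependent mass matrix: on a 1 s passive swing from
horizontal the mechanical-energy drift is ~2.7 % of the drop height at
2 ms and halves when the substep halves (verified in the test suite).
The compiled (numba) inner loop and the reference numpy implementation
agree to 10⁻¹² and are tested against each other; the reference path
is itself tested against independent oracles (homogeneous-transform
forward kinematics, finite-difference Jacobians, a Christoffel-symbol
Lagrangian for the bias forces, and an exact discrete closed form for
constant torque on a single free DOF).

## Actuation and noise

Each DOF carries a second-order activation filter
`t_e t_a sigma'' + (t_e + t_a) sigma' + sigma = c` with excitation
time constant t_e = 30 ms and activation time constant t_a = 40 ms,
discretized by forward Euler at the 2 ms substep; five substeps make
one 10 ms control step.  The discrete one-substep matrices are

    A = [[1, 0.002], [−1.6667, 0.88333]],   B = [0, 1.6667].

The policy action a ∈ [−1, 1]⁷ is corrupted once per control step by
signal-dependent and constant Gaussian noise,
`c = (1 + eta) a + eps`, eta ~ N(0, 0.103), eps ~ N(0, 0.185), and
held over the substeps.  Activation is signed and *not* clipped; the
joint torque `g · sigma` is hard-clipped to the voluntary range ±g.

## Episode, reward, observation

Targets are spheres; a movement succeeds after 10 consecutive control
steps (100 ms dwell) inside the target, and the movement time excludes
that dwell.  Reward is −1 per control step, so maximizing return
minimizes movement time; episodes cap at 150 steps (1.5 s).

The 48-dimensional observation stacks joint angles (7), joint
velocities (7), activations (7), excitations (7), fingertip position
(3), velocity (3), acceleration (3), target position (3), target
velocity (3, zero for static targets), fingertip-minus-target
difference (3), the signed projection of fingertip velocity on the
target direction (1), and the target radius (1).  A fixed elementwise
scale (divisors of order of each quantity's typical magnitude) is
applied before the networks; acceleration, with typical magnitudes of
hundreds of m/s², is divided by 200.

Initial postures are sampled inside the workspace (a box in front of
the body, 0.40 × 0.70 × 0.30 m); an inverse-kinematics anchor set built
from the box's edge midpoints spans the posture space, and episodes
start from a random convex combination of anchors with near-zero
velocity.

## Curriculum and learner

The target diameter starts at 0.60 m.  After every evaluation period
(10 000 steps; 30 greedy episodes) it shrinks by 1 cm if the success
rate strictly exceeds 90 %, grows by 1 cm if strictly below 70 %, and
is clipped to [0.001, 0.60] m; training stops when it falls below
1 cm.  During training, 10 % of episodes draw a uniform random
diameter instead of the curriculum value so large targets are never
forgotten.

The learner is soft actor-critic in plain numpy: tanh-squashed
Gaussian actor, twin critics with a min-target, polyak averaging
(0.005), automatic temperature toward a target entropy of −7 (one per
action dimension), discount 0.99, replay capacity 10⁶, batch 256,
Adam at 3·10⁻⁴, hidden layers (256, 256).  Episode ends by timeout
are *truncations*: the target value bootstraps through them, and only
genuine successes terminate the value recursion.  All gradients are
verified against finite differences in the test suite.

## Evaluation protocols

**Aimed movements**: 13 targets on a circle, visited in the standard
skip-6 order so consecutive movements cross the circle; the circle
radius is `D / (2 sin(6π/13))` so every movement has length D.  Widths
derive from the index of difficulty, `W = D / (2^ID − 1)` (Shannon
formulation `ID = log2(D/W + 1)`).  The default protocol has 10
conditions with IDs spanning [1, 4] and distances 0.15–0.35 m, 50 reps
each: 6500 movements.  Movement times are fit as `MT = a + b·ID` on
per-ID medians (all-movement fits are also available).  Failed
movements enter at the episode cap, which penalizes rather than
censors them.

**Curved movements**: a via-point task advances a small target along
an ellipse (semi-axes 7.5 × 3 cm) to elicit rhythmic tracing; the
speed-curvature relation is fit in log-log space,
`log v = log k + (1 − beta) log rho`, with curvature from central
finite differences and samples below 1 mm/s excluded.

**Oracle fixtures**: minimum-jerk reaches (peak speed 1.875 D/MT at
midtime), constant-equi-affine ellipse traversals (exactly beta = 2/3,
k = gain), and exact linear Fitts tables.  The analysis code must
recover each generator's parameters to the stated precision; these
fixtures also serve as format examples for external data.

## Scaled-down end-to-end condition

The "smoke" configuration exists so the full training loop can be
exercised on a desk budget: only shoulder elevation and elbow flexion
are controlled (the other five DOFs are frozen at zero), so the
fingertip moves in the x = 0 plane.  The target slab
(centre (0, 0.05, 0.60), extent 0.40 × 0.30 m in that plane) was
chosen by scanning the two-link reachable locus of the
elevation/elbow pair: every point of the slab, and of the reduced
ISO circle (D = 0.30 m in the same plane), lies within about a
millimetre of that locus.  The curriculum bottoms out at 9 cm, the
networks shrink to (64, 64), and the entropy target is −2 (two
effective action dimensions).  A 50 000-step seeded run takes about
10 minutes on one CPU and reaches ≥ 90 % greedy success during the
curriculum descent; the reduced aimed-movement protocol (IDs 1, 1.5,
2 at D = 0.30, 5 reps) then tests the difficulty law on the learned
policy.

## Serialization

Configs are YAML with strict unknown-key and cross-field validation
(angles in degrees, converted on load).  Movement recordings are a
CSV of per-step time series plus a JSON sidecar of per-episode
scalars, written at full float precision (`%.17g`, round-trip parsing)
so that save → load is bit-exact; the format carries a version tag.
One master seed deterministically derives all named random streams.
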
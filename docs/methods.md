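# Methods

`formica` simulates the walking of a virtual ant with a three-layer model —
spiking-neuron control, Hill-type muscle actuation, and an articulated
rigid-body skeleton — and fits the free parameters of the controller and the
muscles to reference gait trajectories with a two-stage evolution strategy.
This note records the model equations as implemented, the parameters that
matter, the numerical choices, and what the synthetic reference data do and
do not establish.

## Spiking-neuron controller

Every muscle is driven by one neuron unit representing the motor-neuron pool
of that muscle.  The unit is the two-variable quadratic integrate-and-fire
model

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u),        if v >= 30 mV:  v <- c,  u <- u + d,

integrated by forward Euler with 0.5 ms sub-steps inside each 5 ms physics
step (synchronous update: both derivatives are evaluated on the pre-step
state; a crossing is reset within the same sub-step, so no returned state
exceeds the threshold).  All units use the regular-spiking parameters
a = 0.02, b = 0.2, c = -65 mV, d = 8.  The resting state for these values is
(v, u) = (-70, -14).

The network has three layers: 2 input neurons (slope sensor, turn command),
16 central neurons, and 36 motor neurons.  Angles are encoded linearly as
currents, `I = theta / theta_max * I_max`, with I_max = 20 for both channels
and theta_max defaulting to 20 deg (slope) and 30 deg (turn); currents are
treated as one dimensionless drive quantity throughout.  Layers communicate
by per-physics-step spike indicators scaled by a synaptic gain (20 per unit
weight); weights are constrained to [0, 1].

Three wiring choices are ours (the layer diagram fixes none of them):

* **Baselines.**  Input neurons receive a tonic baseline drive (10) so the
  signed encoded currents modulate firing both up and down; without it a
  negative current is indistinguishable from zero.  Central neurons receive
  the same tonic baseline so the central->motor weights modulate around an
  operating point instead of gating an almost-silent layer.
* **Command sign.**  The turn-command current enters its input neuron with a
  negative sign: the neuron fires above baseline for leftward (negative)
  target orientations.  Excitatory-only synapses can only add drive, so each
  turn direction must be reachable by *increasing* some rate; this convention
  makes "turn left" recruit extra spikes on left-side motor columns, which is
  also the asymmetry reported for real fits of this model family.
* **Motor excitation signal.**  The excitation `v_t` passed to the muscle is
  a post-synaptic trace of the unit's spike train: +1 per spike, exponential
  decay with a 50 ms time constant, clipped to [0, 1].  We first evaluated
  normalising the membrane potential, `(v - c)/(v_thr - c)`, and rejected it
  on measurement: the quadratic membrane spends nearly all its time near
  rest, so the normalised mean is ~0.04 for any drive in [0, 20] — far too
  weak to develop muscle tone.  The trace rate-codes the drive (mean 0 ->
  0.84 as I goes 0 -> 20), so coordination is carried by spike counts.

The standard straight-walk pattern is produced without the weight matrices:
each motor unit has a bias current I (initially 10) gated by a firing window
[T_s, T_e) of the cycle.  Windows are stored relative to each unit's tripod
and shifted by the tripod phase (0 for left-front/right-middle/left-back,
0.5 for the other triad), reproducing the standard gate assignment
(0, 0.5) / (0.5, 1.0).

## Muscles

Activation follows the printed first-order law verbatim,
`a_{t+1} = (v_t - a_t) dt + a_t` with dt in seconds (a 1 s time constant),
clamped to [0, 1].  Contraction force is

    F_CE = F_max * a_t * F_L(L_ce) * F_V(V_ce)
    F_L  = exp(-|(L_ce^beta - 1)/omega|^rho)
    F_V  = (V_max - V_ce)/(V_max + c_V V_ce)        for V_ce <= 0 (shortening)
         = (b_V - a_V V_ce)/(b_V + V_ce)            for V_ce > 0,

with the muscle length lumped at rest (L_ce = 1) inside F_V so the velocity
coefficients collapse to the sums c_V and a_V.  Shortening is negative
velocity.  Initial values seed the optimisation: F_max = 1, beta = 1.5,
rho = 2.0, omega = 3.0, V_max = 5.0, c_V = -7.0, b_V = 0.67, a_V = -1.668.
Force is expressed in millinewtons: with 0.2 mm moment arms and a 24 mg
body, 1 mN is the scale at which single-leg ground reactions reach body
weight (~0.24 mN).  A non-positive F_V denominator is rejected as a
parameter-domain error.

The comparison actuator is a PD servo `tau = k_g (q_ref - q) + k_d qdot`
with the damping term *added*, as the source model family prints it; a
`damping_sign` switch restores conventional negative damping.  The servo is
a sensorimotor feedback loop, so it acts on the previous control tick's
measured joint state (one 5 ms step of sensory latency); the Hill muscle's
force-velocity response is intrinsic mechanics and is instantaneous.  In
the fitted comparison the servo's gain bounds ([0.02, 2] torque/rad,
damping [0, 0.5]) match the plant's ~0.1 mN*mm/rad muscle torque scale;
gains beyond ~0.6 ring through the delayed loop (the overshoot regime of
linear servos).

## Skeleton and kinematics

Trunk segments are boxes with the measured dimensions and masses (head
5.23 mg, thorax 3.87 mg, abdomen 11.35 mg); legs are capsule chains of
radius 0.2 mm with the measured per-position segment lengths and lumped
masses (0.60 / 0.50 / 0.70 mg per single leg; the printed mass-proportion
table is reproduced when legs are counted as left/right pairs, total
24.05 mg).  Each leg is actuated at the body-coxa (yaw), trochanter-femur
(levation) and femur-tibia (flexion) joints: 18 DOF.

Leg roots sit on the thorax at x = +1.2 / 0 / -1.2 mm, y = +/-0.5 mm, with
neutral splay angles 50 / 90 / 130 deg from the body axis.  The distal link
of the two-link planar sub-chain is the tibia plus half the tarsus: the
compliant tarsus drags rather than extending the column, and the half-length
contact point keeps the workspace annulus wide enough for the back legs'
stride excursions.  Closed-form IK (yaw bearing + two-link cosine rule, knee
folded downward) and an analytic Jacobian serve the whole pipeline; ground
forces map to joint torques by the Jacobian transpose.

Muscle attachments use 0.2 mm moment arms (segment-radius order), an
angle-to-length gain of 0.5 /rad, and rest angles centred on the standing
posture computed by IK from the neutral stance; joint limits are +/-60,
+/-60, +/-75 deg about those rest angles.

Working units are (mm, mg, mN, s), a consistent system with g = 9810 mm/s^2;
no boundary rescaling is needed because the reduced backend has no contact
solver with absolute tolerances.

## Reduced physics backend

The backend contract (deterministic stepping, per-foot ground reactions,
fail-at-startup) is pluggable; the shipped implementation is a reduced
deterministic model chosen for testability:

* **Massless stance transmission.**  Each stance leg's joint torques map to
  a ground force by `f = (J^T)^{-1} tau`, vertical component clamped >= 0
  (unilateral contact), magnitude capped at 5 body weights to keep
  near-singular postures finite.
* **Trunk translation.**  Horizontal dynamics integrate the summed
  reactions, slope-tilted gravity and viscous drag (1.2e-3 mN per mm/s, a
  50/s damping rate; locomotion at the millimetre scale is heavily damped).
  The drag is integrated implicitly so the rate is stable at the 5 ms step,
  and the joint velocity fed to the muscle force-velocity relation is
  low-passed at 30 ms (spindle-like smoothing) — with raw step-differenced
  closure rates the F_V feedback loop rings at the step frequency and puts
  a noise floor under the velocity objective.  A slope tilts gravity and is
  simultaneously encoded as the sensory current.
* **Damped-strut height.**  Height relaxes (rate 8/s times the deficit)
  toward the support equilibrium, where support = (active vertical force +
  passive share) / weight.  The passive share (90% of body weight whenever
  at least one leg is grounded) stands for passive joint stiffness and
  exoskeletal
  load-bearing — standing posture in insects is nearly free, and muscles
  mainly modulate support and propel.  The value also keeps the printed
  objective weights well-posed: with a substantially smaller share, static
  support demands near-maximal tonic currents and the energy term
  sum I^2 then makes collapsing cheaper than walking, inverting the fitness
  landscape.  A fully unactuated body still sinks and falls.
* **First-order yaw with a stance anchor.**  The yaw rate relaxes (0.5 s
  time constant) toward a target that combines the *propulsive side
  difference* of the stance forces (10 rad/s per mN — the body pivots
  toward the side pushing harder, as when the inside legs pull the heading
  around a turn) with a restoring term (rate 20/s) toward the heading held
  at the current stance set's touchdown: pinned feet resist body rotation.
  Each touchdown re-anchors at the yaw then reached, so a sustained drive
  asymmetry ratchets the heading cycle by cycle while the alternating
  tripod moment — which otherwise rectifies into an exponential heading
  drift — is absorbed completely (straight walks hold their heading to
  machine precision).

Legs in stance are dynamically actuated — their joint angles follow from the
kinematic closure between trunk pose and the pinned foot, and their torques
are transmitted to the ground; legs in swing are kinematically animated
along the reference trajectory (each leg carries ~5% of body mass).
Switching is driven by the reference phase flags.  A rollout terminates
early when the body centre drops below half the standing height.  Before the
rollout proper, two warm-up cycles let the network and the slow (1 s)
activation dynamics settle while the body stands; the animal walks from
standing tone, not from zero tone.

## Reference gait and deviation metric

The synthetic reference emulates captured strides of the double-tripod gait:
1 s cycle, duty factor 0.5, 4 mm stride, 0.8 mm swing clearance, 4 mm
stance radius, tripod phase offsets {0, 0.5}, 200 samples per cycle.  Stance
feet are exactly stationary in the world frame; swing feet travel a
half-ellipse; joint angles come from the leg IK; Gaussian jitter with a
seeded generator emulates inter-stride variability (jittered targets are
clamped onto the workspace boundary; noiseless out-of-reach specs fail
loudly, naming the offending field).  The implied body speed is
stride/(duty * period) = 8 mm/s — slow walking, chosen so that stride
excursions stay well inside every leg's workspace.

Trajectory deviation is the flat Euclidean norm between two joint channels
resampled to 100 uniform phase points per cycle, computed per joint (not
pooled); the ground-truth channel is the pointwise average of all reference
strides.

## Two-stage optimisation

Both stages use a hand-implemented standard (mu/mu_w, lambda) CMA-ES
(log-rank recombination weights, cumulative step-size adaptation, rank-one
plus rank-mu covariance updates, box constraints by projection).  Defaults
are lambda = 120, mu = 40; initial per-coordinate scales are 10% of the
bound widths unless stated.

**Stage I** (198 parameters = 18 left-right-symmetric units x (I, T_s, T_e +
8 Hill parameters)) fits straight walking.  The objective is

    f = w_s sum_k I^2 + w_v sum_k (nu - nu*)^2 + w_t sum_k (p_f - p_f*)^2

with w_s = 1.0, w_v = 10.0, w_t = 0.5; foot positions are compared in the
body frame, which makes the trajectory term translation-invariant.  Rollouts
that fall are charged for the missing steps as a stationary fallen body:
the velocity residual becomes the full ||nu*||^2 per step while the foot and
current residuals hold their last values, so falling is never cheaper than
walking.  (Holding the velocity residual too was tried first and rejected:
it rewards genomes that touch the target speed for one step and then
collapse.)  Bounds: I in [0, 20],
gates in [0, 1] (expanded windows are sorted and kept at least 0.01 wide),
muscle parameters within +/-50% of their initial values.  Gate parameters
are part of the genome by default (a flag freezes them at the tripod
defaults).

**Stage II** (608 parameters = 2x16 + 16x36 weights in [0, 1]) fits the
synaptic matrices with the Stage-I optimum fixed.  Scenarios (slope, target
orientation) are drawn uniformly from [-alpha theta_max, alpha theta_max]^2
with alpha stepping 0.2 -> 1.0, each phase warm-started from the previous
optimum; the fitness is the scenario sum of w_s f_s + w_v f_v.  The desired
velocity direction rotates by the target orientation once per cycle.  Two
numerical choices: scenarios are drawn once per alpha phase (common random
numbers make the within-phase objective deterministic, so convergence is
measurable), and the initial weight scale is 0.02 — the gated bias already
walks, so the network must start as a small modulation; 10%-of-range random
matrices destroy the gait so thoroughly that no selection gradient survives
at small population sizes.

Evaluations are deterministic given the genome, so reproducibility needs
only the master seed (scenario draws and CMA sampling derive from it).

## Problem sizes

The full-scale study conditions (lambda = 120, mu = 40, 100 s Stage-I and
10 s Stage-II rollouts, thousands of generations) are what the defaults
encode.  The shipped tests and the acceptance script run the identical
pipeline at desk scale.  Stage I runs lambda = 16 on 5 s rollouts for 90
generations in one pass: CMA-ES generations do not look ahead, so the
convergence claims made about a 30-generation run are read off the first 30
generations of its trace (bit-identical to a standalone run), while the
fully converged genome — the only one whose support margin survives the
10 s Stage-II horizon — feeds the later experiments.  Stage II runs
lambda = 30, mu = 10 for 8 generations on the full 10 s rollouts at
alpha = 0.2 with 2 scenarios: selection in 608 dimensions degenerates at
very small populations, and shorter rollouts leave the accumulated heading
error of a mis-steered body below inter-candidate noise, so Stage II trades
generations for population size rather than the reverse.  PD fitting uses
lambda = 8 for 10 generations (saturating for two parameters).  The checks
assert directional outcomes — fitness improves, best-so-far is monotone,
turning left recruits at least as many left-retractor spikes — rather than
the deviation values of the full study, which would additionally require
the real stride recordings.  One directional claim does not transfer to
this reduced plant: the fitted PD servo, a feedback tracker with direct
access to the reference joint trajectory, matches the protraction-axis
joint channel more closely than the open-loop rate-coded muscle drive
(the full-dynamics plant punishes servo stiffness through inertia and
contact; the massless transmission does not), so the per-joint
Hill-beats-PD ordering holds on the coxa-femur and femur-tibia channels
but reverses on body-coxa.

## What the synthetic data do and do not show

The generator reproduces the spatial-temporal structure the optimisation
consumes: tripod phasing, stationary stance feet, smooth swing arcs,
periodicity, realistic joint excursions (~20-40 deg).  It does not reproduce
posture adjustments of real ants, measurement noise correlated across
markers, speed modulation within and across strides, or ground-reaction
profiles of real substrate contact.  Consequently, passing tests establish
that the model and fitting machinery behave correctly and reproduce the
*relationships* reported for the real system (convergence, spike-count
lateralisation, Hill-vs-PD ordering), not that the fitted parameter values
would match those obtained from real recordings.

## Known limitations

* The reduced backend's yaw law and damped-strut support are phenomenological;
  a full rigid-body engine binding (the contract is pluggable) would replace
  both with contact dynamics.
* The tarsus is kinematically lumped (half-length contact point) and has no
  claw adhesion; self-collision is ignored.
* Muscles have no series/parallel elastic elements, pennation or tendon
  dynamics — a contractile element only.
* The activation law's 1 s time constant (printed form taken verbatim) is
  slow relative to the 1 s stride; muscle tone therefore modulates weakly
  within a cycle, and warm-up is required before rollouts.
* Chattering/bursting neuron regimes are available only by overriding the
  regular-spiking parameter set.
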
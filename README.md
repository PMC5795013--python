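# formica

A neuro-musculo-skeletal locomotion simulator for virtual ants.

Walking in insects emerges from the interplay of a spiking nervous system,
nonlinear muscle, and a lightweight articulated body.  `formica` implements
that chain end to end for a morphometrically accurate virtual ant and fits
its free parameters to reference gait data with an evolution strategy.  It
is aimed at researchers in computational neuroscience, biomechanics and
physics-based character animation who want a fully actuated, testable
insect model rather than a kinematic gait player.

## The model

* **Controller** — a network of Izhikevich neurons
  (`v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`, reset `v←c, u←u+d`
  at 30 mV; regular-spiking parameters a=0.02, b=0.2, c=−65, d=8).  Two
  input neurons encode the slope angle and the turn command as currents
  (`I = θ/θ_max · I_max`, I_max = 20); a 16-neuron central layer is fully
  connected to 36 motor neurons, one per muscle.  The standard double-tripod
  pattern comes from gated bias currents (windows [T_s, T_e) of the 1 s
  cycle, tripods half a cycle apart); the synaptic weights let the inputs
  modulate it.
* **Muscles** — Hill-type contractile elements per antagonistic pair:
  `F_CE = F_max · a_t · F_L(L_ce) · F_V(V_ce)` with
  `F_L = exp(−|(L^β−1)/ω|^ρ)` and the two-branch force–velocity hyperbola,
  plus first-order activation dynamics `a_{t+1} = (v_t − a_t)Δt + a_t`.
  A PD servo (`τ = k_g Δq + k_d q̇`) ships as the comparison actuator.
* **Skeleton** — head/thorax/abdomen boxes and six 3-DOF legs built from
  measured ant morphometry (24.05 mg total; leg masses counted as
  left/right pairs reproduce the published mass-proportion table).  Closed
  form IK/FK, analytic Jacobians, and Jacobian-transpose force/torque maps.
* **Optimisation** — two-stage CMA-ES: Stage I fits the 198 per-unit
  neuron+muscle parameters (18 left-right-symmetric units × 11) for straight
  walking against reference foot trajectories; Stage II fits the 608
  synaptic weights (2×16 + 16×36; 806 parameters in total) over scenario
  boxes `[−αθ_max, αθ_max]²` that widen as α steps 0.2 → 1.0.  The Stage-I
  objective is `f = ω_s Σ I² + ω_v Σ (ν−ν*)² + ω_t Σ (p_f−p_f*)²`
  (ω_s=1, ω_v=10, ω_t=0.5).

Rollouts run at a 5 ms physics step on a reduced deterministic backend
(massless stance-force transmission, damped-strut support, first-order yaw);
stance legs are dynamically actuated, swing legs kinematically animated, and
a run ends early if the body falls.  See `docs/methods.md` for every model
equation, default and design decision.

## Worked example

Fit the straight-walk parameters at desk scale and inspect the result:

```python
import formica as fm
from formica.optimization import (CMAConfig, StageSettings, Stage1Genome,
                                  run_stage1)

body = fm.build_body()
ref = fm.generate_reference_gait(fm.GaitSpec(), n_cycles=1, body=body)
result = run_stage1(body, ref,
                    CMAConfig(lam=16, mu=8, generations=30, seed=11),
                    StageSettings(rollout_s=5.0))
print(f"gen-0 best fitness {result.trace['best_f'].iloc[0]:.3g}")
print(f"fitted best fitness {result.best_f:.3g}")

bias, muscles = Stage1Genome.unpack(result.genome_vector).expand()
log = fm.simulate(body, fm.NetworkWeights.zeros(), bias, muscles, ref,
                  fm.SimulationConfig(duration_s=5.0))
print(f"rollout: {log.n_steps} steps, {log.termination_reason}, "
      f"mean forward speed {log.body_velocity[:, 0].mean():.2f} mm/s")
```

prints

```
gen-0 best fitness 1.72e+06
fitted best fitness 2.67e+05
rollout: 1000 steps, completed, mean forward speed 7.35 mm/s
```

The fitness drops six-fold over 30 generations as the evolution strategy
finds bias currents, firing windows and Hill parameters that keep the body
upright and walking near the 8 mm/s reference speed (continuing the same
run to 90 generations reaches ~5 × 10⁴; the residual is dominated by the
neural-energy term Σ I²).

The same pipeline is scriptable from the shell:

```
formica gen-fixtures --config run.yaml        # synthetic reference strides
formica optimize     --config run.yaml --stage 1 --seed 11
formica optimize     --config run.yaml --stage 2 --seed 12
formica simulate     --config run.yaml
formica compare      --config run.yaml        # Hill vs PD deviation table
formica plot         --config run.yaml --log-csv out/rollout.csv
```

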
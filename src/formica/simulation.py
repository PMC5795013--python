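"""Closed-loop locomotion rollouts.

One physics step (5 ms by default) runs the full control chain: the slope
angle and the target orientation are encoded as input currents, the spiking
network converts them — together with the gated bias currents that carry the
standard double-tripod pattern — into 36 motor excitations, first-order
activation dynamics turn excitations into muscle activations, Hill-type
contraction forces become joint torques through the attachment moment arms,
and the physics backend advances the trunk.

Stance and swing are hybrid: legs in stance are dynamically actuated (their
joint angles follow from the kinematic closure between the trunk pose and
the pinned foot, and their muscle torques are transmitted to the ground),
legs in swing are kinematically animated along the reference trajectory.
Switching is driven by the reference gait's phase flags.  A rollout stops
early when the body-centre height drops below a fraction of the standing
height.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import muscle as mu
from .gait import GaitTrajectory
from .neuro import (
    BiasCurrents,
    EncodingConfig,
    NetworkWeights,
    SpikingNetwork,
    encode_input,
    gate_mask,
    motor_unit_index,
)
from .skeleton import (
    BodyModel,
    LEG_NAMES,
    ReducedBackend,
    joint_torque_from_muscles,
    leg_foot_position,
    leg_ik,
    muscle_kinematics,
)

__all__ = [
    "SimulationConfig",
    "SimulationLog",
    "simulate",
    "gate_bias",
    "detect_fall",
    "extract_cycle_summaries",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Rollout configuration.

    ``target_speed_mm_s`` is the magnitude of the desired body-centre
    velocity (straight-forward vector for a zero target orientation; the
    desired heading rotates by ``target_deg`` per locomotion cycle when
    turning).  ``duration_s`` is ideally a multiple of the cycle period.
    """

    dt_s: float = 0.005
    duration_s: float = 10.0
    cycle_period_s: float = 1.0
    slope_deg: float = 0.0
    target_deg: float = 0.0
    target_speed_mm_s: float = 8.0
    fall_fraction: float = 0.5
    seed: int = 0
    actuator: str = "hill"  # "hill" or "pd"
    pd_params: mu.PDParams | None = None
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    #: cycles of network/activation settling with the body held standing
    #: before the rollout proper (the animal stands with tonic muscle tone
    #: before it starts to walk; activation has a 1 s time constant)
    warmup_cycles: float = 2.0
    #: time constant (s) of the low-pass on the joint velocity fed to the
    #: muscle force-velocity relation; raw step-differenced closure rates
    #: are impulsive at stance transitions and drive a discrete oscillation
    #: through the F_V feedback loop (muscle-spindle-like smoothing)
    qdot_filter_tau_s: float = 0.03
    #: sensory latency (s) of the PD servo's joint feedback: the servo is a
    #: sensorimotor loop and acts on the previous control tick's measured
    #: state (one 5 ms physics step by default; real proprioceptive loops
    #: lag at least this much).  The Hill muscle's force-velocity response
    #: is intrinsic mechanics and therefore instantaneous.
    pd_feedback_delay_s: float = 0.005

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.actuator not in ("hill", "pd"):
            raise ValueError("actuator must be 'hill' or 'pd'")
        if self.actuator == "pd" and self.pd_params is None:
            raise ValueError("PD actuator requires pd_params")


@dataclass
class SimulationLog:
    """Step-indexed record of a rollout (all series share the step index)."""

    time: np.ndarray  # (n,)
    body_position: np.ndarray  # (n, 3) mm
    body_velocity: np.ndarray  # (n, 3) mm/s
    yaw: np.ndarray  # (n,)
    joint_angles: np.ndarray  # (n, 6, 3) rad
    joint_torques: np.ndarray  # (n, 6, 3) mN*mm
    activations: np.ndarray  # (n, 36)
    motor_currents: np.ndarray  # (n, 36)
    motor_spikes: np.ndarray  # (n, 36) bool
    foot_body: np.ndarray  # (n, 6, 3) mm
    foot_world: np.ndarray  # (n, 6, 3) mm
    grf_z: np.ndarray  # (n, 6) mN, vertical ground reaction per foot
    stance: np.ndarray  # (n, 6) bool
    target_velocity: np.ndarray  # (n, 3) mm/s
    termination_reason: str  # "completed" or "fell"
    standing_height_mm: float
    dt_s: float
    cycle_period_s: float

    @property
    def n_steps(self) -> int:
        return self.time.size

    def to_csv(self, path) -> None:
        cols: dict[str, np.ndarray] = {"time": self.time, "yaw": self.yaw}
        for i, ax in enumerate("xyz"):
            cols[f"body_{ax}"] = self.body_position[:, i]
            cols[f"vel_{ax}"] = self.body_velocity[:, i]
        for leg_idx, leg in enumerate(LEG_NAMES):
            for j, jn in enumerate(("bc", "cf", "ft")):
                cols[f"q_{leg}_{jn}"] = self.joint_angles[:, leg_idx, j]
                cols[f"tau_{leg}_{jn}"] = self.joint_torques[:, leg_idx, j]
            cols[f"grf_z_{leg}"] = self.grf_z[:, leg_idx]
            cols[f"stance_{leg}"] = self.stance[:, leg_idx].astype(int)
        for u in range(36):
            cols[f"act_{u:02d}"] = self.activations[:, u]
            cols[f"spike_{u:02d}"] = self.motor_spikes[:, u].astype(int)
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")

    def write_manifest(self, path, config: dict, genome_hash: str | None = None) -> None:
        manifest = {
            "config": config,
            "genome_hash": genome_hash,
            "seed": config.get("seed"),
            "termination_reason": self.termination_reason,
            "n_steps": int(self.n_steps),
        }
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


def gate_bias(t_s: float, period_s: float, bias: BiasCurrents) -> np.ndarray:
    """Active-unit mask at absolute time ``t_s`` for a given cycle period."""
    if period_s <= 0:
        raise ValueError("period must be positive")
    return gate_mask(float(np.mod(t_s / period_s, 1.0)), bias)


def detect_fall(height_mm: float, standing_height_mm: float, fraction: float) -> bool:
    """True iff the body centre dropped below fraction * standing height."""
    if standing_height_mm <= 0:
        raise ValueError("standing height must be positive")
    return height_mm < fraction * standing_height_mm


def genome_digest(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for arr in arrays:
        h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _rotation_z(yaw: float) -> np.ndarray:
    c, s = np.cos(yaw), np.sin(yaw)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _hill_force_scalar(p: mu.MuscleParams, a_t: float, l_ce: float, v_ce: float) -> float:
    """Scalar fast path of the Hill product used in the inner rollout loop.

    Must stay numerically identical to
    ``muscle_force = F_max * a_t * force_length * force_velocity``; a test
    pins the equivalence.  Out-of-domain force-velocity denominators return
    zero force here (the rollout treats them as a slack muscle) instead of
    raising.
    """
    f_l = math.exp(-abs((l_ce**p.beta - 1.0) / p.omega) ** p.rho)
    if v_ce <= 0.0:
        den = p.v_max + p.c_v * v_ce
        if den <= 0.0:
            return 0.0
        f_v = (p.v_max - v_ce) / den
    else:
        den = p.b_v + v_ce
        if den <= 0.0:
            return 0.0
        f_v = (p.b_v - p.a_v * v_ce) / den
    return p.f_max * a_t * f_l * f_v


def simulate(
    body: BodyModel,
    weights: NetworkWeights,
    bias: BiasCurrents,
    muscles: list[mu.MuscleParams],
    ref: GaitTrajectory,
    cfg: SimulationConfig,
) -> SimulationLog:
    """Run one closed-loop rollout and log everything.

    ``muscles`` lists 36 parameter sets in motor-unit order (see
    :func:`formica.neuro.motor_unit_index`).  The reference trajectory
    provides the stance/swing phase flags, the kinematic swing targets, and
    the touchdown geometry.
    """
    if len(muscles) != 36:
        raise ValueError(f"expected 36 muscle parameter sets, got {len(muscles)}")
    n_steps = int(round(cfg.duration_s / cfg.dt_s))
    dt, period = cfg.dt_s, cfg.cycle_period_s
    enc = cfg.encoding

    theta_s = float(np.clip(cfg.slope_deg, -enc.theta_max_s, enc.theta_max_s))
    theta_t = float(np.clip(cfg.target_deg, -enc.theta_max_t, enc.theta_max_t))
    i_sensor = encode_input(theta_s, "sensor", enc)
    i_target = encode_input(theta_t, "target", enc)

    network = SpikingNetwork(weights, bias)
    backend = ReducedBackend(body, dt_s=dt, slope_deg=cfg.slope_deg)
    state = backend.reset()
    activation = np.zeros(36)

    # settle the network and muscle tone while standing still
    warmup_steps = int(round(cfg.warmup_cycles * period / dt))
    steps_per_cycle_w = max(int(round(period / dt)), 1)
    for k in range(warmup_steps):
        phase = (k % steps_per_cycle_w) / steps_per_cycle_w
        net = network.step(i_sensor, i_target, phase, dt * 1e3)
        activation = np.clip((net.excitations - activation) * dt + activation, 0.0, 1.0)

    # pre-computed reference templates on the step grid of one cycle
    steps_per_cycle = max(int(round(period / dt)), 1)
    phases = np.arange(steps_per_cycle) / steps_per_cycle
    ref_stance = np.array([ref.stance_at(p) for p in phases])
    ref_q = np.array([ref.q_at(p) for p in phases])
    ref_foot = np.array([ref.foot_at(p) for p in phases])

    # initial stance pins from the reference touchdown geometry
    rot = _rotation_z(state.yaw)
    pins: dict[int, np.ndarray] = {}
    q_prev = np.zeros((6, 3))
    qdot_filt = np.zeros((6, 3))
    alpha_qdot = dt / max(cfg.qdot_filter_tau_s, dt)
    stance_now = ref_stance[0]
    anchor_yaw = state.yaw
    # delayed joint-angle ring buffer for the PD servo's sensory feedback
    delay_steps = max(int(round(cfg.pd_feedback_delay_s / dt)), 0)
    q_hist = [ref_q[0].copy() for _ in range(delay_steps + 1)]
    for leg_idx in range(6):
        q_prev[leg_idx] = ref_q[0, leg_idx]
        if stance_now[leg_idx]:
            pins[leg_idx] = state.position + rot @ ref_foot[0, leg_idx]

    # yaw-rate target: desired heading advances by -target_deg per cycle
    # (negative target orientation = turn left = positive yaw)
    heading_rate = -np.deg2rad(cfg.target_deg) / period

    log = {
        name: np.zeros(shape)
        for name, shape in {
            "time": (n_steps,),
            "body_position": (n_steps, 3),
            "body_velocity": (n_steps, 3),
            "yaw": (n_steps,),
            "joint_angles": (n_steps, 6, 3),
            "joint_torques": (n_steps, 6, 3),
            "activations": (n_steps, 36),
            "motor_currents": (n_steps, 36),
            "foot_body": (n_steps, 6, 3),
            "foot_world": (n_steps, 6, 3),
            "grf_z": (n_steps, 6),
            "target_velocity": (n_steps, 3),
        }.items()
    }
    log["motor_spikes"] = np.zeros((n_steps, 36), dtype=bool)
    log["stance"] = np.zeros((n_steps, 6), dtype=bool)

    reason = "completed"
    n_logged = 0
    prev_stance = stance_now
    for k in range(n_steps):
        t = k * dt
        cyc_idx = k % steps_per_cycle
        phase = phases[cyc_idx]
        stance_now = ref_stance[cyc_idx]
        rot = _rotation_z(state.yaw)

        # stance/swing transitions: pin at touchdown, release at lift-off;
        # any touchdown re-anchors the heading the stance set holds
        for leg_idx in range(6):
            if stance_now[leg_idx] and not prev_stance[leg_idx]:
                pins[leg_idx] = state.position + rot @ ref_foot[cyc_idx, leg_idx]
                qdot_filt[leg_idx] = 0.0  # fresh contact: no carried-over rate
                anchor_yaw = state.yaw
            elif not stance_now[leg_idx] and prev_stance[leg_idx]:
                pins.pop(leg_idx, None)
        prev_stance = stance_now

        net = network.step(i_sensor, i_target, float(phase), dt * 1e3)
        activation = np.clip((net.excitations - activation) * dt + activation, 0.0, 1.0)

        q_now = np.zeros((6, 3))
        tau_now = np.zeros((6, 3))
        foot_b = np.zeros((6, 3))
        foot_w = np.zeros((6, 3))
        stance_inputs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for leg_idx, leg in enumerate(body.legs):
            if stance_now[leg_idx]:
                p_body = rot.T @ (pins[leg_idx] - state.position)
                q = leg_ik(leg, p_body, clamp=True)
                qdot_raw = (q - q_prev[leg_idx]) / dt
                qdot_filt[leg_idx] += alpha_qdot * (qdot_raw - qdot_filt[leg_idx])
                qdot = qdot_filt[leg_idx]
                tau = np.zeros(3)
                for j in range(3):
                    att = body.attachments[leg_idx][j]
                    if cfg.actuator == "hill":
                        (l_a, v_a), (l_n, v_n) = muscle_kinematics(att, q[j], qdot[j])
                        ua = motor_unit_index(leg_idx, j, 0)
                        un = motor_unit_index(leg_idx, j, 1)
                        f_a = _hill_force_scalar(
                            muscles[ua], activation[ua], max(l_a, 1e-6), v_a
                        )
                        f_n = _hill_force_scalar(
                            muscles[un], activation[un], max(l_n, 1e-6), v_n
                        )
                        tau[j] = joint_torque_from_muscles(att, f_a, f_n)
                    else:
                        q_ref_next = ref_q[(cyc_idx + 1) % steps_per_cycle, leg_idx, j]
                        if delay_steps > 0:
                            q_fb = q_hist[0][leg_idx, j]
                            qd_fb = (q_hist[1][leg_idx, j] - q_hist[0][leg_idx, j]) / dt
                        else:
                            q_fb, qd_fb = q[j], qdot[j]
                        tau[j] = mu.pd_torque(q_ref_next, q_fb, qd_fb, cfg.pd_params)
                stance_inputs[leg_idx] = (q, tau)
                q_now[leg_idx] = q
                tau_now[leg_idx] = tau
                foot_b[leg_idx] = p_body
                foot_w[leg_idx] = pins[leg_idx]
            else:
                q = ref_q[cyc_idx, leg_idx]
                q_now[leg_idx] = q
                foot_b[leg_idx] = leg_foot_position(leg, q)
                foot_w[leg_idx] = state.position + rot @ foot_b[leg_idx]
            q_prev[leg_idx] = q_now[leg_idx]

        if delay_steps > 0:  # advance the proprioceptive ring buffer
            q_hist.pop(0)
            q_hist.append(q_now.copy())

        state, grf = backend.step(state, stance_inputs, anchor_yaw=anchor_yaw)

        log["time"][k] = t
        log["body_position"][k] = state.position
        log["body_velocity"][k] = state.velocity
        log["yaw"][k] = state.yaw
        log["joint_angles"][k] = q_now
        log["joint_torques"][k] = tau_now
        log["activations"][k] = activation
        log["motor_currents"][k] = net.motor_currents
        log["motor_spikes"][k] = net.motor_spikes
        log["foot_body"][k] = foot_b
        log["foot_world"][k] = foot_w
        for leg_idx, f in grf.items():
            log["grf_z"][k, leg_idx] = f[2]
        log["stance"][k] = stance_now
        heading = heading_rate * t
        log["target_velocity"][k] = cfg.target_speed_mm_s * np.array(
            [np.cos(heading), np.sin(heading), 0.0]
        )
        n_logged = k + 1

        if detect_fall(state.position[2], backend.standing_height, cfg.fall_fraction):
            reason = "fell"
            break

    sl = slice(0, n_logged)
    return SimulationLog(
        time=log["time"][sl],
        body_position=log["body_position"][sl],
        body_velocity=log["body_velocity"][sl],
        yaw=log["yaw"][sl],
        joint_angles=log["joint_angles"][sl],
        joint_torques=log["joint_torques"][sl],
        activations=log["activations"][sl],
        motor_currents=log["motor_currents"][sl],
        motor_spikes=log["motor_spikes"][sl],
        foot_body=log["foot_body"][sl],
        foot_world=log["foot_world"][sl],
        grf_z=log["grf_z"][sl],
        stance=log["stance"][sl],
        target_velocity=log["target_velocity"][sl],
        termination_reason=reason,
        standing_height_mm=backend.standing_height,
        dt_s=dt,
        cycle_period_s=period,
    )


def extract_cycle_summaries(log: SimulationLog, period_s: float | None = None) -> dict:
    """Phase-aligned per-cycle summaries of a rollout.

    Returns cycle-averaged joint-angle / torque / vertical-ground-force
    curves on the step grid of one cycle, per-muscle spike counts for each
    complete cycle, and the stance mask isolating the stance-stage windows
    of the torque and force curves.
    """
    period = period_s or log.cycle_period_s
    spc = int(round(period / log.dt_s))
    n_cycles = log.n_steps // spc
    if n_cycles < 1:
        raise ValueError("log spans less than one full locomotion cycle")
    n = n_cycles * spc

    def cyc(arr: np.ndarray) -> np.ndarray:
        return arr[:n].reshape((n_cycles, spc) + arr.shape[1:])

    return {
        "n_cycles": n_cycles,
        "phase": np.arange(spc) / spc,
        "joint_angle_curves": cyc(log.joint_angles).mean(axis=0),
        "torque_curves": cyc(log.joint_torques).mean(axis=0),
        "grf_curves": cyc(log.grf_z).mean(axis=0),
        "spike_counts": cyc(log.motor_spikes).sum(axis=1),
        "stance_mask": cyc(log.stance)[0],
    }
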
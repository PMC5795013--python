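"""Spiking-neuron control layer.

The controller is a small network of Izhikevich neurons: two input neurons
encode the slope angle (sensory information) and the target orientation for
the next stride (high-level command) as input currents; a central layer of 16
neurons redistributes those spikes; and 36 motor neurons — one per muscle —
turn gated bias currents plus the central-layer offsets into the excitation
signal that drives muscle activation.

The unit model is the two-variable quadratic integrate-and-fire neuron

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with the after-spike reset ``v <- c``, ``u <- u + d`` whenever ``v`` reaches
the 30 mV threshold.  All units use the regular-spiking parameter set
(a=0.02, b=0.2, c=-65, d=8).  Integration is forward Euler with 0.5 ms
sub-steps inside each 5 ms physics step.

Currents are treated as one dimensionless drive quantity throughout (the
encoding and the bias drive share a common 0-20 scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "EncodingConfig",
    "NetworkWeights",
    "BiasCurrents",
    "SpikingNetwork",
    "NetworkStepResult",
    "NumericalInstabilityError",
    "InputRangeError",
    "step_neuron",
    "encode_input",
    "propagate_spikes",
    "gate_mask",
    "spike_count",
]

#: number of central-layer neurons
N_CENTRAL = 16
#: number of motor units (one per muscle: 6 legs x 3 joints x 2 muscles)
N_MOTOR = 36
#: number of input-layer neurons (slope sensor, target command)
N_INPUT = 2

#: default Euler sub-step (ms); the physics step is an integer multiple
DT_SUBSTEP_MS = 0.5

#: synaptic current injected per pre-synaptic spike at weight 1.0
SYNAPTIC_GAIN = 20.0
#: tonic drive of the input-layer neurons, so that signed encoded currents
#: modulate their firing rate in both directions
INPUT_BASELINE_CURRENT = 10.0
#: tonic drive of the central-layer neurons: gives them a baseline firing
#: rate that the input-layer synapses modulate, so weighted central->motor
#: offsets scale smoothly with the encoded inputs around an operating point
CENTRAL_BASELINE_CURRENT = 10.0


def motor_unit_index(leg_idx: int, joint_idx: int, muscle_idx: int) -> int:
    """Flat motor-unit index: legs (LF,LM,LB,RF,RM,RB) x joints
    (body-coxa, coxa-femur, femur-tibia) x muscles (agonist, antagonist)."""
    return leg_idx * 6 + joint_idx * 2 + muscle_idx


class NumericalInstabilityError(RuntimeError):
    """A membrane state or current became non-finite."""


class InputRangeError(ValueError):
    """An encoded angle exceeds its configured maximum; clamp explicitly."""


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters (dimensionless except the mV reset/threshold)."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_threshold: float = 30.0

    @classmethod
    def regular_spiking(cls) -> "NeuronParams":
        return cls()


@dataclass
class NeuronState:
    """Membrane potential ``v`` (mV) and recovery variable ``u``."""

    v: float
    u: float

    @classmethod
    def rest(cls, params: NeuronParams | None = None) -> "NeuronState":
        """Resting fixed point: 0.04 v^2 + 5 v + 140 - u = 0 with u = b v."""
        p = params or NeuronParams.regular_spiking()
        # 0.04 v^2 + (5 - b) v + 140 = 0, stable (more negative) root
        disc = (5.0 - p.b) ** 2 - 4.0 * 0.04 * 140.0
        if disc < 0:
            raise ValueError("no real resting potential for these parameters")
        v = (-(5.0 - p.b) - np.sqrt(disc)) / (2.0 * 0.04)
        return cls(v=float(v), u=float(p.b * v))


@dataclass(frozen=True)
class EncodingConfig:
    """Linear angle-to-current encoding ranges.

    theta_max_s / theta_max_t are the maximum slope angle and target
    orientation (degrees); i_max_s / i_max_t the corresponding maximum
    input currents (both default 20).
    """

    theta_max_s: float = 20.0
    theta_max_t: float = 30.0
    i_max_s: float = 20.0
    i_max_t: float = 20.0

    def __post_init__(self) -> None:
        if self.theta_max_s <= 0 or self.theta_max_t <= 0:
            raise ValueError("theta_max_s and theta_max_t must be positive")


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    current: float,
    dt_ms: float,
) -> tuple[NeuronState, bool]:
    """Advance one Euler sub-step; returns (new state, spiked flag).

    ``dt_ms`` must not exceed 1 ms (sub-stepping contract).  A state already
    at or above threshold is reset without integrating.  A state that crosses
    threshold during the step is reset in the same call, so no returned state
    ever exceeds the threshold.
    """
    if not (0.0 < dt_ms <= 1.0):
        raise ValueError(f"dt_ms must be in (0, 1] ms, got {dt_ms}")
    if not (np.isfinite(state.v) and np.isfinite(state.u) and np.isfinite(current)):
        raise NumericalInstabilityError(
            f"non-finite neuron input: v={state.v}, u={state.u}, I={current}"
        )
    if state.v >= params.v_threshold:
        return NeuronState(v=params.c, u=state.u + params.d), True
    v, u = state.v, state.u
    v_new = v + dt_ms * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
    u_new = u + dt_ms * params.a * (params.b * v - u)
    if not (np.isfinite(v_new) and np.isfinite(u_new)):
        raise NumericalInstabilityError("neuron state diverged during integration")
    if v_new >= params.v_threshold:
        return NeuronState(v=params.c, u=u_new + params.d), True
    return NeuronState(v=v_new, u=u_new), False


try:  # compiled kernel for the inner integration loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


def _layer_kernel_py(v, u, currents, spiked, n_sub, dt_ms, a, b, c, d, thr):
    # identical floating-point operation order to the numpy path below
    for i in range(v.shape[0]):
        vi, ui, ci = v[i], u[i], currents[i]
        if vi >= thr:
            vi = c
            ui = ui + d
            spiked[i] = True
        for _ in range(n_sub):
            dv = dt_ms * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + ci)
            ui = ui + dt_ms * a * (b * vi - ui)
            vi = vi + dv
            if vi >= thr:
                vi = c
                ui = ui + d
                spiked[i] = True
        v[i] = vi
        u[i] = ui


if _HAVE_NUMBA:
    _layer_kernel = _njit(cache=True)(_layer_kernel_py)
else:  # pragma: no cover
    _layer_kernel = _layer_kernel_py


def _step_layer(
    v: np.ndarray,
    u: np.ndarray,
    params: NeuronParams,
    currents: np.ndarray,
    n_sub: int,
    dt_ms: float,
) -> np.ndarray:
    """Vectorised Euler sub-stepping of one neuron layer, in place.

    Same per-sub-step semantics as :func:`step_neuron`.  Returns a boolean
    array flagging units that spiked at least once during the window.
    """
    spiked = np.zeros(v.shape[0], dtype=np.bool_)
    currents = np.broadcast_to(np.asarray(currents, dtype=float), v.shape).copy()
    _layer_kernel(
        v, u, currents, spiked, n_sub, dt_ms,
        params.a, params.b, params.c, params.d, params.v_threshold,
    )
    if not np.isfinite(v).all() or not np.isfinite(u).all():
        raise NumericalInstabilityError("network layer state diverged")
    return spiked


def encode_input(theta_deg: float, kind: str, cfg: EncodingConfig) -> float:
    """Encode an angle as an input current: theta / theta_max * I_max.

    Linear and sign-preserving; ``kind`` is ``"sensor"`` (slope) or
    ``"target"`` (orientation command).  Out-of-range angles raise
    :class:`InputRangeError` — callers clamp explicitly.
    """
    if kind == "sensor":
        theta_max, i_max = cfg.theta_max_s, cfg.i_max_s
    elif kind == "target":
        theta_max, i_max = cfg.theta_max_t, cfg.i_max_t
    else:
        raise ValueError(f"kind must be 'sensor' or 'target', got {kind!r}")
    if abs(theta_deg) > theta_max:
        raise InputRangeError(
            f"|theta|={abs(theta_deg)} exceeds theta_max={theta_max} for {kind}"
        )
    return theta_deg / theta_max * i_max


@dataclass
class NetworkWeights:
    """Synaptic gains: input->central (2x16) and central->motor (16x36).

    All weights live in [0, 1].
    """

    w_in: np.ndarray
    w_out: np.ndarray

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_in.shape != (N_INPUT, N_CENTRAL):
            raise ValueError(
                f"w_in must have shape {(N_INPUT, N_CENTRAL)}, got {self.w_in.shape}"
            )
        if self.w_out.shape != (N_CENTRAL, N_MOTOR):
            raise ValueError(
                f"w_out must have shape {(N_CENTRAL, N_MOTOR)}, got {self.w_out.shape}"
            )
        if (self.w_in < 0).any() or (self.w_in > 1).any() or (
            self.w_out < 0
        ).any() or (self.w_out > 1).any():
            raise ValueError("synaptic weights must lie in [0, 1]")

    @classmethod
    def zeros(cls) -> "NetworkWeights":
        return cls(np.zeros((N_INPUT, N_CENTRAL)), np.zeros((N_CENTRAL, N_MOTOR)))

    def to_json(self, path) -> None:
        payload = {
            "w_in": {"shape": list(self.w_in.shape), "data": self.w_in.ravel().tolist()},
            "w_out": {
                "shape": list(self.w_out.shape),
                "data": self.w_out.ravel().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NetworkWeights":
        with open(path) as fh:
            payload = json.load(fh)
        w_in = np.array(payload["w_in"]["data"]).reshape(payload["w_in"]["shape"])
        w_out = np.array(payload["w_out"]["data"]).reshape(payload["w_out"]["shape"])
        return cls(w_in, w_out)


@dataclass
class BiasCurrents:
    """Per-motor-unit bias amplitudes with cycle-fraction firing windows.

    ``t_s``/``t_e`` are the canonical gate window of each unit relative to its
    own tripod phase; ``phase_offset`` (0 for the left-front/right-middle/
    left-back tripod, 0.5 for the other) shifts the window to absolute cycle
    phase.  A unit is active at cycle fraction ``p`` iff
    ``(p - phase_offset) mod 1`` lies in ``[t_s, t_e)``.
    """

    i_s: np.ndarray
    t_s: np.ndarray
    t_e: np.ndarray
    phase_offset: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.i_s = np.asarray(self.i_s, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.t_e = np.asarray(self.t_e, dtype=float)
        if self.phase_offset is None:
            self.phase_offset = np.zeros_like(self.i_s)
        self.phase_offset = np.asarray(self.phase_offset, dtype=float)
        n = self.i_s.shape[0]
        for name, arr in (
            ("t_s", self.t_s),
            ("t_e", self.t_e),
            ("phase_offset", self.phase_offset),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if (self.t_s < 0).any() or (self.t_e > 1).any() or (self.t_s >= self.t_e).any():
            raise ValueError("gate windows must satisfy 0 <= T_s < T_e <= 1")

    def absolute_gates(self) -> tuple[np.ndarray, np.ndarray]:
        """Gate windows on the absolute cycle axis (may wrap past 1)."""
        return self.t_s + self.phase_offset, self.t_e + self.phase_offset


def gate_mask(t_phase: float, bias: BiasCurrents) -> np.ndarray:
    """Boolean mask of units whose firing window contains ``t_phase``."""
    rel = np.mod(t_phase - bias.phase_offset, 1.0)
    return (rel >= bias.t_s) & (rel < bias.t_e)


def propagate_spikes(weights: np.ndarray, spikes: np.ndarray, gain: float = SYNAPTIC_GAIN) -> np.ndarray:
    """Current offsets from a layer's spike indicators: gain * spikes @ W."""
    return gain * (np.asarray(spikes, dtype=float) @ np.asarray(weights, dtype=float))


class NetworkStepResult(NamedTuple):
    excitations: np.ndarray     # (36,) motor excitation v_t, in [0, 1]
    motor_currents: np.ndarray  # (36,) total injected current per motor unit
    input_spikes: np.ndarray    # (2,) bool
    central_spikes: np.ndarray  # (16,) bool
    motor_spikes: np.ndarray    # (36,) bool


class SpikingNetwork:
    """The input -> central -> motor spiking network.

    Layers are advanced sequentially within each physics step: the input
    layer integrates the encoded currents (on top of a tonic baseline), its
    per-step spike indicators drive the central layer through ``w_in``, and
    the central indicators plus the gated bias currents drive the motor
    layer through ``w_out``.

    The motor excitation returned for each muscle is a post-synaptic
    excitation trace of that unit's spike train: a unit jump per spike with
    exponential decay (time constant ``excitation_tau_s``, default 50 ms),
    clipped to [0, 1].  This rate-codes the drive — a muscle receives more
    sustained excitation when its neuron emits more spike trains — which is
    what lets the controller coordinate legs by spike count.  (Normalising
    the membrane potential instead was rejected: the quadratic membrane
    spends nearly all its time near rest, so its time average is ~0.04
    regardless of drive, far too weak to develop muscle tone.)
    """

    def __init__(
        self,
        weights: NetworkWeights,
        bias: BiasCurrents,
        params: NeuronParams | None = None,
        dt_substep_ms: float = DT_SUBSTEP_MS,
        synaptic_gain: float = SYNAPTIC_GAIN,
        input_baseline: float = INPUT_BASELINE_CURRENT,
        central_baseline: float = CENTRAL_BASELINE_CURRENT,
        excitation_tau_s: float = 0.05,
    ) -> None:
        if bias.i_s.shape != (N_MOTOR,):
            raise ValueError(f"bias currents must have shape ({N_MOTOR},)")
        if not (0.0 < dt_substep_ms <= 1.0):
            raise ValueError("dt_substep_ms must be in (0, 1] ms")
        self.weights = weights
        self.bias = bias
        self.params = params or NeuronParams.regular_spiking()
        self.dt_substep_ms = dt_substep_ms
        self.synaptic_gain = synaptic_gain
        self.input_baseline = input_baseline
        self.central_baseline = central_baseline
        self.excitation_tau_s = excitation_tau_s
        rest = NeuronState.rest(self.params)
        n_total = N_INPUT + N_CENTRAL + N_MOTOR
        self._v = np.full(n_total, rest.v)
        self._u = np.full(n_total, rest.u)
        self._trace = np.zeros(N_MOTOR)

    def _slices(self):
        return (
            slice(0, N_INPUT),
            slice(N_INPUT, N_INPUT + N_CENTRAL),
            slice(N_INPUT + N_CENTRAL, None),
        )

    def step(
        self,
        sensor_current: float,
        target_current: float,
        t_phase: float,
        dt_ms: float = 5.0,
    ) -> NetworkStepResult:
        if not (0.0 <= t_phase < 1.0):
            raise ValueError(f"t_phase must be in [0, 1), got {t_phase}")
        n_sub = int(round(dt_ms / self.dt_substep_ms))
        if n_sub < 1 or abs(n_sub * self.dt_substep_ms - dt_ms) > 1e-9:
            raise ValueError("dt_ms must be an integer multiple of the sub-step")
        s_in, s_ce, s_mo = self._slices()
        p, dt = self.params, self.dt_substep_ms

        # Wiring convention: the slope neuron fires above baseline when the
        # terrain rises (more propulsion needed), and the command neuron
        # fires above baseline for leftward (negative) target orientations.
        # Excitatory-only synapses can then realise either turn by placing
        # weight on the matching side's motor columns.
        i_input = self.input_baseline + np.array([sensor_current, -target_current])
        input_spikes = _step_layer(self._v[s_in], self._u[s_in], p, i_input, n_sub, dt)

        i_central = self.central_baseline + propagate_spikes(
            self.weights.w_in, input_spikes, self.synaptic_gain
        )
        central_spikes = _step_layer(
            self._v[s_ce], self._u[s_ce], p, i_central, n_sub, dt
        )

        gated = gate_mask(t_phase, self.bias)
        offsets = propagate_spikes(self.weights.w_out, central_spikes, self.synaptic_gain)
        motor_currents = np.where(gated, self.bias.i_s, 0.0) + offsets
        motor_spikes = _step_layer(
            self._v[s_mo], self._u[s_mo], p, motor_currents, n_sub, dt
        )

        decay = np.exp(-dt_ms * 1e-3 / self.excitation_tau_s)
        self._trace = np.clip(self._trace * decay + motor_spikes, 0.0, 1.0)
        excitations = self._trace.copy()
        return NetworkStepResult(
            excitations=excitations,
            motor_currents=motor_currents,
            input_spikes=input_spikes,
            central_spikes=central_spikes,
            motor_spikes=motor_spikes,
        )


def spike_count(spike_train) -> int:
    """Number of spikes in a boolean spike train over a window."""
    train = np.asarray(spike_train)
    if train.size == 0:
        raise ValueError("spike train window must be non-empty")
    return int(np.count_nonzero(train))
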
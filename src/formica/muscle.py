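"""Hill-type muscle actuation and the PD-servo baseline.

Each joint is driven by an antagonistic pair of muscles.  A muscle converts
the motor-neuron excitation ``v_t`` into an activation ``a_t`` through a
first-order filter,

    a_{t+1} = (v_t - a_t) * dt + a_t,

and produces the contractile force

    F_CE = F_max * a_t * F_L(L_ce) * F_V(V_ce),

where the force-length factor is ``F_L = exp(-|(L_ce^beta - 1)/omega|^rho)``
and the force-velocity factor is the usual two-branch Hill hyperbola with the
muscle length lumped at its rest value (L_ce = 1) inside F_V, so the
shortening and lengthening coefficients collapse to ``c_V = c_V0 + c_V1`` and
``a_V = a_V0 + a_V1 + a_V2``.  Shortening is the ``V_ce <= 0`` branch.

Force is expressed in millinewtons: with the 0.2 mm moment arms and the
milligram-scale body of the modelled ant, a peak isometric force of order
1 mN puts single-leg ground reactions at the scale of the body weight
(~0.24 mN), which is the physiologically sensible regime.

The PD servo used as the comparison actuator implements

    tau = k_g (q_{t+1} - q_t) + k_d qdot_t

with the damping term added (not subtracted) by default; a sign switch
restores the conventional negative-feedback damping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "MuscleParams",
    "MuscleState",
    "PDParams",
    "ParameterDomainError",
    "update_activation",
    "force_length",
    "force_velocity",
    "muscle_force",
    "pd_torque",
]


class ParameterDomainError(ValueError):
    """A force-velocity denominator left the valid (positive) domain."""


@dataclass(frozen=True)
class MuscleParams:
    """Hill parameter set Omega = (F_max, beta, rho, omega, V_max, c_V, b_V, a_V).

    Defaults are the initial values used to seed the evolutionary fit.
    F_max is in millinewtons; lengths are normalised to the rest length and
    velocities to rest lengths per second.
    """

    f_max: float = 1.0
    beta: float = 1.5
    rho: float = 2.0
    omega: float = 3.0
    v_max: float = 5.0
    c_v: float = -7.0
    b_v: float = 0.67
    a_v: float = -1.668

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError("F_max must be positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.v_max <= 0:
            raise ValueError("V_max must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"muscle": self.__dict__.copy()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "MuscleParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload["muscle"])


@dataclass
class MuscleState:
    """Activation plus normalised contractile length/velocity."""

    a_t: float = 0.0
    l_ce: float = 1.0
    v_ce: float = 0.0


@dataclass(frozen=True)
class PDParams:
    """PD-servo gain and damping; ``damping_sign=+1`` matches the printed
    servo law, ``-1`` the conventional negative damping."""

    k_g: float
    k_d: float
    damping_sign: float = 1.0

    def __post_init__(self) -> None:
        if self.k_g <= 0:
            raise ValueError("k_g must be positive")


def update_activation(a_t: float, v_t: float, dt_s: float) -> float:
    """First-order activation update, clamped to [0, 1]."""
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    return float(np.clip((v_t - a_t) * dt_s + a_t, 0.0, 1.0))


def force_length(l_ce, p: MuscleParams):
    """Force-length factor exp(-|(L^beta - 1)/omega|^rho); in (0, 1]."""
    l_ce = np.asarray(l_ce, dtype=float)
    if (l_ce <= 0).any() if l_ce.ndim else l_ce <= 0:
        raise ValueError("L_ce must be positive")
    out = np.exp(-np.abs((l_ce**p.beta - 1.0) / p.omega) ** p.rho)
    return float(out) if out.ndim == 0 else out


def force_velocity(v_ce, p: MuscleParams):
    """Two-branch force-velocity factor, continuous (value 1) at V_ce = 0.

    Shortening branch (V_ce <= 0): (V_max - V_ce) / (V_max + c_V V_ce).
    Lengthening branch (V_ce > 0): (b_V - a_V V_ce) / (b_V + V_ce).
    A non-positive denominator is a parameter-domain error rather than a
    negative or singular force.
    """
    v_ce = np.asarray(v_ce, dtype=float)
    den_short = p.v_max + p.c_v * v_ce
    den_long = p.b_v + v_ce
    short = v_ce <= 0
    bad = (short & (den_short <= 0)) | (~short & (den_long <= 0))
    if bad.any() if bad.ndim else bad:
        raise ParameterDomainError(
            "force-velocity denominator is non-positive for this V_ce"
        )
    out = np.where(
        short,
        (p.v_max - v_ce) / np.where(short, den_short, 1.0),
        (p.b_v - p.a_v * v_ce) / np.where(short, 1.0, den_long),
    )
    return float(out) if out.ndim == 0 else out


def muscle_force(p: MuscleParams, a_t: float, l_ce: float, v_ce: float) -> float:
    """Contractile force F_CE = F_max * a_t * F_L * F_V (millinewtons)."""
    if not 0.0 <= a_t <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    return p.f_max * a_t * force_length(l_ce, p) * force_velocity(v_ce, p)


def pd_torque(q_target: float, q_t: float, qdot_t: float, p: PDParams) -> float:
    """Servo torque k_g (q_target - q_t) + sign * k_d qdot_t."""
    return p.k_g * (q_target - q_t) + p.damping_sign * p.k_d * qdot_t
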
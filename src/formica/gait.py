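"""Reference gait trajectories: synthesis, statistics and the deviation metric.

The reference data stand in for motion-captured strides of freely walking
ants.  The generator emulates the double-tripod gait: the left-front,
right-middle and left-back legs step in phase, the opposite triad half a
cycle later.  During stance a foot stays put on the ground (so, relative to
the advancing body, it travels backward on a straight line at
``stride / (duty * period)``); during swing it returns along a smooth
half-elliptic arc with a given clearance.  Joint angles are recovered from
the foot path by per-leg inverse kinematics, and optional Gaussian jitter
emulates measurement noise and inter-stride variability.

Trajectory deviation between a ground-truth and a simulated joint channel is
the flat Euclidean distance ``d = ||T_g - T_s||`` over cycle samples, with
both channels resampled to a common number of points per cycle (100 by
default).  The ground-truth channel is the pointwise average of all recorded
strides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .skeleton import (
    BodyModel,
    LEG_NAMES,
    ReachError,
    build_body,
    leg_ik,
)

__all__ = [
    "GaitSpec",
    "GaitTrajectory",
    "GaitCSVError",
    "generate_reference_gait",
    "average_trajectory",
    "trajectory_distance",
    "resample_cycle",
    "read_gait_csv",
    "write_gait_csv",
    "DEFAULT_RESAMPLE_N",
]

#: default number of phase samples per cycle for the deviation metric
DEFAULT_RESAMPLE_N = 100

#: double-tripod phase offsets (cycle fraction) in LEG_NAMES order
TRIPOD_PHASE_OFFSETS = (0.0, 0.5, 0.0, 0.5, 0.0, 0.5)

GAIT_CSV_COLUMNS = (
    "time",
    "leg",
    "phase",
    "foot_x",
    "foot_y",
    "foot_z",
    "q_bc",
    "q_cf",
    "q_ft",
    "stance",
)


class GaitCSVError(ValueError):
    """Malformed gait CSV (bad header, non-monotone time, ...)."""


@dataclass(frozen=True)
class GaitSpec:
    """Parameters of the synthetic double-tripod gait.

    ``stride_mm`` is the foot excursion relative to the body; the implied
    body speed is ``stride / (duty * period)``.
    """

    period_s: float = 1.0
    duty_factor: float = 0.5
    stride_mm: float = 4.0
    swing_clearance_mm: float = 0.8
    stance_width_mm: float = 4.0  # radial foot distance from the leg root
    phase_offsets: tuple = TRIPOD_PHASE_OFFSETS
    samples_per_cycle: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must lie strictly in (0, 1)")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.stride_mm <= 0 or self.swing_clearance_mm < 0:
            raise ValueError("stride_mm must be positive, clearance non-negative")
        if len(self.phase_offsets) != 6:
            raise ValueError("phase_offsets must give one offset per leg")
        if self.samples_per_cycle < 2:
            raise ValueError("samples_per_cycle must be at least 2")

    @property
    def body_speed_mm_s(self) -> float:
        return self.stride_mm / (self.duty_factor * self.period_s)


@dataclass
class GaitTrajectory:
    """Per-stride time series of foot positions and joint angles.

    Arrays are indexed ``[sample, leg, ...]`` in LEG_NAMES order.  Foot
    positions are in the body frame (mm); ``foot_world`` additionally stores
    the world-frame path when known.  ``stance`` flags ground contact.
    """

    time: np.ndarray  # (n,) s, strictly increasing
    period_s: float
    q: np.ndarray  # (n, 6, 3) rad
    foot_body: np.ndarray  # (n, 6, 3) mm
    stance: np.ndarray  # (n, 6) bool
    foot_world: np.ndarray | None = None  # (n, 6, 3) mm
    body_position: np.ndarray | None = None  # (n, 3) mm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if (np.diff(self.time) <= 0).any():
            raise ValueError("time must be strictly increasing")
        n = self.time.size
        self.q = np.asarray(self.q, dtype=float).reshape(n, 6, 3)
        self.foot_body = np.asarray(self.foot_body, dtype=float).reshape(n, 6, 3)
        self.stance = np.asarray(self.stance, dtype=bool).reshape(n, 6)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def n_cycles(self) -> float:
        dt = self.time[1] - self.time[0]
        return (self.time[-1] - self.time[0] + dt) / self.period_s

    def phase(self) -> np.ndarray:
        return np.mod(self.time / self.period_s, 1.0)

    def joint_channel(self, leg: int | str, joint: int) -> np.ndarray:
        if isinstance(leg, str):
            leg = LEG_NAMES.index(leg)
        return self.q[:, leg, joint]

    # -- periodic phase lookups (first recorded cycle as the template) ----
    def _template(self) -> tuple[np.ndarray, slice]:
        dt = self.time[1] - self.time[0]
        spc = max(int(round(self.period_s / dt)), 1)
        spc = min(spc, self.n_samples)
        return np.arange(spc) / spc, slice(0, spc)

    def q_at(self, phase: float) -> np.ndarray:
        """Joint angles (6, 3) at a cycle fraction, periodic linear interp."""
        grid, sl = self._template()
        return _periodic_interp(phase, grid, self.q[sl])

    def foot_at(self, phase: float) -> np.ndarray:
        grid, sl = self._template()
        return _periodic_interp(phase, grid, self.foot_body[sl])

    def stance_at(self, phase: float) -> np.ndarray:
        grid, sl = self._template()
        idx = int(np.round(phase * len(grid))) % len(grid)
        return self.stance[sl][idx]


def _periodic_interp(phase: float, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    p = np.mod(phase, 1.0)
    n = len(grid)
    x = p * n
    i0 = int(np.floor(x)) % n
    i1 = (i0 + 1) % n
    w = x - np.floor(x)
    return (1.0 - w) * values[i0] + w * values[i1]


def generate_reference_gait(
    spec: GaitSpec,
    n_cycles: int = 1,
    noise_sd_mm: float = 0.0,
    seed: int | None = None,
    body: BodyModel | None = None,
) -> GaitTrajectory:
    """Synthesise a double-tripod reference gait.

    Stance feet are stationary in the world frame (for zero noise); swing
    feet travel a half-ellipse of the given clearance.  Joint angles come
    from closed-form inverse kinematics of each foot path.  Gaussian jitter
    of standard deviation ``noise_sd_mm`` is added to the foot positions
    before the IK when ``noise_sd_mm > 0``.
    """
    body = body or build_body()
    body = replace(body, stance_radius_mm=spec.stance_width_mm)
    rng = np.random.default_rng(seed)
    n = spec.samples_per_cycle * n_cycles
    dt = spec.period_s / spec.samples_per_cycle
    time = np.arange(n) * dt
    duty = spec.duty_factor
    half = spec.stride_mm / 2.0

    q = np.zeros((n, 6, 3))
    foot_body = np.zeros((n, 6, 3))
    stance = np.zeros((n, 6), dtype=bool)
    for leg_idx, leg in enumerate(body.legs):
        neutral = body.neutral_foot_position(leg_idx)
        ph = np.mod(time / spec.period_s - spec.phase_offsets[leg_idx], 1.0)
        in_stance = ph < duty
        x_rel = np.where(
            in_stance,
            half - (ph / duty) * spec.stride_mm,
            -half + ((ph - duty) / (1.0 - duty)) * spec.stride_mm,
        )
        z_rel = np.where(
            in_stance,
            0.0,
            spec.swing_clearance_mm * np.sin(np.pi * (ph - duty) / (1.0 - duty)),
        )
        feet = np.tile(neutral, (n, 1))
        feet[:, 0] += x_rel
        feet[:, 2] += z_rel
        if noise_sd_mm > 0:
            feet += rng.normal(0.0, noise_sd_mm, size=feet.shape)
        stance[:, leg_idx] = in_stance
        foot_body[:, leg_idx] = feet
        # jittered targets may graze the workspace boundary; clamp them
        # (strict for the deterministic path so bad specs fail loudly)
        clamp = noise_sd_mm > 0
        for k in range(n):
            try:
                q[k, leg_idx] = leg_ik(leg, feet[k], clamp=clamp)
            except ReachError as err:
                raise ReachError(
                    f"gait spec puts the {leg.name} foot out of reach "
                    f"(check stride_mm / stance_width_mm / swing_clearance_mm): {err}"
                ) from err

    speed = spec.body_speed_mm_s
    body_position = np.column_stack(
        [speed * time, np.zeros(n), np.full(n, body.standing_height_mm)]
    )
    foot_world = foot_body + body_position[:, None, :]
    return GaitTrajectory(
        time=time,
        period_s=spec.period_s,
        q=q,
        foot_body=foot_body,
        stance=stance,
        foot_world=foot_world,
        body_position=body_position,
    )


def average_trajectory(trajectories: list[GaitTrajectory]) -> GaitTrajectory:
    """Pointwise mean of equally sampled trajectories (resample first)."""
    if not trajectories:
        raise ValueError("cannot average an empty list of trajectories")
    n = trajectories[0].n_samples
    for t in trajectories[1:]:
        if t.n_samples != n:
            raise ValueError(
                "trajectories must be resampled to equal lengths before averaging"
            )
    base = trajectories[0]
    q = np.mean([t.q for t in trajectories], axis=0)
    foot = np.mean([t.foot_body for t in trajectories], axis=0)
    stance = np.mean([t.stance for t in trajectories], axis=0) >= 0.5
    world = None
    if all(t.foot_world is not None for t in trajectories):
        world = np.mean([t.foot_world for t in trajectories], axis=0)
    body = None
    if all(t.body_position is not None for t in trajectories):
        body = np.mean([t.body_position for t in trajectories], axis=0)
    return GaitTrajectory(
        time=base.time.copy(),
        period_s=base.period_s,
        q=q,
        foot_body=foot,
        stance=stance,
        foot_world=world,
        body_position=body,
    )


def trajectory_distance(t_g: np.ndarray, t_s: np.ndarray) -> float:
    """Euclidean deviation ``||T_g - T_s||`` between two joint channels."""
    a = np.asarray(t_g, dtype=float).ravel()
    b = np.asarray(t_s, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"channel lengths differ ({a.size} vs {b.size}); resample first"
        )
    return float(np.linalg.norm(a - b))


def resample_cycle(traj: GaitTrajectory, n: int) -> GaitTrajectory:
    """Linear interpolation onto ``n`` uniform phase points per cycle."""
    if n < 2:
        raise ValueError("n must be at least 2")
    cycles = max(int(round(traj.n_cycles)), 1)
    t_old = traj.time
    t_new = (
        t_old[0]
        + (np.arange(n * cycles) / n) * traj.period_s
    )
    t_new = t_new[t_new <= t_old[-1] + 1e-12]

    def interp(arr: np.ndarray) -> np.ndarray:
        flat = arr.reshape(arr.shape[0], -1)
        out = np.empty((t_new.size, flat.shape[1]))
        for j in range(flat.shape[1]):
            out[:, j] = np.interp(t_new, t_old, flat[:, j])
        return out.reshape((t_new.size,) + arr.shape[1:])

    stance_f = interp(traj.stance.astype(float)) >= 0.5
    return GaitTrajectory(
        time=t_new,
        period_s=traj.period_s,
        q=interp(traj.q),
        foot_body=interp(traj.foot_body),
        stance=stance_f,
        foot_world=None if traj.foot_world is None else interp(traj.foot_world),
    )


def write_gait_csv(traj: GaitTrajectory, path) -> None:
    """Write the documented long-format dialect, one row per (time, leg)."""
    rows = []
    phase = traj.phase()
    for k in range(traj.n_samples):
        for leg_idx, leg_name in enumerate(LEG_NAMES):
            rows.append(
                (
                    traj.time[k],
                    leg_name,
                    phase[k],
                    *traj.foot_body[k, leg_idx],
                    *traj.q[k, leg_idx],
                    int(traj.stance[k, leg_idx]),
                )
            )
    frame = pd.DataFrame(rows, columns=GAIT_CSV_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# formica gait trajectory\n")
        fh.write("# units: time s, foot_* mm (body frame), q_* rad\n")
        fh.write(f"# period_s = {traj.period_s!r}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_gait_csv(path) -> GaitTrajectory:
    """Parse the gait CSV dialect back into a trajectory (lossless)."""
    period = None
    header_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if "period_s" in stripped and "=" in stripped:
                    period = float(stripped.split("=", 1)[1])
                continue
            header_line = lineno
            header = [c.strip() for c in stripped.split(",")]
            break
        else:
            raise GaitCSVError(f"{path}: empty gait file")
    if header_line is None or tuple(header) != GAIT_CSV_COLUMNS:
        raise GaitCSVError(
            f"{path}:{header_line or 1}: malformed header {header!r}, "
            f"expected {','.join(GAIT_CSV_COLUMNS)}"
        )
    frame = pd.read_csv(path, comment="#")
    if frame.empty:
        raise GaitCSVError(f"{path}: no data rows")
    if period is None:
        raise GaitCSVError(f"{path}: missing '# period_s = ...' comment line")
    times = np.sort(frame["time"].unique())
    if times.size > 1 and (np.diff(times) <= 0).any():
        raise GaitCSVError(f"{path}: non-monotone time column")
    n = times.size
    q = np.zeros((n, 6, 3))
    foot = np.zeros((n, 6, 3))
    stance = np.zeros((n, 6), dtype=bool)
    time_index = {t: i for i, t in enumerate(times)}
    for row_pos, row in enumerate(frame.itertuples(index=False)):
        if row.leg not in LEG_NAMES:
            raise GaitCSVError(
                f"{path}: data row {row_pos + 1}: unknown leg label {row.leg!r}"
            )
        k = time_index[row.time]
        leg_idx = LEG_NAMES.index(row.leg)
        foot[k, leg_idx] = (row.foot_x, row.foot_y, row.foot_z)
        q[k, leg_idx] = (row.q_bc, row.q_cf, row.q_ft)
        stance[k, leg_idx] = bool(row.stance)
    return GaitTrajectory(
        time=times, period_s=period, q=q, foot_body=foot, stance=stance
    )
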
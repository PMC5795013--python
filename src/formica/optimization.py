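"""Two-stage evolutionary fitting of the controller and muscle parameters.

Stage I fits, for the standard case of walking straight forward, the bias
current and firing window of every motor neuron together with the eight Hill
parameters of its muscle.  Left-right symmetry halves the 36 neuron-muscle
pairs to 18 units of 11 parameters each — (I, T_s, T_e) plus
Omega = (F_max, beta, rho, omega, V_max, c_V, b_V, a_V) — for a genome of
exactly 11 * 18 = 198 values.  Stage II fixes the Stage-I optimum and fits
the synaptic weights of the spiking network (2x16 input-to-central plus
16x36 central-to-motor = 608 values in [0, 1]), which let the slope and
turning inputs modulate the standard pattern.  The combined dimension is
806.

Both stages use Covariance Matrix Adaptation (CMA-ES): each generation
samples lambda candidates from N(m, sigma^2 C), ranks them by the objective,
and recombines the mu best into the new mean while adapting C and sigma
(rank-one plus rank-mu updates, cumulative step-size control).  Stage II
additionally widens the scenario box progressively: slope/target scenarios
are drawn uniformly from [-alpha*theta_max, alpha*theta_max]^2 with alpha
stepping 0.2 -> 1.0, each phase warm-started from the previous optimum.

The Stage-I objective combines a velocity-tracking term, a foot-trajectory
term and a neural-energy term:

    f = w_s * sum_k I^2  +  w_v * sum_k (nu - nu*)^2  +  w_t * sum_k (p_f - p_f*)^2

with weights w_s = 1.0, w_v = 10.0, w_t = 0.5.  Stage II sums w_s f_s +
w_v f_v over the sampled scenarios.  Rollouts that end in a fall are padded
by holding the last per-step residual to the full horizon, so falling is
never cheaper than walking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import muscle as mu
from .gait import (
    DEFAULT_RESAMPLE_N,
    GaitTrajectory,
    average_trajectory,
    resample_cycle,
    trajectory_distance,
)
from .neuro import (
    BiasCurrents,
    EncodingConfig,
    N_CENTRAL,
    N_INPUT,
    N_MOTOR,
    NetworkWeights,
    motor_unit_index,
    spike_count,
)
from .simulation import SimulationConfig, SimulationLog, extract_cycle_summaries, simulate
from .skeleton import BodyModel, JOINT_NAMES, LEG_NAMES, LEG_POSITIONS, TRIPOD_A

__all__ = [
    "STAGE1_DIM",
    "STAGE2_DIM",
    "TOTAL_DIM",
    "Stage1Genome",
    "Stage2Genome",
    "CMAConfig",
    "CMAES",
    "CMAResult",
    "ObjectiveWeights",
    "ObjectiveBreakdown",
    "objective_stage1",
    "objective_stage2",
    "cma_run",
    "run_stage1",
    "run_stage2",
    "fit_pd",
    "compare_actuators",
    "stage1_bounds",
    "stage2_bounds",
    "save_genome",
    "load_genome",
]

#: per-unit parameter ordering: neuron (I, T_s, T_e) then Omega as printed
UNIT_FIELDS = (
    "I",
    "T_s",
    "T_e",
    "f_max",
    "beta",
    "rho",
    "omega",
    "v_max",
    "c_v",
    "b_v",
    "a_v",
)
N_UNITS = 18  # 3 leg positions x 3 joints x 2 muscles (left-right symmetric)
STAGE1_DIM = N_UNITS * len(UNIT_FIELDS)  # 198
STAGE2_DIM = N_INPUT * N_CENTRAL + N_CENTRAL * N_MOTOR  # 608
TOTAL_DIM = STAGE1_DIM + STAGE2_DIM  # 806

#: initial values for every neuron-muscle unit
INITIAL_UNIT = {
    "I": 10.0,
    "T_s": 0.0,
    "T_e": 0.5,
    "f_max": 1.0,
    "beta": 1.5,
    "rho": 2.0,
    "omega": 3.0,
    "v_max": 5.0,
    "c_v": -7.0,
    "b_v": 0.67,
    "a_v": -1.668,
}

GENOME_FORMAT_TAG = "formica-genome-v1"


def _unit_index(position_idx: int, joint_idx: int, muscle_idx: int) -> int:
    return position_idx * 6 + joint_idx * 2 + muscle_idx


@dataclass
class Stage1Genome:
    """Per-unit neuron + muscle parameters under left-right symmetry.

    ``values`` has shape (18, 11) with rows ordered by leg position
    (front, middle, back), joint (body-coxa, coxa-femur, femur-tibia) and
    muscle (agonist, antagonist), and columns in :data:`UNIT_FIELDS` order.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_UNITS, len(UNIT_FIELDS)):
            raise ValueError(
                f"stage-I genome must have shape {(N_UNITS, len(UNIT_FIELDS))}"
            )

    @classmethod
    def defaults(cls) -> "Stage1Genome":
        row = np.array([INITIAL_UNIT[f] for f in UNIT_FIELDS])
        return cls(np.tile(row, (N_UNITS, 1)))

    def pack(self) -> np.ndarray:
        return self.values.ravel().copy()

    @classmethod
    def unpack(cls, vec: np.ndarray) -> "Stage1Genome":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != STAGE1_DIM:
            raise ValueError(
                f"stage-I genome vector must have length {STAGE1_DIM}, got {vec.size}"
            )
        return cls(vec.reshape(N_UNITS, len(UNIT_FIELDS)))

    def expand(self) -> tuple[BiasCurrents, list[mu.MuscleParams]]:
        """Mirror the 18 units onto all 36 motor units.

        Left and right legs of the same position share identical unit
        parameters; the tripod phase offset (0 for LF/RM/LB, 0.5 for the
        others) is applied separately so the canonical firing window is
        copied verbatim.
        """
        i_s = np.zeros(N_MOTOR)
        t_s = np.zeros(N_MOTOR)
        t_e = np.zeros(N_MOTOR)
        offset = np.zeros(N_MOTOR)
        muscles: list[mu.MuscleParams | None] = [None] * N_MOTOR
        col = {f: i for i, f in enumerate(UNIT_FIELDS)}
        for leg_idx, leg_name in enumerate(LEG_NAMES):
            pos_idx = LEG_POSITIONS.index(
                {"F": "front", "M": "middle", "B": "back"}[leg_name[1]]
            )
            for j in range(3):
                for m in range(2):
                    unit = self.values[_unit_index(pos_idx, j, m)]
                    k = motor_unit_index(leg_idx, j, m)
                    i_s[k] = np.clip(unit[col["I"]], 0.0, None)
                    lo, hi = sorted((unit[col["T_s"]], unit[col["T_e"]]))
                    lo = float(np.clip(lo, 0.0, 1.0))
                    hi = float(np.clip(hi, 0.0, 1.0))
                    if hi - lo < 0.01:  # degenerate window: keep a sliver open
                        hi = min(lo + 0.01, 1.0)
                        lo = hi - 0.01
                    t_s[k], t_e[k] = lo, hi
                    offset[k] = 0.0 if leg_name in TRIPOD_A else 0.5
                    muscles[k] = mu.MuscleParams(
                        f_max=max(unit[col["f_max"]], 1e-6),
                        beta=unit[col["beta"]],
                        rho=unit[col["rho"]],
                        omega=max(unit[col["omega"]], 1e-6),
                        v_max=max(unit[col["v_max"]], 1e-6),
                        c_v=unit[col["c_v"]],
                        b_v=unit[col["b_v"]],
                        a_v=unit[col["a_v"]],
                    )
        bias = BiasCurrents(i_s=i_s, t_s=t_s, t_e=t_e, phase_offset=offset)
        return bias, muscles  # type: ignore[return-value]


@dataclass
class Stage2Genome:
    """Flattened synaptic weights (row-major w_in then w_out)."""

    weights: NetworkWeights

    @classmethod
    def zeros(cls) -> "Stage2Genome":
        return cls(NetworkWeights.zeros())

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.weights.w_in.ravel(), self.weights.w_out.ravel()]
        )

    @classmethod
    def unpack(cls, vec: np.ndarray) -> "Stage2Genome":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != STAGE2_DIM:
            raise ValueError(
                f"stage-II genome vector must have length {STAGE2_DIM}, got {vec.size}"
            )
        vec = np.clip(vec, 0.0, 1.0)
        n_in = N_INPUT * N_CENTRAL
        return cls(
            NetworkWeights(
                vec[:n_in].reshape(N_INPUT, N_CENTRAL),
                vec[n_in:].reshape(N_CENTRAL, N_MOTOR),
            )
        )


def stage1_bounds() -> np.ndarray:
    """(198, 2) box: I in [0, 20], gates in [0, 1], Omega within +/-50%."""
    per_field = {
        "I": (0.0, 20.0),
        "T_s": (0.0, 1.0),
        "T_e": (0.0, 1.0),
    }
    rows = []
    for f in UNIT_FIELDS:
        if f in per_field:
            rows.append(per_field[f])
        else:
            v = INITIAL_UNIT[f]
            lo, hi = sorted((0.5 * v, 1.5 * v))
            rows.append((lo, hi))
    return np.tile(np.array(rows), (N_UNITS, 1))


def stage2_bounds() -> np.ndarray:
    return np.tile(np.array([[0.0, 1.0]]), (STAGE2_DIM, 1))


def save_genome(path, stage: int, vector: np.ndarray, meta: dict | None = None) -> None:
    payload = {
        "format": GENOME_FORMAT_TAG,
        "stage": int(stage),
        "values": np.asarray(vector, dtype=float).ravel().tolist(),
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_genome(path) -> tuple[int, np.ndarray, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != GENOME_FORMAT_TAG:
        raise ValueError(f"{path}: not a {GENOME_FORMAT_TAG} genome file")
    return int(payload["stage"]), np.array(payload["values"]), payload.get("meta", {})


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveWeights:
    w_s: float = 1.0
    w_v: float = 10.0
    w_t: float = 0.5

    def __post_init__(self) -> None:
        if self.w_s < 0 or self.w_v < 0 or self.w_t < 0:
            raise ValueError("objective weights must be non-negative")


class ObjectiveBreakdown:
    """Total fitness with its velocity / trajectory / energy components."""

    __slots__ = ("f", "f_v", "f_t", "f_s")

    def __init__(self, f: float, f_v: float, f_t: float, f_s: float) -> None:
        self.f, self.f_v, self.f_t, self.f_s = f, f_v, f_t, f_s

    def __repr__(self) -> str:
        return (
            f"ObjectiveBreakdown(f={self.f:.6g}, f_v={self.f_v:.6g}, "
            f"f_t={self.f_t:.6g}, f_s={self.f_s:.6g})"
        )


def objective_stage1(
    log: SimulationLog,
    ref: GaitTrajectory,
    w: ObjectiveWeights = ObjectiveWeights(),
    n_full_steps: int | None = None,
) -> ObjectiveBreakdown:
    """Stage-I fitness from a rollout log.

    Foot residuals compare body-frame foot positions against the reference
    at the same cycle phase (the objective is therefore invariant to where
    the body is in the world).  If the rollout ended early (a fall), the
    missing steps are charged as a stationary fallen body: the velocity
    residual becomes the full ``||nu*||^2`` per step, while the foot and
    current residuals hold their last values.  Falling is therefore never
    cheaper than walking — holding the *velocity* residual instead would
    reward genomes that reach the target speed for one step and collapse.
    """
    n = log.n_steps
    phases = np.mod(log.time / log.cycle_period_s, 1.0)
    ref_feet = np.array([ref.foot_at(p) for p in phases])
    res_v = np.sum((log.body_velocity - log.target_velocity) ** 2, axis=1)
    res_t = np.sum((log.foot_body - ref_feet) ** 2, axis=(1, 2))
    res_s = np.sum(log.motor_currents**2, axis=1)
    f_v, f_t, f_s = float(res_v.sum()), float(res_t.sum()), float(res_s.sum())
    n_full = n_full_steps if n_full_steps is not None else n
    if n_full > n:  # early fall: the body lies still for the rest
        pad = n_full - n
        f_v += float(np.sum(log.target_velocity[-1] ** 2)) * pad
        f_t += float(res_t[-1]) * pad
        f_s += float(res_s[-1]) * pad
    return ObjectiveBreakdown(
        f=w.w_s * f_s + w.w_v * f_v + w.w_t * f_t, f_v=f_v, f_t=f_t, f_s=f_s
    )


def objective_stage2(
    evaluations: list[tuple[float, float]],
    w: ObjectiveWeights = ObjectiveWeights(),
) -> float:
    """Stage-II fitness: sum of w_s f_s + w_v f_v over the scenarios."""
    if not evaluations:
        raise ValueError("stage-II objective needs at least one scenario")
    return float(sum(w.w_s * f_s + w.w_v * f_v for f_s, f_v in evaluations))


# ---------------------------------------------------------------------------
# CMA-ES
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CMAConfig:
    """Evolution-strategy settings.

    ``sigma0`` multiplies the per-coordinate scales (which default to 10% of
    the bound widths).  Stage-II extras: ``n_scenarios`` per evaluation and
    the alpha widening schedule.
    """

    lam: int = 120
    mu: int = 40
    sigma0: float = 1.0
    generations: int = 100
    seed: int = 0
    n_scenarios: int = 8
    alpha_start: float = 0.2
    alpha_step: float = 0.2
    alpha_end: float = 1.0
    recombination: str = "log"  # "log" or "equal"

    def __post_init__(self) -> None:
        if not 0 < self.mu <= self.lam:
            raise ValueError("need 0 < mu <= lambda")
        if not (0.0 <= self.alpha_start <= self.alpha_end <= 1.0):
            raise ValueError("alpha schedule must ascend within [0, 1]")

    def alphas(self) -> list[float]:
        out, a = [], self.alpha_start
        while a <= self.alpha_end + 1e-9:
            out.append(round(a, 10))
            if self.alpha_step <= 0:
                break
            a += self.alpha_step
        return out


class CMAES:
    """Minimal (mu/mu_w, lambda) CMA-ES with box constraints by projection.

    Standard cumulative step-size adaptation plus rank-one / rank-mu
    covariance updates.  Per-coordinate ``scales`` enter as the initial
    diagonal of C, so anisotropic parameter ranges are handled without
    rescaling the genome.

    Box constraints use repair: ``ask`` returns candidates projected onto
    the box (these are what the caller evaluates), while the distribution
    update in ``tell`` uses the raw unprojected samples ranked by the
    repaired fitness.  Updating with the projected points instead would
    bias the mean away from optima that sit on the boundary (for example
    all-zero synaptic weights), making every later generation worse than
    the first.
    """

    def __init__(
        self,
        m0: np.ndarray,
        lam: int,
        mu: int,
        sigma0: float = 1.0,
        bounds: np.ndarray | None = None,
        scales: np.ndarray | None = None,
        seed: int = 0,
        recombination: str = "log",
    ) -> None:
        self.m = np.asarray(m0, dtype=float).copy()
        self.n = self.m.size
        self.lam, self.mu = int(lam), int(mu)
        if not 0 < self.mu <= self.lam:
            raise ValueError("need 0 < mu <= lambda")
        self.sigma = float(sigma0)
        self.bounds = None if bounds is None else np.asarray(bounds, dtype=float)
        if scales is None:
            if self.bounds is not None:
                scales = 0.1 * (self.bounds[:, 1] - self.bounds[:, 0])
            else:
                scales = np.ones(self.n)
        scales = np.maximum(np.asarray(scales, dtype=float), 1e-12)
        self.C = np.diag(scales**2)
        self.rng = np.random.default_rng(seed)

        if recombination == "equal":
            w = np.ones(self.mu)
        elif recombination == "log":
            w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        else:
            raise ValueError("recombination must be 'log' or 'equal'")
        self.weights = w / w.sum()
        self.mu_eff = 1.0 / np.sum(self.weights**2)

        n, mu_eff = self.n, self.mu_eff
        self.c_sigma = (mu_eff + 2.0) / (n + mu_eff + 5.0)
        self.d_sigma = (
            1.0
            + 2.0 * max(0.0, np.sqrt((mu_eff - 1.0) / (n + 1.0)) - 1.0)
            + self.c_sigma
        )
        self.c_c = (4.0 + mu_eff / n) / (n + 4.0 + 2.0 * mu_eff / n)
        self.c_1 = 2.0 / ((n + 1.3) ** 2 + mu_eff)
        self.c_mu = min(
            1.0 - self.c_1,
            2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((n + 2.0) ** 2 + mu_eff),
        )
        self.chi_n = np.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n * n))
        self.p_sigma = np.zeros(n)
        self.p_c = np.zeros(n)
        self.generation = 0
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf
        self._decompose()

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2.0
        eigval, eigvec = np.linalg.eigh(self.C)
        eigval = np.maximum(eigval, 1e-20)
        self.B = eigvec
        self.D = np.sqrt(eigval)

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.n))
        y = z * self.D[None, :] @ self.B.T
        x = self.m[None, :] + self.sigma * y
        self._raw = x
        if self.bounds is not None:
            x = np.clip(x, self.bounds[:, 0], self.bounds[:, 1])
        self._repair_dist2 = np.sum((self._raw - x) ** 2, axis=1)
        return x

    def tell(self, xs: np.ndarray, fs: np.ndarray) -> None:
        fs = np.asarray(fs, dtype=float).copy()
        fs[~np.isfinite(fs)] = np.inf  # failed evaluations rank worst
        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < self.best_f:
            self.best_f = float(fs[order[0]])
            self.best_x = xs[order[0]].copy()
        raw = getattr(self, "_raw", None)
        # rank by the repaired fitness but update with the raw coordinates:
        # recombining projected points biases the mean away from boundary
        # optima, while any fitness-scaled projection penalty turns out to
        # dominate the ranking for ordinary Gaussian clipping mass
        elites_source = raw if raw is not None and raw.shape == xs.shape else xs
        elites = elites_source[order[: self.mu]]
        y_elite = (elites - self.m[None, :]) / self.sigma
        y_w = self.weights @ y_elite
        self.m = self.m + self.sigma * y_w

        # step-size path in the isotropic coordinates
        c_inv_sqrt_yw = self.B @ ((self.B.T @ y_w) / self.D)
        self.p_sigma = (1.0 - self.c_sigma) * self.p_sigma + np.sqrt(
            self.c_sigma * (2.0 - self.c_sigma) * self.mu_eff
        ) * c_inv_sqrt_yw
        self.generation += 1
        h_sigma = float(
            np.linalg.norm(self.p_sigma)
            / np.sqrt(1.0 - (1.0 - self.c_sigma) ** (2.0 * self.generation))
            / self.chi_n
            < 1.4 + 2.0 / (self.n + 1.0)
        )
        self.p_c = (1.0 - self.c_c) * self.p_c + h_sigma * np.sqrt(
            self.c_c * (2.0 - self.c_c) * self.mu_eff
        ) * y_w

        rank_mu = np.einsum("i,ij,ik->jk", self.weights, y_elite, y_elite)
        delta_h = (1.0 - h_sigma) * self.c_c * (2.0 - self.c_c)
        self.C = (
            (1.0 - self.c_1 - self.c_mu) * self.C
            + self.c_1 * (np.outer(self.p_c, self.p_c) + delta_h * self.C)
            + self.c_mu * rank_mu
        )
        self.sigma *= np.exp(
            (self.c_sigma / self.d_sigma)
            * (np.linalg.norm(self.p_sigma) / self.chi_n - 1.0)
        )
        self.sigma = float(np.clip(self.sigma, 1e-12, 1e6))
        self._decompose()


@dataclass
class CMAResult:
    best_x: np.ndarray
    best_f: float
    trace: pd.DataFrame  # generation, best_f, mean_f, sigma, best_so_far

    @property
    def best_so_far(self) -> np.ndarray:
        return self.trace["best_so_far"].to_numpy()


def cma_run(
    evaluate,
    cfg: CMAConfig,
    bounds: np.ndarray,
    m0: np.ndarray,
    scales: np.ndarray | None = None,
    checkpoint_path=None,
) -> CMAResult:
    """Generic CMA loop: evaluate is genome -> scalar fitness (lower better).

    Non-finite fitness values are kept but rank worst.  The returned trace
    carries per-generation best/mean fitness, sigma and the non-increasing
    best-so-far bookkeeping.  A JSON checkpoint (mean, sigma, generation) is
    written after each generation when a path is given.
    """
    es = CMAES(
        m0,
        lam=cfg.lam,
        mu=cfg.mu,
        sigma0=cfg.sigma0,
        bounds=bounds,
        scales=scales,
        seed=cfg.seed,
        recombination=cfg.recombination,
    )
    rows = []
    for gen in range(cfg.generations):
        xs = es.ask()
        fs = np.array([evaluate(x) for x in xs])
        es.tell(xs, fs)
        finite = fs[np.isfinite(fs)]
        rows.append(
            {
                "generation": gen,
                "best_f": float(np.min(fs)),
                "mean_f": float(np.mean(finite)) if finite.size else np.inf,
                "sigma": es.sigma,
                "best_so_far": es.best_f,
            }
        )
        if checkpoint_path is not None:
            with open(checkpoint_path, "w") as fh:
                json.dump(
                    {
                        "generation": gen,
                        "sigma": es.sigma,
                        "mean": es.m.tolist(),
                        "best_f": es.best_f,
                        "best_x": es.best_x.tolist(),
                    },
                    fh,
                )
    return CMAResult(best_x=es.best_x, best_f=es.best_f, trace=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# stage drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSettings:
    """Rollout settings shared by the stage drivers.

    The full-scale study runs 100 s (100 cycles) rollouts for Stage I and
    10 s for Stage II; desk-scale runs shorten these.
    """

    rollout_s: float = 100.0
    dt_s: float = 0.005
    cycle_period_s: float = 1.0
    target_speed_mm_s: float | None = None  # None: derive from the reference
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    freeze_gates: bool = False
    #: initial per-coordinate sampling scale for the Stage-II weights; the
    #: gated bias alone already walks, so the network starts as a small
    #: modulation around zero rather than a 10%-of-range perturbation
    stage2_scale: float = 0.02


def _reference_speed(ref: GaitTrajectory, settings: StageSettings) -> float:
    if settings.target_speed_mm_s is not None:
        return settings.target_speed_mm_s
    if ref.body_position is None:
        raise ValueError(
            "reference trajectory carries no body track; set target_speed_mm_s"
        )
    span = ref.time[-1] - ref.time[0]
    return float(
        np.linalg.norm(ref.body_position[-1, :2] - ref.body_position[0, :2]) / span
    )


def _stage1_sim_config(settings: StageSettings, speed: float, **over) -> SimulationConfig:
    return SimulationConfig(
        dt_s=settings.dt_s,
        duration_s=settings.rollout_s,
        cycle_period_s=settings.cycle_period_s,
        target_speed_mm_s=speed,
        encoding=settings.encoding,
        **over,
    )


@dataclass
class StageResult:
    genome_vector: np.ndarray
    best_f: float
    trace: pd.DataFrame


def run_stage1(
    body: BodyModel,
    ref: GaitTrajectory,
    cfg: CMAConfig,
    settings: StageSettings = StageSettings(),
) -> StageResult:
    """Fit the per-unit bias currents, firing windows and muscle parameters.

    The initial mean is the printed seed (I=10, F_max=1, beta=1.5, rho=2.0,
    omega=3.0, V_max=5.0, c_V=-7.0, b_V=0.67, a_V=-1.668, tripod default
    gates); the network weights stay zero at this stage, so the gated bias
    currents alone shape the straight-walk pattern.
    """
    bounds = stage1_bounds()
    speed = _reference_speed(ref, settings)
    sim_cfg = _stage1_sim_config(settings, speed)
    n_full = int(round(settings.rollout_s / settings.dt_s))
    zeros = NetworkWeights.zeros()
    defaults = Stage1Genome.defaults().values
    gate_cols = [UNIT_FIELDS.index("T_s"), UNIT_FIELDS.index("T_e")]

    def evaluate(vec: np.ndarray) -> float:
        genome = Stage1Genome.unpack(vec)
        if settings.freeze_gates:
            genome.values[:, gate_cols] = defaults[:, gate_cols]
        bias, muscles = genome.expand()
        log = simulate(body, zeros, bias, muscles, ref, sim_cfg)
        return objective_stage1(log, ref, settings.weights, n_full).f

    result = cma_run(evaluate, cfg, bounds, Stage1Genome.defaults().pack())
    return StageResult(result.best_x, result.best_f, result.trace)


def sample_scenarios(
    rng: np.random.Generator, n: int, alpha: float, enc: EncodingConfig
) -> np.ndarray:
    """Uniform (theta_s, theta_t) pairs from the alpha-scaled box."""
    lo = np.array([-alpha * enc.theta_max_s, -alpha * enc.theta_max_t])
    hi = -lo
    return rng.uniform(lo, hi, size=(n, 2))


def run_stage2(
    body: BodyModel,
    stage1_vector: np.ndarray,
    ref: GaitTrajectory,
    cfg: CMAConfig,
    settings: StageSettings = StageSettings(rollout_s=10.0),
) -> StageResult:
    """Fit the synaptic weights over progressively wider scenario boxes.

    Each alpha phase draws ``cfg.n_scenarios`` (slope, target) pairs from
    the alpha-box once (seeded from the master seed) and evaluates every
    candidate of every generation on that common scenario set, so the
    within-phase objective is deterministic and fitnesses are comparable
    across generations.  Each candidate's weight matrices are scored by the
    sum of w_s f_s + w_v f_v over the scenarios.  Phases warm-start
    cumulatively from the previous optimum.  The Stage-I optimum supplies
    the bias currents and muscle parameters and stays fixed.
    """
    bias, muscles = Stage1Genome.unpack(stage1_vector).expand()
    bounds = stage2_bounds()
    speed = _reference_speed(ref, settings)
    n_full = int(round(settings.rollout_s / settings.dt_s))
    master = np.random.default_rng(cfg.seed)

    def evaluate_on(vec: np.ndarray, scenarios: np.ndarray) -> float:
        weights = Stage2Genome.unpack(vec).weights
        evals = []
        for theta_s, theta_t in scenarios:
            sim_cfg = _stage1_sim_config(
                settings, speed, slope_deg=float(theta_s), target_deg=float(theta_t)
            )
            log = simulate(body, weights, bias, muscles, ref, sim_cfg)
            br = objective_stage1(log, ref, settings.weights, n_full)
            evals.append((br.f_s, br.f_v))
        return objective_stage2(evals, settings.weights)

    m = Stage2Genome.zeros().pack()
    rows = []
    best_x, best_f = m.copy(), np.inf
    for alpha in cfg.alphas():
        es = CMAES(
            m,
            lam=cfg.lam,
            mu=cfg.mu,
            sigma0=cfg.sigma0,
            bounds=bounds,
            scales=np.full(STAGE2_DIM, settings.stage2_scale),
            seed=int(master.integers(2**31 - 1)),
            recombination=cfg.recombination,
        )
        scenarios = sample_scenarios(master, cfg.n_scenarios, alpha, settings.encoding)
        for gen in range(cfg.generations):
            xs = es.ask()
            fs = np.array([evaluate_on(x, scenarios) for x in xs])
            es.tell(xs, fs)
            rows.append(
                {
                    "alpha": alpha,
                    "generation": gen,
                    "best_f": float(np.min(fs)),
                    "mean_f": float(np.mean(fs[np.isfinite(fs)])),
                    "sigma": es.sigma,
                    "best_so_far": es.best_f,
                }
            )
        m = es.best_x if es.best_x is not None else es.m
        if es.best_f < best_f:
            best_f, best_x = es.best_f, es.best_x.copy()
    return StageResult(best_x, float(best_f), pd.DataFrame(rows))


def fit_pd(
    body: BodyModel,
    ref: GaitTrajectory,
    cfg: CMAConfig,
    settings: StageSettings = StageSettings(),
    k_g_bounds: tuple[float, float] = (0.02, 2.0),
    k_d_bounds: tuple[float, float] = (0.0, 0.5),
) -> tuple[mu.PDParams, StageResult]:
    """Fit the two PD-servo coefficients under the Stage-I objective."""
    bounds = np.array([k_g_bounds, k_d_bounds])
    speed = _reference_speed(ref, settings)
    n_full = int(round(settings.rollout_s / settings.dt_s))
    bias, muscles = Stage1Genome.defaults().expand()
    zeros = NetworkWeights.zeros()

    def evaluate(vec: np.ndarray) -> float:
        params = mu.PDParams(k_g=max(vec[0], 1e-6), k_d=max(vec[1], 0.0))
        sim_cfg = _stage1_sim_config(
            settings, speed, actuator="pd", pd_params=params
        )
        log = simulate(body, zeros, bias, muscles, ref, sim_cfg)
        return objective_stage1(log, ref, settings.weights, n_full).f

    result = cma_run(evaluate, cfg, bounds, np.array([0.5, 0.1]))
    params = mu.PDParams(k_g=float(result.best_x[0]), k_d=float(result.best_x[1]))
    return params, StageResult(result.best_x, result.best_f, result.trace)


def _cycle_channel(log: SimulationLog, leg: str, joint: int, n: int) -> np.ndarray:
    """Cycle-averaged joint channel resampled to n phase points.

    A rollout that fell before completing one cycle is padded by holding the
    last logged angle, consistent with the early-fall treatment in the
    objective: falling does not shrink the comparison window.
    """
    spc = int(round(log.cycle_period_s / log.dt_s))
    angles = log.joint_angles[:, LEG_NAMES.index(leg), joint]
    if log.n_steps < spc:
        angles = np.concatenate(
            [angles, np.full(spc - log.n_steps, angles[-1] if angles.size else 0.0)]
        )
        curve = angles
        phase = np.arange(spc) / spc
    else:
        summaries = extract_cycle_summaries(log)
        curve = summaries["joint_angle_curves"][:, LEG_NAMES.index(leg), joint]
        phase = summaries["phase"]
    phase_new = np.arange(n) / n
    return np.interp(phase_new, phase, curve, period=1.0)


def compare_actuators(
    body: BodyModel,
    ref_strides: list[GaitTrajectory],
    stage1_vector: np.ndarray,
    pd_params: mu.PDParams,
    settings: StageSettings = StageSettings(rollout_s=10.0),
    leg: str = "LM",
    n_samples: int = DEFAULT_RESAMPLE_N,
) -> pd.DataFrame:
    """Per-joint trajectory deviation of both actuators from the ground truth.

    The ground-truth channel T_g per joint is the average of all reference
    strides (middle leg by default); each actuator's channel T_s is its
    cycle-averaged simulated joint trajectory.  Both actuators track the
    stride average (the same construction as the ground truth) rather than
    one arbitrary jittered stride, so the deviation measures tracking
    quality, not the jitter of whichever stride happened to be replayed.
    Deviations are the Euclidean distance over ``n_samples`` uniform phase
    points, reported in radians.
    """
    resampled = [resample_cycle(s, n_samples) for s in ref_strides]
    t_g = average_trajectory(resampled)
    ref = average_trajectory(ref_strides)
    bias, muscles = Stage1Genome.unpack(stage1_vector).expand()
    zeros = NetworkWeights.zeros()
    speed = _reference_speed(ref, settings)

    logs = {
        "hill": simulate(
            body, zeros, bias, muscles, ref, _stage1_sim_config(settings, speed)
        ),
        "pd": simulate(
            body,
            zeros,
            bias,
            muscles,
            ref,
            _stage1_sim_config(settings, speed, actuator="pd", pd_params=pd_params),
        ),
    }
    rows = {}
    leg_idx = LEG_NAMES.index(leg)
    for j, joint_name in enumerate(JOINT_NAMES):
        g = np.interp(
            np.arange(n_samples) / n_samples,
            np.mod(t_g.time / t_g.period_s, 1.0)[: n_samples],
            t_g.q[:n_samples, leg_idx, j],
            period=1.0,
        )
        rows[joint_name] = {
            name: trajectory_distance(g, _cycle_channel(log, leg, j, n_samples))
            for name, log in logs.items()
        }
    return pd.DataFrame(rows).T


def middle_retractor_spike_counts(
    log: SimulationLog, joint: int = 0, muscle: int = 0
) -> tuple[int, int]:
    """Spike counts of the left and right middle-leg body-coxa retractor.

    The retractor is the agonist of the body-coxa pair: its positive joint
    torque swings the leg backward, which under the stance force balance is
    the propulsive stroke.  Counts are taken over
    complete locomotion cycles only: the two tripods fire in opposite half
    cycles, so a partial final cycle would bias the comparison toward
    whichever side fires first.
    """
    left = motor_unit_index(LEG_NAMES.index("LM"), joint, muscle)
    right = motor_unit_index(LEG_NAMES.index("RM"), joint, muscle)
    spc = int(round(log.cycle_period_s / log.dt_s))
    n = (log.n_steps // spc) * spc if log.n_steps >= spc else log.n_steps
    return (
        spike_count(log.motor_spikes[:n, left]),
        spike_count(log.motor_spikes[:n, right]),
    )
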
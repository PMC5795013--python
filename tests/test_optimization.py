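"""Genome packing, objective functions and the CMA-ES core."""

import numpy as np
import pandas as pd
import pytest

from formica.gait import GaitTrajectory
from formica.neuro import N_MOTOR
from formica.optimization import (
    CMAConfig,
    CMAES,
    ObjectiveWeights,
    STAGE1_DIM,
    STAGE2_DIM,
    Stage1Genome,
    Stage2Genome,
    TOTAL_DIM,
    UNIT_FIELDS,
    cma_run,
    load_genome,
    objective_stage1,
    objective_stage2,
    sample_scenarios,
    save_genome,
    stage1_bounds,
    stage2_bounds,
)
from formica.neuro import EncodingConfig, NetworkWeights, motor_unit_index
from formica.simulation import SimulationLog
from formica.skeleton import LEG_NAMES


class TestGenomeDimensions:
    def test_stage_dimensions(self):
        assert STAGE1_DIM == 198
        assert STAGE2_DIM == 608
        assert TOTAL_DIM == 806

    def test_default_stage1_packs_to_198(self):
        assert Stage1Genome.defaults().pack().shape == (198,)

    def test_stage2_packs_to_608(self):
        vec = Stage2Genome.zeros().pack()
        assert vec.shape == (608,)

    def test_wrong_lengths_report_expected_size(self):
        with pytest.raises(ValueError, match="198"):
            Stage1Genome.unpack(np.zeros(197))
        with pytest.raises(ValueError, match="608"):
            Stage2Genome.unpack(np.zeros(609))


class TestRoundTrips:
    def test_stage1_pack_unpack_identity(self, rng):
        values = rng.uniform(0, 1, (18, 11))
        genome = Stage1Genome(values)
        again = Stage1Genome.unpack(genome.pack())
        np.testing.assert_array_equal(again.values, values)

    def test_stage2_pack_unpack_identity(self, rng):
        w = NetworkWeights(rng.uniform(0, 1, (2, 16)), rng.uniform(0, 1, (16, 36)))
        again = Stage2Genome.unpack(Stage2Genome(w).pack())
        np.testing.assert_array_equal(again.weights.w_in, w.w_in)
        np.testing.assert_array_equal(again.weights.w_out, w.w_out)

    def test_stage2_unpack_clamps_to_unit_box(self):
        vec = np.full(608, 2.0)
        assert Stage2Genome.unpack(vec).weights.w_in.max() == 1.0

    def test_genome_json_round_trip(self, tmp_path, rng):
        vec = rng.normal(0, 1, 198)
        path = tmp_path / "genome.json"
        save_genome(path, 1, vec, {"note": "test"})
        stage, back, meta = load_genome(path)
        assert stage == 1 and meta["note"] == "test"
        np.testing.assert_allclose(back, vec)


class TestMirrorExpansion:
    def test_left_and_right_units_share_parameters(self, rng):
        genome = Stage1Genome(rng.uniform(0.1, 0.9, (18, 11)))
        genome.values[:, UNIT_FIELDS.index("I")] = rng.uniform(0, 20, 18)
        bias, muscles = genome.expand()
        for pos in ("F", "M", "B"):
            li, ri = LEG_NAMES.index("L" + pos), LEG_NAMES.index("R" + pos)
            for j in range(3):
                for m in range(2):
                    lk, rk = motor_unit_index(li, j, m), motor_unit_index(ri, j, m)
                    assert bias.i_s[lk] == bias.i_s[rk]
                    assert bias.t_s[lk] == bias.t_s[rk]
                    assert bias.t_e[lk] == bias.t_e[rk]
                    assert muscles[lk] == muscles[rk]

    def test_tripod_phase_offsets_differ_across_sides(self):
        bias, _ = Stage1Genome.defaults().expand()
        lf = motor_unit_index(LEG_NAMES.index("LF"), 0, 0)
        rf = motor_unit_index(LEG_NAMES.index("RF"), 0, 0)
        assert bias.phase_offset[lf] == 0.0
        assert bias.phase_offset[rf] == 0.5
        # absolute firing windows reproduce the printed tripod gates
        t_s_abs, t_e_abs = bias.absolute_gates()
        assert (t_s_abs[lf], t_e_abs[lf]) == (0.0, 0.5)
        assert (t_s_abs[rf], t_e_abs[rf]) == (0.5, 1.0)

    def test_default_expansion_reproduces_initial_values(self):
        bias, muscles = Stage1Genome.defaults().expand()
        assert np.all(bias.i_s == 10.0)
        assert muscles[0].f_max == 1.0 and muscles[0].c_v == -7.0


def make_log(n, currents=0.0, vel_err=0.0, foot_err=0.0, dt=0.005):
    """Minimal synthetic rollout log with controlled residuals."""
    target = np.tile([8.0, 0.0, 0.0], (n, 1))
    return SimulationLog(
        time=np.arange(n) * dt,
        body_position=np.zeros((n, 3)),
        body_velocity=target + vel_err,
        yaw=np.zeros(n),
        joint_angles=np.zeros((n, 6, 3)),
        joint_torques=np.zeros((n, 6, 3)),
        activations=np.zeros((n, 36)),
        motor_currents=np.full((n, 36), 0.0) + currents,
        motor_spikes=np.zeros((n, 36), dtype=bool),
        foot_body=np.zeros((n, 6, 3)) + foot_err,
        foot_world=np.zeros((n, 6, 3)),
        grf_z=np.zeros((n, 6)),
        stance=np.ones((n, 6), dtype=bool),
        target_velocity=target,
        termination_reason="completed",
        standing_height_mm=1.8,
        dt_s=dt,
        cycle_period_s=1.0,
    )


def zero_reference(n, dt=0.005):
    return GaitTrajectory(
        time=np.arange(n) * dt,
        period_s=1.0,
        q=np.zeros((n, 6, 3)),
        foot_body=np.zeros((n, 6, 3)),
        stance=np.ones((n, 6), dtype=bool),
    )


class TestStage1Objective:
    def test_perfect_tracking_zero_fitness(self):
        log = make_log(200)
        br = objective_stage1(log, zero_reference(200))
        assert br.f == 0.0 and br.f_v == 0.0 and br.f_t == 0.0 and br.f_s == 0.0

    def test_current_energy_term(self):
        # one unit at I=10 for 3 steps with w_s = 1: f = 3 * 10^2 = 300
        log = make_log(3)
        log.motor_currents[:, 0] = 10.0
        br = objective_stage1(log, zero_reference(3), ObjectiveWeights(w_v=0, w_t=0))
        assert br.f_s == pytest.approx(300.0)
        assert br.f == pytest.approx(300.0)

    def test_foot_error_quadratic(self):
        a = objective_stage1(make_log(50, foot_err=0.5), zero_reference(50))
        b = objective_stage1(make_log(50, foot_err=1.0), zero_reference(50))
        assert b.f_t == pytest.approx(4.0 * a.f_t)

    def test_early_fall_charged_as_stationary_body(self):
        # 10 logged steps with residual 12, then 90 padded steps at the
        # full target-speed residual ||nu*||^2 = 64: falling cannot be
        # cheaper than walking
        log = make_log(10, vel_err=2.0)
        full = objective_stage1(log, zero_reference(10), n_full_steps=100)
        short = objective_stage1(log, zero_reference(10), n_full_steps=10)
        assert short.f_v == pytest.approx(10 * 12.0)
        assert full.f_v == pytest.approx(10 * 12.0 + 90 * 64.0)

    def test_early_fall_holds_last_foot_and_current_residuals(self):
        log = make_log(10, foot_err=0.5, currents=2.0)
        full = objective_stage1(log, zero_reference(10), n_full_steps=100)
        short = objective_stage1(log, zero_reference(10), n_full_steps=10)
        assert full.f_t == pytest.approx(10.0 * short.f_t)
        assert full.f_s == pytest.approx(10.0 * short.f_s)

    def test_invariant_under_step_relabelling(self, rng):
        log = make_log(60)
        log.motor_currents[:] = rng.uniform(0, 5, (60, 36))
        log.body_velocity[:] = rng.normal(8, 1, (60, 3))
        base = objective_stage1(log, zero_reference(60))
        perm = rng.permutation(60)
        log.motor_currents[:] = log.motor_currents[perm]
        log.body_velocity[:] = log.body_velocity[perm]
        log.target_velocity[:] = log.target_velocity[perm]
        shuffled = objective_stage1(log, zero_reference(60))
        assert shuffled.f == pytest.approx(base.f, rel=1e-9)

    def test_nonnegative(self, rng):
        log = make_log(30, vel_err=rng.normal(0, 1), foot_err=0.3, currents=2.0)
        assert objective_stage1(log, zero_reference(30)).f >= 0


class TestStage2Objective:
    def test_single_scenario_reduces_to_weighted_sum(self):
        w = ObjectiveWeights()
        assert objective_stage2([(3.0, 4.0)], w) == pytest.approx(3.0 + 40.0)

    def test_perfect_scenarios_zero(self):
        assert objective_stage2([(0.0, 0.0)] * 4) == 0.0

    def test_two_scenario_substitution(self):
        # (1, 2) and (3, 4) with w_s=1, w_v=10: 1+20+3+40 = 64
        assert objective_stage2([(1.0, 2.0), (3.0, 4.0)]) == pytest.approx(64.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            objective_stage2([])


class TestScenarioSampling:
    def test_seeded_and_bounded(self):
        enc = EncodingConfig()
        a = sample_scenarios(np.random.default_rng(5), 20, 0.2, enc)
        b = sample_scenarios(np.random.default_rng(5), 20, 0.2, enc)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.abs(a[:, 0]) <= 0.2 * enc.theta_max_s)
        assert np.all(np.abs(a[:, 1]) <= 0.2 * enc.theta_max_t)

    def test_alpha_zero_degenerate_box(self):
        scen = sample_scenarios(np.random.default_rng(0), 8, 0.0, EncodingConfig())
        np.testing.assert_allclose(scen, 0.0)


class TestCMAES:
    def test_default_config_population_sizes(self):
        cfg = CMAConfig()
        assert cfg.lam == 120 and cfg.mu == 40

    def test_sphere_converges_with_small_population(self):
        es = CMAES(np.full(10, 3.0), lam=16, mu=8, scales=np.ones(10), seed=1)
        for gen in range(200):
            xs = es.ask()
            es.tell(xs, (xs**2).sum(axis=1))
            if es.best_f < 1e-6:
                break
        assert es.best_f < 1e-6
        assert gen < 200

    def test_equal_weights_full_selection_gives_centroid(self):
        es = CMAES(np.zeros(4), lam=6, mu=6, seed=0, recombination="equal")
        xs = es.ask()
        es.tell(xs, np.arange(6.0))
        np.testing.assert_allclose(es.m, xs.mean(axis=0), atol=1e-12)

    def test_bounds_respected_by_samples(self):
        bounds = np.tile([[0.0, 1.0]], (5, 1))
        es = CMAES(np.full(5, 0.5), lam=40, mu=10, bounds=bounds, seed=2)
        xs = es.ask()
        assert xs.min() >= 0.0 and xs.max() <= 1.0

    def test_nonfinite_fitness_ranks_worst(self):
        es = CMAES(np.zeros(3), lam=8, mu=4, scales=np.ones(3), seed=3)
        xs = es.ask()
        fs = (xs**2).sum(axis=1)
        fs[0] = np.nan
        es.tell(xs, fs)
        assert np.isfinite(es.best_f)

    def test_cma_run_trace_best_so_far_non_increasing(self):
        cfg = CMAConfig(lam=12, mu=6, generations=60, seed=4)
        res = cma_run(
            lambda x: float(((x - 2.0) ** 2).sum()),
            cfg,
            bounds=np.tile([[-5.0, 5.0]], (6, 1)),
            m0=np.zeros(6),
        )
        assert np.all(np.diff(res.best_so_far) <= 0)
        assert res.best_f < 1e-3
        assert set(res.trace.columns) >= {"generation", "best_f", "mean_f", "sigma"}

    def test_checkpoint_written(self, tmp_path):
        cfg = CMAConfig(lam=8, mu=4, generations=3, seed=5)
        path = tmp_path / "ck.json"
        cma_run(
            lambda x: float((x**2).sum()),
            cfg,
            bounds=np.tile([[-1.0, 1.0]], (3, 1)),
            m0=np.zeros(3),
            checkpoint_path=path,
        )
        import json

        state = json.loads(path.read_text())
        assert state["generation"] == 2 and "mean" in state


class TestBounds:
    def test_stage1_bounds_shape_and_printed_ranges(self):
        b = stage1_bounds()
        assert b.shape == (198, 2)
        cols = {f: i for i, f in enumerate(UNIT_FIELDS)}
        assert tuple(b[cols["I"]]) == (0.0, 20.0)
        assert tuple(b[cols["c_v"]]) == (-10.5, -3.5)
        assert np.all(b[:, 0] < b[:, 1])

    def test_stage2_bounds_unit_box(self):
        b = stage2_bounds()
        assert b.shape == (608, 2)
        assert np.all(b[:, 0] == 0.0) and np.all(b[:, 1] == 1.0)
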
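"""Body assembly, morphometry, leg kinematics and the reduced backend."""

import numpy as np
import pytest

from formica.skeleton import (
    BodyModel,
    ConfigurationError,
    LEG_NAMES,
    LegGeometry,
    Morphometry,
    MuscleAttachment,
    ReachError,
    ReducedBackend,
    build_body,
    joint_torque_from_muscles,
    leg_foot_position,
    leg_ik,
    leg_jacobian,
    mass_proportions,
    muscle_kinematics,
    torques_from_ground_force,
)


class TestBuildBody:
    def test_middle_femur_length(self, body):
        lm = body.legs[LEG_NAMES.index("LM")]
        assert lm.femur == pytest.approx(2.82)

    def test_eighteen_actuated_dof(self, body):
        assert body.n_actuated_dof == 18

    def test_total_mass_counts_leg_pairs(self, body):
        # trunk 20.45 mg + 2 * (0.60 + 0.50 + 0.70) mg
        assert body.total_mass_mg == pytest.approx(24.05)

    def test_missing_segment_rejected(self):
        morpho = Morphometry(trunk={"head": ((1, 1, 1), 1.0)})
        with pytest.raises(ConfigurationError):
            build_body(morpho)

    def test_nonpositive_morphometry_rejected(self):
        morpho = Morphometry(leg_masses={"front": -1.0, "middle": 0.5, "back": 0.7})
        with pytest.raises(ConfigurationError):
            build_body(morpho)


class TestMassProportions:
    @pytest.mark.parametrize(
        "segment, printed",
        [
            ("head", 21.75),
            ("thorax", 16.09),
            ("abdomen", 47.19),
            ("front_leg_pair", 5.00),
            ("middle_leg_pair", 4.12),
            ("back_leg_pair", 5.82),
        ],
    )
    def test_printed_percentages(self, body, segment, printed):
        props = mass_proportions(body)
        assert props[segment] == pytest.approx(printed, abs=0.05)

    def test_sum_to_one_hundred(self, body):
        assert sum(mass_proportions(body).values()) == pytest.approx(100.0, abs=0.05)

    def test_single_segment_degenerate_body(self, body):
        lonely = BodyModel(
            trunk={"head": body.trunk["head"]},
            legs=[],
            attachments=[],
            joint_half_width_rad=body.joint_half_width_rad,
        )
        assert mass_proportions(lonely) == {"head": pytest.approx(100.0)}


class TestMirrorSymmetry:
    def test_mirroring_is_an_involution(self, body):
        twice = body.mirrored().mirrored()
        for leg_a, leg_b in zip(body.legs, twice.legs):
            assert leg_a == leg_b
        assert twice.trunk == body.trunk

    def test_mirrored_legs_swap_sides(self, body):
        m = body.mirrored()
        assert m.legs[0].name == "LF" and m.legs[0].side == 1
        # the mirrored left-front comes from the original right-front
        assert m.legs[0].root[1] == -body.legs[3].root[1]

    def test_mirror_symmetric_feet(self, body):
        q = np.array([0.2, -0.4, -1.2])
        left = leg_foot_position(body.legs[LEG_NAMES.index("LM")], q)
        right = leg_foot_position(body.legs[LEG_NAMES.index("RM")], q)
        np.testing.assert_allclose(left * [1, -1, 1], right, atol=1e-12)


class TestMuscleTorque:
    def test_antagonistic_balance(self):
        att = MuscleAttachment(leg=0, joint=0)
        assert joint_torque_from_muscles(att, 2.0, 2.0) == pytest.approx(0.0)

    def test_agonist_only(self):
        att = MuscleAttachment(leg=0, joint=0, arm_agonist_mm=0.3)
        assert joint_torque_from_muscles(att, 2.0, 0.0) == pytest.approx(0.6)

    def test_signed_substitution(self):
        att = MuscleAttachment(leg=0, joint=0, arm_agonist_mm=0.5, arm_antagonist_mm=0.5)
        assert joint_torque_from_muscles(att, 2.0, 1.0) == pytest.approx(0.5)

    def test_negative_forces_rejected(self):
        att = MuscleAttachment(leg=0, joint=0)
        with pytest.raises(ValueError):
            joint_torque_from_muscles(att, -1.0, 0.0)


class TestMuscleKinematics:
    def test_rest_angle_gives_rest_length(self):
        att = MuscleAttachment(leg=0, joint=0, q_rest=0.3)
        (l_a, v_a), (l_n, v_n) = muscle_kinematics(att, 0.3, 0.0)
        assert l_a == pytest.approx(1.0) and l_n == pytest.approx(1.0)
        assert v_a == 0.0 and v_n == 0.0

    def test_gain_substitution(self):
        # the agonist (positive-torque muscle) shortens as the angle grows
        att = MuscleAttachment(leg=0, joint=0, q_rest=0.0, gain=0.5)
        (l_a, _), (l_n, _) = muscle_kinematics(att, 0.2, 0.0)
        assert l_a == pytest.approx(0.9)
        assert l_n == pytest.approx(1.1)

    def test_velocity_signs_opposite(self):
        att = MuscleAttachment(leg=0, joint=0, gain=0.5)
        (_, v_a), (_, v_n) = muscle_kinematics(att, 0.0, 2.0)
        assert v_a == pytest.approx(-1.0) and v_n == pytest.approx(1.0)

    def test_each_muscle_damps_the_motion_it_drives(self):
        # agonist torque is positive; during +qdot motion it must be on the
        # concentric (force-dropping) branch so the pair opposes the motion
        att = MuscleAttachment(leg=0, joint=0, gain=0.5)
        (_, v_a), (_, v_n) = muscle_kinematics(att, 0.0, 2.0)
        assert v_a < 0  # agonist shortening -> concentric force drop
        assert v_n > 0  # antagonist lengthening -> eccentric brake


def planar_two_link():
    """Unit-link planar arm embedded in the leg chain (yaw frozen at 0)."""
    return LegGeometry(
        name="T2", side=1, position="middle", coxa=0.0, femur=1.0,
        tibia=1.0, tarsus=0.0, mass_mg=1.0, root=(0.0, 0.0, 0.0), splay_rad=0.0,
    )


class TestJacobian:
    def test_planar_two_link_textbook_case(self):
        # straight along x, unit transverse tip force: torques (2, 1);
        # the fully extended pose is singular for the embedding 3-DOF chain
        leg = planar_two_link()
        with pytest.warns(RuntimeWarning):
            tau = torques_from_ground_force(leg, np.zeros(3), np.array([0.0, 0.0, 1.0]))
        assert tau[1] == pytest.approx(2.0)
        assert tau[2] == pytest.approx(1.0)
        assert tau[0] == pytest.approx(0.0)

    def test_zero_force_zero_torques(self, body):
        q = np.array([0.1, -0.5, -1.5])
        tau = torques_from_ground_force(body.legs[0], q, np.zeros(3))
        np.testing.assert_allclose(tau, 0.0)

    def test_matches_finite_difference_oracle(self, body, rng):
        h = 1e-6
        for leg in body.legs:
            for _ in range(5):
                q = rng.uniform([-0.5, -1.0, -2.2], [0.5, 1.0, -0.3])
                jac = leg_jacobian(leg, q)
                num = np.zeros((3, 3))
                for j in range(3):
                    dq = np.zeros(3)
                    dq[j] = h
                    num[:, j] = (
                        leg_foot_position(leg, q + dq) - leg_foot_position(leg, q - dq)
                    ) / (2 * h)
                np.testing.assert_allclose(jac, num, atol=1e-6)
                force = rng.normal(0, 1, 3)
                np.testing.assert_allclose(
                    torques_from_ground_force(leg, q, force), num.T @ force, atol=1e-5
                )

    def test_singular_configuration_warns_but_returns(self):
        leg = planar_two_link()
        # fold the chain so the foot sits on the yaw axis: q1 column vanishes
        q = np.array([0.0, np.pi / 2, 0.0])
        with pytest.warns(RuntimeWarning):
            tau = torques_from_ground_force(leg, q, np.array([1.0, 0.0, 0.0]))
        assert np.all(np.isfinite(tau))


class TestInverseKinematics:
    def test_round_trip_on_random_reachable_targets(self, body, rng):
        for i, leg in enumerate(body.legs):
            base = body.neutral_foot_position(i)
            for _ in range(20):
                target = base + rng.normal(0, 0.8, 3) * [1.0, 1.0, 0.3]
                q = leg_ik(leg, target)
                np.testing.assert_allclose(
                    leg_foot_position(leg, q), target, atol=1e-9
                )

    def test_unreachable_target_raises(self, body):
        with pytest.raises(ReachError):
            leg_ik(body.legs[0], np.array([50.0, 50.0, 0.0]))

    def test_clamped_solution_stays_finite(self, body):
        q = leg_ik(body.legs[0], np.array([50.0, 50.0, 0.0]), clamp=True)
        assert np.all(np.isfinite(q))


class TestMorphometryCSV:
    def test_tables_load_in_printed_column_order(self, tmp_path):
        lengths = tmp_path / "lengths.csv"
        lengths.write_text(
            "position,coxa,femur,tibia,tarsus\n"
            "Front,0.25,2.49,2.33,2.37\n"
            "Middle,0.25,2.82,2.74,3.13\n"
            "Back,0.25,3.48,3.40,3.80\n"
        )
        masses = tmp_path / "masses.csv"
        masses.write_text(
            "segment,dim_x,dim_y,dim_z,mass\n"
            "Head,2.67,2.20,0.50,5.23\n"
            "Thorax,3.07,1.01,0.50,3.87\n"
            "Abdomen,3.43,2.46,0.50,11.35\n"
            "Front leg,0.2,0.2,7.44,0.60\n"
            "Middle leg,0.2,0.2,8.94,0.50\n"
            "Back leg,0.2,0.2,10.93,0.70\n"
        )
        morpho = Morphometry.from_csv(lengths, masses)
        built = build_body(morpho)
        default = build_body()
        assert built.total_mass_mg == pytest.approx(default.total_mass_mg)
        assert built.legs[1].femur == pytest.approx(2.82)


def test_body_yaml_round_trip(body, tmp_path):
    path = tmp_path / "body.yaml"
    body.to_yaml(path)
    loaded = BodyModel.from_yaml(path)
    assert loaded.total_mass_mg == pytest.approx(body.total_mass_mg)
    for a, b in zip(loaded.legs, body.legs):
        assert a == b
    for i in range(6):
        for j in range(3):
            assert loaded.attachments[i][j].q_rest == pytest.approx(
                body.attachments[i][j].q_rest
            )


class TestReducedBackend:
    def test_zero_gravity_zero_torque_state_unchanged(self, body):
        backend = ReducedBackend(body, gravity_mm_s2=0.0)
        state = backend.reset()
        new, grf = backend.step(state, {})
        np.testing.assert_allclose(new.position, state.position)
        np.testing.assert_allclose(new.velocity, state.velocity)
        assert new.yaw == state.yaw
        assert grf == {}

    def test_unsupported_body_sinks_under_gravity(self, body):
        backend = ReducedBackend(body)
        state = backend.reset()
        heights = [state.position[2]]
        for _ in range(50):
            state, _ = backend.step(state, {})
            heights.append(state.position[2])
        # strictly decreasing until the trunk rests on the ground
        above = [h for h in heights if h > 0.0]
        assert len(above) > 2
        assert all(b < a for a, b in zip(above, above[1:]))
        assert heights[-1] == 0.0

    def test_deterministic_given_identical_inputs(self, body):
        q = leg_ik(body.legs[0], body.neutral_foot_position(0))
        tau = np.array([0.01, 0.2, 0.1])
        outs = []
        for _ in range(2):
            backend = ReducedBackend(body)
            state = backend.reset()
            for _ in range(100):
                state, grf = backend.step(state, {0: (q, tau)})
            outs.append((state.position.copy(), state.yaw, grf[0].copy()))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        assert outs[0][1] == outs[1][1]
        np.testing.assert_array_equal(outs[0][2], outs[1][2])

    def test_vertical_support_slows_sinking(self, body):
        # a stance leg transmitting upward force keeps the body higher
        i = LEG_NAMES.index("LM")
        leg = body.legs[i]
        q = leg_ik(leg, body.neutral_foot_position(i))
        jac = leg_jacobian(leg, q)
        # static balance tau + J^T f = 0: this torque transmits +0.05 mN up
        tau_up = -jac.T @ np.array([0.0, 0.0, 0.05])
        backend = ReducedBackend(body)
        s_up, s_down = backend.reset(), backend.reset()
        for _ in range(100):
            s_up, _ = backend.step(s_up, {i: (q, tau_up)})
            s_down, _ = backend.step(s_down, {i: (q, np.zeros(3))})
        assert s_up.position[2] > s_down.position[2]
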
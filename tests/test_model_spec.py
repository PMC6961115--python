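import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actinfsim.model_spec import (
    ACTION_LABELS,
    C_CAT_INTACT,
    C_CAT_LESIONED,
    ENV_CAT_DISTAL,
    ENV_CAT_PROXIMAL,
    ENV_DOG_DISTAL,
    ENV_DOG_PROXIMAL,
    ENV_NONE,
    FIGHT_FLIGHT,
    FREEZE,
    HORIZON,
    N_POLICIES,
    N_STEPS,
    ORIENT,
    ROAM,
    VIS_CAT,
    FactorSpec,
    ModalitySpec,
    ModelConfig,
    ModelValidationError,
    PolicySet,
    build_jerry_model,
    build_policy_set,
    load_model,
    model_from_dict,
    model_to_dict,
    save_model,
    validate_model,
    variant_config,
)

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestSpecs:
    def test_factor_needs_two_levels(self):
        with pytest.raises(ValueError):
            FactorSpec("x", ("only",))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            ModalitySpec("x", ("a", "a"))


class TestPolicySet:
    def test_seven_policies_with_stated_composition(self):
        ps = build_policy_set()
        assert ps.U.shape == (N_STEPS, N_POLICIES)
        has_fof = [(ps.U[:, p] == FIGHT_FLIGHT).any() for p in range(N_POLICIES)]
        has_frz = [(ps.U[:, p] == FREEZE).any() for p in range(N_POLICIES)]
        assert sum(has_fof) == 3
        assert sum(has_frz) == 3
        neither = [not (f or z) for f, z in zip(has_fof, has_frz)]
        assert sum(neither) == 1

    def test_all_policies_prefixed_roam_then_orient(self):
        ps = build_policy_set()
        assert (ps.U[0] == ROAM).all()
        assert (ps.U[1] == ORIENT).all()

    def test_policy_1_is_unrelenting_fight_or_flight(self):
        ps = build_policy_set()
        assert ps.U[:, 0].tolist() == [ROAM, ORIENT] + [FIGHT_FLIGHT] * 3

    def test_policy_4_is_unrelenting_freeze(self):
        ps = build_policy_set()
        assert ps.U[:, 3].tolist() == [ROAM, ORIENT] + [FREEZE] * 3

    def test_bias_uniform(self):
        ps = build_policy_set()
        np.testing.assert_allclose(ps.E, 1.0 / N_POLICIES)

    def test_columns_distinct(self):
        ps = build_policy_set()
        cols = {tuple(ps.U[:, p]) for p in range(N_POLICIES)}
        assert len(cols) == N_POLICIES


class TestBuilder:
    def test_default_model_validates(self, intact_model):
        assert validate_model(intact_model).ok

    def test_intact_vision_preferences(self, intact_model):
        m = intact_model
        vis = m.C[m.modality_index("vision")]
        np.testing.assert_array_equal(vis, [2.0, -1.0, 1.0, -6.25, -0.5])

    def test_lesion_changes_exactly_one_scalar(self, intact_model, lesioned_model):
        diffs = []
        for name, a, b in [
            *[("A", x, y) for x, y in zip(intact_model.A, lesioned_model.A)],
            *[("B", x, y) for x, y in zip(intact_model.B, lesioned_model.B)],
            *[("C", x, y) for x, y in zip(intact_model.C, lesioned_model.C)],
            *[("D", x, y) for x, y in zip(intact_model.D, lesioned_model.D)],
        ]:
            idx = np.argwhere(a != b)
            for coord in idx:
                diffs.append((name, tuple(coord), a[tuple(coord)], b[tuple(coord)]))
        assert len(diffs) == 1
        name, coord, before, after = diffs[0]
        assert name == "C"
        assert before == C_CAT_INTACT == -6.25
        assert after == C_CAT_LESIONED == -10.0

    def test_lesioned_vision_vector(self, lesioned_model):
        vis = lesioned_model.C[1]
        np.testing.assert_array_equal(vis, [2.0, -1.0, 1.0, -10.0, -0.5])

    def test_unsafe_prior_one_hot_on_distal_cat(self, unsafe_model):
        d = unsafe_model.D[0]
        expect = np.zeros(5)
        expect[ENV_CAT_DISTAL] = 1.0
        np.testing.assert_array_equal(d, expect)

    def test_safe_prior_flat(self, intact_model):
        np.testing.assert_allclose(intact_model.D[0], 0.2)

    def test_motion_heart_priors_roaming_start(self, intact_model):
        np.testing.assert_array_equal(intact_model.D[1], [1.0, 0.0])
        np.testing.assert_array_equal(intact_model.D[2], [1.0, 0.0])

    def test_audition_and_proprio_preferences(self, intact_model):
        np.testing.assert_array_equal(intact_model.C[0], [1.0, -1.0, -2.0])
        np.testing.assert_array_equal(intact_model.C[2], [1.0, -1.0, -10.0, 0.0])

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="p_attract"):
            ModelConfig(p_attract=1.5)
        with pytest.raises(ValueError, match="context"):
            ModelConfig(context="danger")

    def test_variant_config_mapping(self):
        assert not variant_config("I").lesioned
        assert variant_config("II").context == "unsafe"
        assert variant_config("III").lesioned
        cfg = variant_config("IV")
        assert cfg.lesioned and cfg.context == "unsafe"
        with pytest.raises(ModelValidationError):
            variant_config("V")


class TestContingencies:
    """Qualitative likelihood/transition constraints of the scenario world."""

    def test_blur_when_moving_with_high_heart(self, intact_model):
        A_vis = intact_model.A[1]
        for env in range(5):
            col = A_vis[:, env, 0, 1]  # moving, high heart
            assert col[4] == 1.0  # blur regardless of the scene

    def test_moving_low_heart_distal_equiprobable_dot_or_empty(self, intact_model):
        A_vis = intact_model.A[1]
        for env in (ENV_CAT_DISTAL, ENV_DOG_DISTAL):
            col = A_vis[:, env, 0, 0]
            assert col[0] == pytest.approx(0.5)
            assert col[1] == pytest.approx(0.5)

    def test_still_vision_veridical(self, intact_model):
        A_vis = intact_model.A[1]
        assert A_vis[0, 0, 1, 0] == 1.0  # none -> empty horizon
        assert A_vis[1, ENV_CAT_DISTAL, 1, 0] == 1.0  # distal -> dot
        assert A_vis[VIS_CAT, ENV_CAT_PROXIMAL, 1, 0] == 1.0
        assert A_vis[2, ENV_DOG_PROXIMAL, 1, 1] == 1.0

    def test_spurious_sound_probability(self):
        m = build_jerry_model(ModelConfig(eps_sound=0.25))
        A_aud = m.A[0]
        assert A_aud[0, 0, 0, 0] == pytest.approx(0.75)
        assert A_aud[1, 0, 0, 0] + A_aud[2, 0, 0, 0] == pytest.approx(0.25)

    def test_proprio_likelihood_one_hot(self, intact_model):
        A_pb = intact_model.A[2]
        for mo in range(2):
            for h in range(2):
                for env in range(5):
                    col = A_pb[:, env, mo, h]
                    assert col.max() == 1.0 and col.sum() == 1.0

    def test_cat_dog_transitions_forbidden_exactly(self, intact_model):
        B_env = intact_model.B[0]
        cat = (ENV_CAT_DISTAL, ENV_CAT_PROXIMAL)
        dog = (ENV_DOG_DISTAL, ENV_DOG_PROXIMAL)
        for a in range(4):
            for i in cat:
                for j in dog:
                    assert B_env[a, j, i] == 0.0
                    assert B_env[a, i, j] == 0.0

    def test_motion_heart_deterministic_action_effects(self, intact_model):
        B_mot, B_hrt = intact_model.B[1], intact_model.B[2]
        assert (B_mot[ROAM, 0] == 1.0).all()
        assert (B_mot[FIGHT_FLIGHT, 0] == 1.0).all()
        assert (B_mot[ORIENT, 1] == 1.0).all()
        assert (B_mot[FREEZE, 1] == 1.0).all()
        assert (B_hrt[ORIENT, 1] == 1.0).all()
        assert (B_hrt[FIGHT_FLIGHT, 1] == 1.0).all()
        assert (B_hrt[ROAM, 0] == 1.0).all()
        assert (B_hrt[FREEZE, 0] == 1.0).all()

    def test_evasion_limit_moves_proximal_cat_out(self):
        m = build_jerry_model(ModelConfig(p_evade=1.0))
        B_env = m.B[0]
        assert B_env[FIGHT_FLIGHT, ENV_CAT_DISTAL, ENV_CAT_PROXIMAL] == 1.0
        assert B_env[FIGHT_FLIGHT, ENV_NONE, ENV_CAT_DISTAL] == 1.0

    def test_freeze_conceals_but_does_not_displace_a_proximal_cat(self):
        m = build_jerry_model(ModelConfig(p_wander=0.4))
        B_env = m.B[0]
        # a distal cat loses interest at the wander rate; a proximal one stays
        assert B_env[FREEZE, ENV_NONE, ENV_CAT_DISTAL] == pytest.approx(0.4)
        assert B_env[FREEZE, ENV_CAT_PROXIMAL, ENV_CAT_PROXIMAL] == 1.0


@settings(max_examples=40, deadline=None)
@given(eps=probs, pa=probs, pe=probs, pw=probs)
def test_probability_arrays_normalized_over_parameter_grid(eps, pa, pe, pw):
    model = build_jerry_model(
        ModelConfig(eps_sound=eps, p_attract=pa, p_evade=pe, p_wander=pw)
    )
    report = validate_model(model)
    assert report.ok, [str(v) for v in report.violations]


class TestValidateModel:
    def test_scaled_likelihood_reports_coordinates(self, intact_model):
        import dataclasses

        bad_A = tuple(a.copy() for a in intact_model.A)
        bad_A[0][:, 2, 0, 0] *= 0.5
        bad = dataclasses.replace(intact_model, A=bad_A)
        report = validate_model(bad)
        assert not report.ok
        assert len(report.violations) == 1
        v = report.violations[0]
        assert v.kind == "normalization"
        assert "A[audition](2, 0, 0)" in v.location

    def test_bad_policy_prefix_reported(self, intact_model):
        import dataclasses

        U = intact_model.policies.U.copy()
        U[0, 2] = ORIENT
        bad_ps = PolicySet(
            actions=ACTION_LABELS, U=U, E=intact_model.policies.E
        )
        bad = dataclasses.replace(intact_model, policies=bad_ps)
        report = validate_model(bad)
        assert any(v.kind == "policy-prefix" and "2" in v.location
                   for v in report.violations)

    def test_negative_probability_reported(self, intact_model):
        import dataclasses

        D = tuple(d.copy() for d in intact_model.D)
        D[0][0] = -0.2
        D[0][1] = 0.6
        bad = dataclasses.replace(intact_model, D=D)
        report = validate_model(bad)
        kinds = {v.kind for v in report.violations}
        assert "negative" in kinds

    def test_horizon_constraint(self, intact_model):
        import dataclasses

        bad = dataclasses.replace(intact_model, horizon=HORIZON + 1)
        report = validate_model(bad)
        assert any(v.kind == "dimension" and v.location == "horizon"
                   for v in report.violations)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, lesioned_model):
        path = tmp_path / "model.yaml"
        save_model(lesioned_model, path)
        loaded = load_model(path)
        for a, b in zip(lesioned_model.A, loaded.A):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(lesioned_model.B, loaded.B):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(lesioned_model.C, loaded.C):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(lesioned_model.D, loaded.D):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(
            lesioned_model.policies.U, loaded.policies.U
        )
        assert loaded.config == lesioned_model.config

    def test_dict_has_named_blocks(self, intact_model):
        doc = model_to_dict(intact_model)
        for key in ("factors", "modalities", "A", "B", "C", "D", "E", "U"):
            assert key in doc

    def test_dict_round_trip(self, intact_model):
        doc = model_to_dict(intact_model)
        again = model_to_dict(model_from_dict(doc))
        assert doc == again

    def test_shipped_default_documents(self):
        from importlib.resources import files

        for name, lesioned in (("intact.yaml", False), ("lesioned.yaml", True)):
            path = files("actinfsim") / "models" / name
            loaded = model_from_dict(__import__("yaml").safe_load(path.read_text()))
            ref = build_jerry_model(ModelConfig(lesioned=lesioned))
            for a, b in zip(ref.C, loaded.C):
                np.testing.assert_array_equal(a, b)
            assert validate_model(loaded).ok
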
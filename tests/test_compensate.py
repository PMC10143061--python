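"""Compensation model assembly, command correction, closed-loop trials."""

import json

import numpy as np
import pytest

import stagecal as sc
from stagecal.compensate import rectangle_plan
from stagecal.errors import SchemaError


class TestCompensateMove:
    def test_identity_model_is_identity(self):
        model = sc.CompensationModel(M_prime=1.0, delta=(0, 0), theta_deg=0.0,
                                     axis=sc.AxisErrors.zero())
        for d in [(100, 0), (0, 90), (-100, 0), (0, -90)]:
            cmd, _ = sc.compensate_move(model, d)
            assert np.allclose(cmd, d)

    def test_pure_deflection_is_inverse_rotation(self):
        model = sc.CompensationModel(M_prime=1.0, delta=(0, 0),
                                     theta_deg=-5.578,
                                     axis=sc.AxisErrors.zero())
        cmd, _ = sc.compensate_move(model, (100.0, 0.0))
        th = np.radians(5.578)
        assert np.allclose(cmd, (100 * np.cos(th), 100 * np.sin(th)))

    def test_pure_axis_error_is_inverse_scaling(self):
        model = sc.CompensationModel(M_prime=1.0, delta=(0, 0), theta_deg=0.0,
                                     axis=sc.AxisErrors(dxp=-0.0087))
        cmd, _ = sc.compensate_move(model, (100.0, 0.0))
        assert np.isclose(cmd[0], 100 / 0.9913)
        assert np.isclose(cmd[0], 100.878, atol=1e-3)

    def test_paper_literal_mode_evaluates_printed_formula(self):
        ax = sc.AxisErrors(dxp=-0.0087, dyp=-0.0095)
        model = sc.CompensationModel(M_prime=0.9922, delta=(-2.3718, -2.7474),
                                     theta_deg=-5.578, axis=ax,
                                     mode="paper_literal")
        d = np.array([100.0, 100.0])
        cmd, _ = sc.compensate_move(model, d)
        s = np.hypot(*d)
        g = (1 - 0.0087) * np.cos(np.radians(45)) + \
            (1 - 0.0095) * np.sin(np.radians(45))
        th = np.radians(-5.578)
        expect = d + 0.9922 * np.array([-2.3718, -2.7474]) * g * s * \
            np.array([np.cos(th), np.sin(th)])
        assert np.allclose(cmd, expect)

    def test_delta_applied_once_for_absolute_positioning(self, truth_model):
        d = np.array([200.0, -100.0])
        model = sc.CompensationModel(
            M_prime=1.0, delta=(1.5, -0.7), theta_deg=0.0,
            axis=sc.AxisErrors.zero(),
        )
        plain, _ = sc.compensate_move(model, d, apply_delta=False)
        offset, _ = sc.compensate_move(model, d, apply_delta=True)
        assert np.allclose(offset - plain, (1.5, -0.7))


def test_inverse_consistency_with_exact_model(default_truth, truth_model):
    """forward(compensate(d)) = d (in image um) when the model equals the
    ground truth, in every quadrant."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        d = rng.uniform(-500, 500, 2)
        cmd, _ = sc.compensate_move(truth_model, d)
        actual = sc.forward_stage_model(default_truth, cmd)
        th = np.radians(default_truth.theta_true_deg)
        c, s = np.cos(th), np.sin(th)
        achieved = np.array([c * actual[0] - s * actual[1],
                             s * actual[0] + c * actual[1]])
        achieved *= default_truth.M_true / default_truth.M_nominal
        assert np.allclose(achieved, d, atol=1e-6)


class TestModelSerialization:
    def test_round_trip(self, truth_model):
        doc = truth_model.to_json()
        back = sc.CompensationModel.from_json(json.loads(json.dumps(doc)))
        assert back.M_prime == truth_model.M_prime
        assert back.theta_deg == truth_model.theta_deg
        assert back.axis == truth_model.axis
        assert back.intr == truth_model.intr

    def test_unknown_schema_rejected(self, truth_model):
        doc = truth_model.to_json()
        doc["schema_version"] = "99"
        with pytest.raises(SchemaError):
            sc.CompensationModel.from_json(doc)

    def test_missing_field_named(self, truth_model):
        doc = truth_model.to_json()
        doc.pop("theta_deg")
        with pytest.raises(SchemaError, match="theta_deg"):
            sc.CompensationModel.from_json(doc)

    def test_build_requires_calibration_fields(self):
        with pytest.raises(SchemaError, match="M_prime"):
            sc.build_compensation_model({}, 0.0, sc.AxisErrors.zero())


class TestSingleShot:
    def test_zero_error_truth_gives_zero_residual(self):
        truth = sc.GroundTruth(M_true=20.0, theta_true_deg=0.0, k_true=0.0,
                               dxp=0, dxm=0, dyp=0, dym=0)
        model = sc.CompensationModel(M_prime=1.0, delta=(0, 0), theta_deg=0.0,
                                     axis=sc.AxisErrors.zero(),
                                     intr=truth.intr)
        rep = sc.single_shot_trial(model, truth, (901.0, 202.0))
        assert rep.residual_norm < 1e-9

    def test_exact_model_residual_vanishes(self, default_truth, truth_model):
        rep = sc.single_shot_trial(truth_model, default_truth, (901.0, 202.0))
        assert rep.residual_norm < 1e-9

    def test_compensation_beats_identity(self, default_truth, truth_model):
        rng = np.random.default_rng(5)
        comp, uncomp = [], []
        for _ in range(20):
            t = rng.uniform([100, 100], [1100, 800])
            comp.append(sc.single_shot_trial(
                truth_model, default_truth, t).residual_norm)
            uncomp.append(sc.single_shot_trial(
                truth_model, default_truth, t,
                compensated=False).residual_norm)
        assert np.median(comp) < np.median(uncomp)

    def test_residual_norm_invariant(self, default_truth, truth_model):
        rep = sc.single_shot_trial(truth_model, default_truth, (50.0, 880.0),
                                   compensated=False)
        assert np.isclose(rep.residual_norm**2,
                          rep.residual_x**2 + rep.residual_y**2, atol=1e-12)


def test_residuals_degrade_monotonically_with_theta_error(default_truth):
    """Injecting growing deflection miscalibration grows the residual."""
    rng = np.random.default_rng(23)
    targets = rng.uniform([100, 100], [1100, 800], (15, 2))
    medians = []
    for dth in (0.0, 0.1, 0.3, 0.9):
        model = sc.CompensationModel(
            M_prime=default_truth.M_true / default_truth.M_nominal,
            delta=(0, 0),
            theta_deg=default_truth.theta_true_deg + dth,
            axis=default_truth.axis_errors(),
            intr=default_truth.intr,
        )
        medians.append(np.median([
            sc.single_shot_trial(model, default_truth, t).residual_norm
            for t in targets
        ]))
    assert all(a < b for a, b in zip(medians, medians[1:]))


class TestCumulative:
    def test_zero_error_truth_gives_near_zero_mismatch(self):
        truth = sc.GroundTruth(M_true=20.0, theta_true_deg=0.0, k_true=0.0,
                               dxp=0, dxm=0, dyp=0, dym=0, seed=3)
        model = sc.CompensationModel(M_prime=1.0, delta=(0, 0), theta_deg=0.0,
                                     axis=sc.AxisErrors.zero(),
                                     intr=truth.intr)
        rep = sc.cumulative_trial(model, truth, plan_class=1, seed=0)
        assert rep.residual_norm < 0.1  # registration tolerance, um

    def test_uncompensated_mismatch_matches_forward_arithmetic(
            self, default_truth, truth_model):
        rep = sc.cumulative_trial(truth_model, default_truth, plan_class=3,
                                  seed=0, compensated=False)
        n = 3
        expect = 600 * n * np.array([
            default_truth.dxp - default_truth.dxm,
            default_truth.dyp - default_truth.dym,
        ])
        assert abs(rep.residual_norm - np.linalg.norm(expect)) < 0.25
        assert rep.meta["n_images"] == 13

    def test_invalid_plan_class_rejected(self, truth_model, default_truth):
        with pytest.raises(Exception):
            rectangle_plan(6)


class TestStageCompensator:
    def test_fit_transform_and_params(self, default_truth):
        block = {"M_prime": 0.9922, "delta_x": 0.0, "delta_y": 0.0,
                 "k": 5e-8, "u0": 600.0, "v0": 450.0, "fx": 0.9922,
                 "fy": 0.9922}
        est = sc.StageCompensator().fit(
            {"calibration": block, "theta_deg": -5.578,
             "axis_errors": {"dxp": -0.0087, "dxm": -0.0097,
                             "dyp": -0.0095, "dym": -0.0087}}
        )
        out = est.transform([[100.0, 0.0], [0.0, -50.0]])
        assert out.shape == (2, 2)
        assert out[0, 0] > 100  # under-travel means over-command
        params = est.get_params()
        assert params["mode"] == "coherent"
        from sklearn.base import clone

        clone(est)  # estimator is cloneable

    def test_save_load_round_trip(self, tmp_path, truth_model):
        est = sc.StageCompensator()
        est.model_ = truth_model
        est.save(tmp_path / "model.json")
        back = sc.StageCompensator.load(tmp_path / "model.json")
        assert back.model_.axis == truth_model.axis
        assert np.allclose(back.transform([[100.0, 10.0]]),
                           est.transform([[100.0, 10.0]]))

    def test_missing_sections_raise_schema_errors(self):
        with pytest.raises(SchemaError):
            sc.StageCompensator().fit({"calibration": {}, "theta_deg": 0.0})


def test_error_transform_exposed_by_model(truth_model):
    T = truth_model.error_transform(beta_deg=0.0).T
    s = np.sin(np.radians(truth_model.theta_deg))
    assert np.isclose(T[1, 0], s * truth_model.M_prime)
    assert np.isclose(T[0, 2], truth_model.axis.dxp * truth_model.M_prime)
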
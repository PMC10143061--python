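"""Synthetic rig: rendering, series simulation, forward stage model."""

import numpy as np
import pytest

import stagecal as sc
from stagecal.errors import ConfigurationError, InvalidArgumentError


class TestRenderGridImage:
    def test_default_raster_size(self, default_truth):
        img = sc.render_grid_image(default_truth, sc.GridSpec())
        assert img.shape == (900, 1200)
        assert img.dtype == np.uint8

    def test_deterministic_for_fixed_seed(self, default_truth):
        spec = sc.GridSpec(image_w=300, image_h=200)
        a = sc.render_grid_image(default_truth, spec, (7.0, -3.0), noise_key=4)
        b = sc.render_grid_image(default_truth, spec, (7.0, -3.0), noise_key=4)
        assert np.array_equal(a, b)

    def test_noise_key_varies_noise_only(self, default_truth):
        spec = sc.GridSpec(image_w=300, image_h=200)
        a = sc.render_grid_image(default_truth, spec, noise_key=0)
        b = sc.render_grid_image(default_truth, spec, noise_key=1)
        assert not np.array_equal(a, b)
        assert abs(a.astype(float).mean() - b.astype(float).mean()) < 1.0

    def test_axis_parallel_lines_when_no_rotation_or_distortion(self):
        truth = sc.GroundTruth(theta_true_deg=0.0, k_true=0.0,
                               noise_sigma=0.0)
        lines = sc.extract_center_lines(
            sc.render_grid_image(truth, sc.GridSpec())
        )
        assert abs(lines.tilt_deg("vertical")) < 0.02
        assert abs(lines.tilt_deg("horizontal")) < 0.02

    def test_empty_view_is_a_configuration_error(self):
        truth = sc.GroundTruth(speckle_n=0, noise_sigma=0.0)
        with pytest.raises(ConfigurationError):
            sc.render_grid_image(truth, sc.GridSpec(), stage_pos=(50000, 0))


class TestForwardStageModel:
    def test_zero_errors_identity(self):
        truth = sc.GroundTruth(dxp=0, dxm=0, dyp=0, dym=0)
        assert np.allclose(
            sc.forward_stage_model(truth, (123.4, -56.7)), (123.4, -56.7)
        )

    def test_relative_scaling(self, default_truth):
        actual = sc.forward_stage_model(default_truth, (100.0, 0.0))
        assert np.allclose(actual, (100 * (1 - 0.0087), 0.0))
        assert np.isclose(actual[0], 99.13)

    def test_direction_selects_error_sign(self):
        truth = sc.GroundTruth(dxp=-0.01, dxm=0.02)
        fwd = sc.forward_stage_model
        assert np.isclose(fwd(truth, (100, 0))[0], 99.0)
        assert np.isclose(fwd(truth, (-100, 0))[0], -102.0)

    def test_rejects_non_finite(self, default_truth):
        with pytest.raises(InvalidArgumentError):
            sc.forward_stage_model(default_truth, (np.inf, 0.0))


class TestSimulateSeries:
    def test_series_length_and_commanded_positions(self, default_truth):
        plan = sc.DisplacementPlan(axis="x", direction=1, n_steps=3,
                                   step_um=600)
        spec = sc.GridSpec(image_w=300, image_h=220)
        frames, commanded = sc.simulate_series(default_truth, spec, plan)
        assert len(frames) == 4
        assert np.allclose(commanded[:, 0], [0, 600, 1200, 1800])
        assert np.allclose(commanded[:, 1], 0)

    def test_half_frame_overlap_offset_zero_errors(self):
        """With zero stage errors and no deflection, a half-frame X step
        produces exactly a half-width pixel offset."""
        truth = sc.GroundTruth(theta_true_deg=0.0, k_true=0.0, dxp=0, dxm=0,
                               dyp=0, dym=0, noise_sigma=0.0, seed=5)
        spec = sc.GridSpec()
        step = (spec.image_w / 2) / truth.px_per_um
        plan = sc.DisplacementPlan(axis="x", n_steps=1, step_um=step)
        frames, _ = sc.simulate_series(truth, spec, plan)
        expected = step * truth.px_per_um
        r = sc.estimate_offset(frames[0], frames[1],
                               expected=(expected, 0.0), search_radius=12.0)
        assert abs(r.dx - expected) < 0.1
        assert abs(r.dy) < 0.1

    def test_injected_error_shrinks_measured_offset(self):
        """dx+ = -1% at a 600 um step shows up as a 6 um-equivalent deficit
        in the measured inter-frame offset."""
        truth = sc.GroundTruth(theta_true_deg=0.0, k_true=0.0, dxp=-0.01,
                               dxm=0, dyp=0, dym=0, noise_sigma=0.0, seed=6)
        spec = sc.GridSpec()
        # off the engraved scale: the 600 um step is 12 grid pitches, so
        # grid content would correlate at the nominal offset and mask the
        # injected error; the blank-substrate speckle pins the true offset
        plan = sc.DisplacementPlan(axis="x", n_steps=1, step_um=600,
                                   start_um=(0.0, 1600.0))
        frames, _ = sc.simulate_series(truth, spec, plan)
        nominal = 600 * truth.px_per_um
        r = sc.estimate_offset(frames[0], frames[1],
                               expected=(nominal, 0.0), search_radius=12.0)
        deficit_um = (nominal - r.dx) / truth.px_per_um
        assert np.isclose(deficit_um, 6.0, atol=0.15)

    def test_rectangle_plan_image_counts(self):
        from stagecal.compensate import rectangle_plan

        # class 5 walks 21 frames (4*5 steps + start) of 600 um
        steps = rectangle_plan(5)
        assert len(steps) + 1 == 21
        assert np.allclose(np.abs(steps).max(axis=1), 600.0)
        assert np.allclose(steps.sum(axis=0), 0.0)
        assert len(rectangle_plan(1)) + 1 == 5


def test_pixel_scale_consistency(noise_free_truth):
    """A commanded move of s um displaces the image content by
    s * px_per_um pixels (zero-error rig), within 0.1 px."""
    truth = sc.GroundTruth(dxp=0, dxm=0, dyp=0, dym=0, noise_sigma=0.0,
                           theta_true_deg=0.0, k_true=0.0, seed=2)
    spec = sc.GridSpec()
    r = sc.estimate_offset(
        sc.render_grid_image(truth, spec, (0, 0), 0),
        sc.render_grid_image(truth, spec, (250.0, 0.0), 1),
        expected=(250 * truth.px_per_um, 0), search_radius=12.0,
    )
    assert abs(r.dx - 250 * truth.px_per_um) < 0.1


def test_ground_truth_sidecar_round_trip(tmp_path, default_truth):
    spec = sc.GridSpec(image_w=240, image_h=180)
    plan = sc.DisplacementPlan(n_steps=1, step_um=120)
    frames, commanded = sc.simulate_series(default_truth, spec, plan)
    out = sc.simulate.write_series(frames, commanded, default_truth,
                                   tmp_path / "series")
    import json

    sidecar = json.loads((out / "ground_truth.json").read_text())
    assert sc.GroundTruth.from_json(sidecar["ground_truth"]) == default_truth
    from stagecal.io import read_raster

    assert np.array_equal(read_raster(out / "frame_000.tif"), frames[0])
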
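"""Plumb-line calibration: extraction, LM fit, DLT, decomposition."""

import numpy as np
import pytest

import stagecal as sc
from stagecal.distortion import _tls_line
from stagecal.errors import (
    DegenerateGeometryError,
    ExtractionError,
    InvalidArgumentError,
)


def make_synthetic_lines(k, u0, v0, n_per_family=8, n_pts=60, noise=0.0,
                         rng=None, image=(900, 1200)):
    """Exact centerline points of an ideal grid pushed through the inverse
    distortion map — the ground-truth oracle for the plumb-line fit."""
    h, w = image
    intr = sc.IntrinsicParams(fx=1, fy=1, u0=u0, v0=v0, k=k)
    rng = rng or np.random.default_rng(0)
    lines = []
    for family in ("vertical", "horizontal"):
        coords = np.linspace(80, (w if family == "vertical" else h) - 80,
                             n_per_family)
        for c in coords:
            if family == "vertical":
                pts = np.column_stack(
                    [np.full(n_pts, c), np.linspace(10, h - 10, n_pts)]
                )
            else:
                pts = np.column_stack(
                    [np.linspace(10, w - 10, n_pts), np.full(n_pts, c)]
                )
            obs = sc.distort_point(pts, intr)
            if noise:
                obs = obs + rng.normal(0, noise, obs.shape)
            lines.append(sc.CenterLine(points=obs, orientation=family))
    return sc.CenterLineSet(
        vertical=[l for l in lines if l.orientation == "vertical"],
        horizontal=[l for l in lines if l.orientation == "horizontal"],
        image_shape=image,
    )


class TestExtractCenterLines:
    def test_counts_full_grid(self, default_truth):
        """A 20-square grid that fits the raster yields 21 + 21 centerlines."""
        spec = sc.GridSpec(image_w=1150, image_h=1150)
        lines = sc.extract_center_lines(
            sc.render_grid_image(default_truth, spec)
        )
        assert len(lines.vertical) == 21
        assert len(lines.horizontal) == 21

    def test_blank_raster_is_an_extraction_error(self):
        with pytest.raises(ExtractionError):
            sc.extract_center_lines(np.full((200, 300), 200, dtype=np.uint8))

    def test_tilt_recovery(self):
        truth = sc.GroundTruth(theta_true_deg=-5.5, k_true=0.0,
                               noise_sigma=0.0)
        lines = sc.extract_center_lines(
            sc.render_grid_image(truth, sc.GridSpec())
        )
        assert abs(lines.tilt_deg("vertical") - (-5.5)) < 0.05


class TestStraightnessResiduals:
    def test_zero_for_exact_line_with_zero_distortion(self):
        pts = np.column_stack([np.full(20, 100.0), np.linspace(0, 99, 20)])
        ln = sc.CenterLine(points=pts, orientation="vertical")
        ln.fit_line()
        r = sc.straightness_residuals(
            (0.0, 600.0, 450.0, [ln.alpha], [ln.phi]), [ln]
        )
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_forward_model_consistency(self):
        """Points distorted with k_true evaluate to ~zero objective at the
        true parameters."""
        lines = make_synthetic_lines(5e-8, 600, 450)
        alphas = [l.alpha for l in lines.lines]
        phis = [l.phi for l in lines.lines]
        # (alpha, phi) of the undistorted lines:
        for i, l in enumerate(lines.lines):
            und = sc.undistort_point(
                l.points, sc.IntrinsicParams(1, 1, 600, 450, 5e-8)
            )
            alphas[i], phis[i] = _tls_line(und)
        r = sc.straightness_residuals((5e-8, 600.0, 450.0, alphas, phis),
                                      lines)
        assert float(np.sum(r**2)) < 1e-12


class TestFitDistortion:
    def test_recovers_k_on_exact_points(self):
        fit = sc.fit_distortion(make_synthetic_lines(5e-8, 600, 450))
        assert abs(fit.intr.k - 5e-8) / 5e-8 < 0.01
        assert abs(fit.intr.u0 - 600) < 2
        assert abs(fit.intr.v0 - 450) < 2
        assert fit.converged

    def test_zero_distortion_recovered_exactly(self):
        fit = sc.fit_distortion(make_synthetic_lines(0.0, 600, 450))
        assert abs(fit.intr.k) < 1e-12

    def test_single_family_is_degenerate(self):
        lines = make_synthetic_lines(1e-8, 600, 450)
        only_v = sc.CenterLineSet(vertical=lines.vertical, horizontal=[],
                                  image_shape=lines.image_shape)
        with pytest.raises(DegenerateGeometryError):
            sc.fit_distortion(only_v)

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_noisy_centers_still_recover_k(self, seed):
        lines = make_synthetic_lines(
            5e-8, 600, 450, noise=0.1, rng=np.random.default_rng(seed)
        )
        fit = sc.fit_distortion(lines)
        assert abs(fit.intr.k - 5e-8) / 5e-8 < 0.10


class TestEstimateHomography:
    @staticmethod
    def correspondences_from(H, rng, n_pts=6, n_lines=5):
        Ht = sc.Homography(H)
        P = rng.uniform(-50, 50, (n_pts, 2))
        p = Ht.apply(P)
        wl, il = [], []
        for _ in range(n_lines):
            q1, q2 = rng.uniform(-50, 50, (2, 2))
            wl.append(np.cross([*q1, 1.0], [*q2, 1.0]))
            il.append(np.cross([*Ht.apply(q1[None])[0], 1.0],
                               [*Ht.apply(q2[None])[0], 1.0]))
        return Ht, sc.Correspondences(P, p, np.array(wl), np.array(il))

    def test_identity_recovery(self):
        _, c = self.correspondences_from(np.eye(3),
                                         np.random.default_rng(3))
        H = sc.estimate_homography(c)
        assert np.abs(H.H - sc.Homography(np.eye(3)).H).max() < 1e-12

    def test_exact_recovery_of_random_homography(self):
        rng = np.random.default_rng(42)
        Hm = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        Hm[2, 2] = 1.0
        Ht, c = self.correspondences_from(Hm, rng)
        H = sc.estimate_homography(c)
        assert np.abs(H.H - Ht.H).max() < 1e-9

    def test_scale_invariance_of_correspondences(self):
        rng = np.random.default_rng(5)
        Hm = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        Hm[2, 2] = 1.0
        _, c = self.correspondences_from(Hm, rng)
        H1 = sc.estimate_homography(c)
        c2 = sc.Correspondences(c.world_points, c.image_points,
                                c.world_lines * 3.7, c.image_lines * -0.2)
        H2 = sc.estimate_homography(c2)
        assert np.abs(H1.H - H2.H).max() < 1e-9

    def test_collinear_points_degenerate(self):
        P = np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]])
        with pytest.raises((DegenerateGeometryError, InvalidArgumentError)):
            sc.estimate_homography(
                sc.Correspondences(P, P, np.empty((0, 3)), np.empty((0, 3)))
            )


class TestDecomposeImaging:
    def test_unit_focal_magnification(self):
        A = np.array([[1.0, 0, 600], [0, 1.0, 450], [0, 0, 1]])
        Hm = A @ np.column_stack([[1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        _, mag, _ = sc.decompose_imaging(
            sc.Homography(Hm), sc.IntrinsicParams(1, 1, 600, 450), 20, 20, 20,
            estimate_focal=False,
        )
        assert np.isclose(mag.M, 20.0)

    def test_magnification_ratio_of_worked_example(self):
        mag = sc.MagnificationResult.from_focal(
            fx=19.843 / 20, fy=19.843 / 20, Lu=20, Lv=20, M_nominal=20
        )
        assert np.isclose(mag.M, 19.843)
        assert abs(mag.M_prime - 0.9922) <= 5e-5 + 1e-12

    def test_known_pose_round_trip(self):
        A = np.array([[1.0, 0, 600], [0, 1.0, 450], [0, 0, 1]])
        t = np.array([-2.5, -2.7, 0.2])
        Hm = A @ np.column_stack([[1, 0, 0], [0, 1, 0], t])
        pose, _, _ = sc.decompose_imaging(
            sc.Homography(Hm), sc.IntrinsicParams(1, 1, 600, 450), 20, 20, 20,
            estimate_focal=False,
        )
        assert np.abs(pose.t - t).max() < 1e-9

    def test_in_plane_rotation_recovered(self):
        th = np.radians(-5.578)
        c, s = np.cos(th), np.sin(th)
        A = np.array([[1.0, 0, 600], [0, 1.0, 450], [0, 0, 1]])
        cols = 0.99215 * np.array([[c, -s], [s, c], [0, 0]])
        Hm = A @ np.column_stack([cols[:, 0], cols[:, 1], [1.0, 2.0, 1.0]])
        pose, mag, _ = sc.decompose_imaging(
            sc.Homography(Hm), sc.IntrinsicParams(1, 1, 600, 450), 20, 20, 20
        )
        assert np.isclose(mag.M_prime, 0.99215, atol=1e-9)
        ang = np.degrees(np.arctan2(pose.R[1, 0], pose.R[0, 0]))
        assert np.isclose(ang, -5.578, atol=1e-9)


def test_end_to_end_recovery_noise_free():
    """render -> extract -> fit -> homography -> decompose recovers the
    generative (k, M') within 2 percent."""
    truth = sc.GroundTruth(noise_sigma=0.0, seed=4)
    cal = sc.DistortionCalibrator().fit(
        sc.render_grid_image(truth, sc.GridSpec())
    )
    assert abs(cal.k_ - truth.k_true) / truth.k_true < 0.02
    assert abs(cal.M_prime_ - truth.M_true / truth.M_nominal) < 0.02 * 0.992
    assert abs(cal.u0_ - truth.u0) < 2 and abs(cal.v0_ - truth.v0) < 2
    # transform undistorts with the fitted intrinsics
    pt = cal.transform([[900.0, 700.0]])[0]
    expected = sc.undistort_point((900.0, 700.0), cal.intr_)
    assert np.allclose(pt, expected)


def test_objective_never_increases_across_fit():
    """The reported optimum is no worse than the TLS initialization."""
    lines = make_synthetic_lines(5e-8, 600, 450, noise=0.05)
    for ln in lines.lines:
        ln.fit_line()
    init_res = sc.straightness_residuals(
        (0.0, 600.0, 450.0,
         [l.alpha for l in lines.lines], [l.phi for l in lines.lines]),
        lines,
    )
    fit = sc.fit_distortion(lines)
    assert fit.objective_value <= float(np.sum(init_res**2)) + 1e-12
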
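import numpy as np
import pytest

import stagecal as sc


@pytest.fixture(scope="session")
def default_truth():
    """The worked-example rig: M'~0.992, theta -5.578 deg, k 5e-8,
    per-axis errors ~-0.9%, image noise sigma 2."""
    return sc.GroundTruth(seed=1)


@pytest.fixture(scope="session")
def noise_free_truth():
    return sc.GroundTruth(seed=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def grid_image(default_truth):
    return sc.render_grid_image(default_truth, sc.GridSpec())


@pytest.fixture(scope="session")
def calibration(default_truth):
    """Full synthetic calibration shared by the closed-loop tests."""
    return sc.calibrate_synthetic(default_truth)


@pytest.fixture(scope="session")
def truth_model(default_truth):
    """Compensation model built directly from the generative truth."""
    return sc.CompensationModel(
        M_prime=default_truth.M_true / default_truth.M_nominal,
        delta=(0.0, 0.0),
        theta_deg=default_truth.theta_true_deg,
        axis=default_truth.axis_errors(),
        intr=default_truth.intr,
        M_nominal=default_truth.M_nominal,
        pixel_pitch_um=default_truth.pixel_pitch_um,
    )


@pytest.fixture(scope="session")
def speckle_image():
    """A grid-free textured raster for pure registration tests."""
    rng = np.random.default_rng(11)
    img = np.full((300, 400), 200.0)
    for _ in range(120):
        u, v = rng.uniform(15, 385), rng.uniform(15, 285)
        sig = rng.uniform(1.5, 3.5)
        depth = rng.uniform(40, 120)
        r = int(np.ceil(4 * sig))
        uu = np.arange(int(u) - r, int(u) + r + 1)
        vv = np.arange(int(v) - r, int(v) + r + 1)
        ok_u = (uu >= 0) & (uu < 400)
        ok_v = (vv >= 0) & (vv < 300)
        g = np.exp(-0.5 * (((vv[ok_v, None] - v) ** 2 +
                            (uu[None, ok_u] - u) ** 2) / sig**2))
        img[np.ix_(vv[ok_v], uu[ok_u])] -= depth * g
    return np.clip(img, 0, 255)
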
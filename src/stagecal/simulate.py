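"""Synthetic ground-truth generator for calibration-grid imagery.

Renders a square calibration grid (dark lines on a bright background, the
"standard ruler" of a stage-micrometer scale) as seen through the forward
imaging model: world grid -> stage offset -> mounting rotation theta ->
magnification -> second-order radial distortion -> additive Gaussian noise ->
8-bit quantization.  Also simulates stepped displacement series with injected
per-axis mechanical errors, so every estimator in the package has a recovery
test against known truth.

Rendering is anti-aliased by construction: grid lines carry a Gaussian
cross-section, so intensity-weighted centroids of scanline profiles recover
line centers to well below 0.01 px on noise-free images.  Intensities follow
a brightfield convention: background 200, line cores 50, noise clipped to
[0, 255], 8-bit output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .model import IntrinsicParams, undistort_point

__all__ = [
    "GroundTruth",
    "GridSpec",
    "DisplacementPlan",
    "render_grid_image",
    "simulate_series",
    "forward_stage_model",
    "write_series",
]

BACKGROUND = 200.0
LINE_LEVEL = 50.0


@dataclass
class GridSpec:
    """Geometry of the rendered calibration grid.

    ``n_squares`` squares of side ``pitch_um`` per side; the raster is
    ``image_w`` x ``image_h`` pixels.  ``line_width_px`` is the rendered line
    thickness (the Gaussian cross-section sigma is half of it).  With
    ``periodic=True`` the line lattice extends over the whole plane, which is
    what displacement series need (a bounded 20x20 scale would leave the
    field of view after a few 600 µm steps).
    """

    n_squares: int = 20
    pitch_um: float = 50.0
    image_w: int = 1200
    image_h: int = 900
    line_width_px: float = 3.0
    periodic: bool = False

    def __post_init__(self):
        if self.n_squares < 2:
            raise InvalidArgumentError("n_squares must be >= 2")
        if self.pitch_um <= 0 or self.line_width_px <= 0:
            raise InvalidArgumentError("pitch_um and line_width_px must be positive")

    @property
    def half_extent_um(self) -> float:
        return self.n_squares * self.pitch_um / 2.0


@dataclass
class DisplacementPlan:
    """A stepped single-axis move: ``n_steps`` steps of ``step_um`` along
    +/-X or +/-Y (axis in {"x","y"}, direction in {+1,-1}).

    ``start_um`` offsets the whole series; stepping experiments are run on a
    blank substrate region beside the engraved scale, because a step that is
    a whole number of grid pitches (600 µm = 12 x 50 µm) makes the grid
    self-similar under the nominal offset and biases the measured error
    toward zero.
    """

    axis: str = "x"
    direction: int = 1
    n_steps: int = 10
    step_um: float = 600.0
    start_um: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.axis not in ("x", "y"):
            raise InvalidArgumentError("axis must be 'x' or 'y'")
        if self.direction not in (1, -1):
            raise InvalidArgumentError("direction must be +1 or -1")
        if self.n_steps < 1 or self.step_um <= 0:
            raise InvalidArgumentError("n_steps >= 1 and step_um > 0 required")

    def commanded_positions(self) -> np.ndarray:
        """Commanded stage positions (n_steps+1, 2) in µm."""
        steps = np.zeros((self.n_steps + 1, 2))
        i = 0 if self.axis == "x" else 1
        steps[:, i] = self.direction * self.step_um * np.arange(self.n_steps + 1)
        return steps + np.asarray(self.start_um, dtype=float)


# Defaults mirror the calibrated rig of the worked example: 20x objective
# with actual magnification 19.843 on a 20 µm pixel pitch (~0.992 px/µm),
# mounting deflection -5.578 deg, and per-axis relative displacement errors
# of -0.87%..-0.97% (the per-600-px mean offsets of a stepping experiment).
@dataclass
class GroundTruth:
    """Generative parameters for the synthetic rig.

    Besides the engraved grid, the substrate carries a fixed field of
    pseudo-random speckle marks (dust, engraving defects) outside the grid
    square — without them a translated view of a purely periodic target is
    indistinguishable from a lattice-shifted one and stitching would be
    ill-posed, on the synthetic rig as on a real one.
    """

    M_true: float = 19.843
    M_nominal: float = 20.0
    pixel_pitch_um: float = 20.0  # Lu = Lv, sensor pixel side in µm
    theta_true_deg: float = -5.578
    k_true: float = 5e-8  # px^-2
    u0: float = 600.0
    v0: float = 450.0
    dxp: float = -0.0087
    dxm: float = -0.0097
    dyp: float = -0.0095
    dym: float = -0.0087
    noise_sigma: float = 2.0
    seed: int = 0
    speckle_n: int = 120000
    speckle_extent_um: float = 10000.0  # half-extent of the speckle field

    def __post_init__(self):
        vals = [self.M_true, self.M_nominal, self.pixel_pitch_um,
                self.theta_true_deg, self.k_true, self.u0, self.v0,
                self.dxp, self.dxm, self.dyp, self.dym, self.noise_sigma]
        if not np.all(np.isfinite(vals)):
            raise InvalidArgumentError("ground-truth parameters must be finite")

    @property
    def px_per_um(self) -> float:
        """Image pixels per µm of stage travel (= M / pixel pitch)."""
        return self.M_true / self.pixel_pitch_um

    @property
    def intr(self) -> IntrinsicParams:
        f = self.px_per_um
        return IntrinsicParams(fx=f, fy=f, u0=self.u0, v0=self.v0, k=self.k_true)

    def axis_errors(self):
        from .model import AxisErrors

        return AxisErrors(dxp=self.dxp, dxm=self.dxm, dyp=self.dyp, dym=self.dym)

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        return cls(**d)


def _speckle_field(truth: GroundTruth) -> np.ndarray:
    """World positions, core sigmas (px) and depths of the speckle marks.

    Drawn once per ground truth from a dedicated stream of the seed, so the
    marks are anchored to the specimen, not to frames.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(truth.seed) & 0x7FFFFFFF, 0x5BEC])
    )
    e = truth.speckle_extent_um
    pos = rng.uniform(-e, e, size=(truth.speckle_n, 2))
    sigma_px = rng.uniform(1.5, 4.0, size=truth.speckle_n)
    depth = rng.uniform(40.0, 110.0, size=truth.speckle_n)
    return pos, sigma_px, depth


def _grid_distance_um(w: np.ndarray, pitch: float, half_extent: float,
                      periodic: bool) -> np.ndarray:
    """Distance (µm) from world coordinates to the nearest grid line of one
    family, +inf outside the grid extent for bounded grids."""
    d = np.abs((w + pitch / 2.0) % pitch - pitch / 2.0)
    if not periodic:
        d = np.where(np.abs(w) <= half_extent + 1e-9, d, np.inf)
    return d


def render_grid_image(truth: GroundTruth, spec: GridSpec,
                      stage_pos=(0.0, 0.0), noise_key: int = 0) -> np.ndarray:
    """Render one 8-bit frame of the grid at a given stage position.

    For every observed pixel the theoretical (distortion-free) position is
    obtained in closed form from the radial model, mapped back through the
    rotation/magnification to world µm, and shaded by the distance to the
    nearest grid line.  Deterministic for a fixed ``(truth.seed, noise_key)``.
    """
    m = truth.px_per_um
    if m <= 0:
        raise ConfigurationError("non-positive pixel scale")
    sx, sy = float(stage_pos[0]), float(stage_pos[1])

    v, u = np.mgrid[0 : spec.image_h, 0 : spec.image_w].astype(float)
    # observed -> theoretical (closed form, this IS the distortion model)
    du, dv = u - truth.u0, v - truth.v0
    r2 = du * du + dv * dv
    ut = u + truth.k_true * du * r2
    vt = v + truth.k_true * dv * r2
    # theoretical pixel -> world µm (undo rotation, magnification, stage)
    th = np.radians(truth.theta_true_deg)
    c, s = np.cos(th), np.sin(th)
    xr = (ut - truth.u0) / m
    yr = (vt - truth.v0) / m
    X = c * xr + s * yr - sx
    Y = -s * xr + c * yr - sy

    grid_visible = True
    if not spec.periodic:
        he = spec.half_extent_um
        inside = (np.abs(X) <= he + spec.pitch_um) & (np.abs(Y) <= he + spec.pitch_um)
        grid_visible = bool(inside.any())
    sigma_um = (spec.line_width_px / 2.0) / m
    dX = _grid_distance_um(X, spec.pitch_um, spec.half_extent_um, spec.periodic)
    dY = _grid_distance_um(Y, spec.pitch_um, spec.half_extent_um, spec.periodic)
    # a point on a vertical line must still lie within the grid's Y extent
    if not spec.periodic:
        he = spec.half_extent_um
        dX = np.where(np.abs(Y) <= he + 1e-9, dX, np.inf)
        dY = np.where(np.abs(X) <= he + 1e-9, dY, np.inf)
    with np.errstate(over="ignore"):
        cover = np.maximum(
            np.exp(-0.5 * (dX / sigma_um) ** 2), np.exp(-0.5 * (dY / sigma_um) ** 2)
        )
    img = BACKGROUND - (BACKGROUND - LINE_LEVEL) * cover
    n_dots = 0
    if truth.speckle_n > 0 and not spec.periodic:
        n_dots = _stamp_speckle(img, truth, spec, (sx, sy))
    if not grid_visible and n_dots == 0:
        raise ConfigurationError(
            "nothing to image: grid and speckle field entirely outside the "
            "raster at this stage position"
        )
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(truth.seed) & 0x7FFFFFFF, int(noise_key)])
        )
        img = img + rng.normal(0.0, truth.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _stamp_speckle(img: np.ndarray, truth: GroundTruth, spec: GridSpec,
                   stage_pos) -> int:
    """Add the in-view speckle marks to a rendered frame.

    Marks inside the grid square (plus one pitch of margin) are skipped —
    the engraved scale center is clean.  Each mark is projected through the
    full forward model (rotation, magnification, radial distortion) so its
    subpixel observed position is exactly consistent with the grid.
    """
    from .model import distort_point

    m = truth.px_per_um
    th = np.radians(truth.theta_true_deg)
    c, s = np.cos(th), np.sin(th)
    sx, sy = stage_pos
    pos, sigma_px, depth = _speckle_field(truth)
    he = spec.half_extent_um + spec.pitch_um
    outside = np.maximum(np.abs(pos[:, 0]), np.abs(pos[:, 1])) > he
    # coarse in-view preselection in theoretical pixel coords
    xr = pos[:, 0] + sx
    yr = pos[:, 1] + sy
    ut = truth.u0 + m * (c * xr - s * yr)
    vt = truth.v0 + m * (s * xr + c * yr)
    h, w = img.shape
    margin = 60.0
    keep = outside & (ut > -margin) & (ut < w + margin) & \
        (vt > -margin) & (vt < h + margin)
    idx = np.flatnonzero(keep)
    intr = truth.intr
    n = 0
    for i in idx:
        u_obs, v_obs = distort_point((ut[i], vt[i]), intr)
        sig = sigma_px[i]
        r = int(np.ceil(4 * sig))
        u0i, v0i = int(np.floor(u_obs)), int(np.floor(v_obs))
        lo_u, hi_u = max(u0i - r, 0), min(u0i + r + 1, w)
        lo_v, hi_v = max(v0i - r, 0), min(v0i + r + 1, h)
        if lo_u >= hi_u or lo_v >= hi_v:
            continue
        uu = np.arange(lo_u, hi_u, dtype=float) - u_obs
        vv = np.arange(lo_v, hi_v, dtype=float) - v_obs
        g = np.exp(-0.5 * ((vv[:, None] ** 2 + uu[None, :] ** 2) / sig**2))
        img[lo_v:hi_v, lo_u:hi_u] -= depth[i] * g
        n += 1
    np.clip(img, 0.0, None, out=img)
    return n


def forward_stage_model(truth: GroundTruth, command) -> np.ndarray:
    """Actual stage displacement (µm) achieved for a commanded one.

    Each component is scaled by ``(1 + delta)`` with the sign-appropriate
    relative error chosen by the command's direction.  The deflection angle
    only enters when projecting displacements to pixels, not here.
    """
    cmd = np.asarray(command, dtype=float)
    if not np.all(np.isfinite(cmd)):
        raise InvalidArgumentError("command must be finite")
    dx, dy = truth.axis_errors().select(cmd[0], cmd[1])
    return np.array([cmd[0] * (1.0 + dx), cmd[1] * (1.0 + dy)])


def simulate_series(truth: GroundTruth, spec: GridSpec, plan: DisplacementPlan):
    """Render an ordered displacement series.

    Frame ``i`` is rendered at the *actual* stage position reached after the
    commanded steps, each corrupted by the direction-appropriate relative
    error.  Returns ``(frames, commanded_positions)``.
    """
    commanded = plan.commanded_positions()
    frames = []
    pos = commanded[0].copy()  # the starting placement is taken as exact
    for i in range(len(commanded)):
        if i > 0:
            step = commanded[i] - commanded[i - 1]
            pos = pos + forward_stage_model(truth, step)
        frames.append(render_grid_image(truth, spec, stage_pos=pos, noise_key=i))
    return frames, commanded


def write_series(frames, commanded, truth: GroundTruth, out_dir,
                 fmt: str = "tiff") -> Path:
    """Write a rendered series plus a ground-truth sidecar JSON."""
    from .io import write_raster

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        write_raster(out / f"frame_{i:03d}.{ 'tif' if fmt=='tiff' else 'png'}", frame)
    sidecar = {
        "ground_truth": truth.to_json(),
        "commanded_positions_um": np.asarray(commanded).tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return out
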
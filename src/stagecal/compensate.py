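"""Assembly and application of the combined error-compensation model.

The model carries the five calibrated coefficients — magnification ratio
``M'``, distortion compensation offsets ``(delta_x, delta_y)``, deflection
angle ``theta``, and the per-axis displacement errors — and converts a
desired displacement (µm, measured on the image at nominal magnification)
into the stage command that actually realizes it.

Two evaluation modes:

``coherent`` (default)
    the invertible reading: the desired displacement is scaled by ``1/M'``,
    rotated by ``-theta`` into stage axes, and each component divided by
    ``(1 + delta)`` with the error pair selected by the post-rotation motion
    quadrant.  With a model equal to the ground truth this inverts the
    forward stage model exactly.  The distortion offsets ``delta`` are a
    constant recentering term meaningful only for absolute positioning and
    are applied once per absolute move when ``apply_delta`` is set, never
    per step.

``paper_literal``
    evaluates the printed closed-form update
    ``X1 = X0 + M' * delta_x * mu * s * cos(theta)`` (and the sine analog
    for Y) with the scalar quadrant gain — retained verbatim for audit; it
    is not invertible and is not used by the closed-loop trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidArgumentError, SchemaError
from .mech import mu as mech_mu
from .model import (
    AxisErrors,
    DeflectionParams,
    ExtrinsicPose,
    IntrinsicParams,
    compose_error_transform,
    undistort_point,
)
from .registration import estimate_offset
from .simulate import GridSpec, GroundTruth, forward_stage_model, render_grid_image

__all__ = [
    "CompensationModel",
    "TrialReport",
    "build_compensation_model",
    "compensate_move",
    "single_shot_trial",
    "cumulative_trial",
    "StageCompensator",
]

SCHEMA_VERSION = "1"
_REQUIRED_CALIB = ("M_prime", "delta_x", "delta_y", "k", "u0", "v0", "fx", "fy")


@dataclass
class CompensationModel:
    """The five compensation coefficients plus the intrinsics they rely on."""

    M_prime: float
    delta: tuple
    theta_deg: float
    axis: AxisErrors
    mode: str = "coherent"
    intr: IntrinsicParams | None = None
    M_nominal: float = 20.0
    pixel_pitch_um: float = 20.0

    def __post_init__(self):
        if self.mode not in ("coherent", "paper_literal"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        vals = [self.M_prime, self.delta[0], self.delta[1], self.theta_deg]
        if not np.all(np.isfinite(vals)):
            raise InvalidArgumentError("model coefficients must be finite")

    @property
    def px_per_um_nominal(self) -> float:
        return self.M_nominal / self.pixel_pitch_um

    @property
    def px_per_um(self) -> float:
        """Calibrated pixel scale (px/µm)."""
        return self.M_prime * self.px_per_um_nominal

    def error_transform(self, beta_deg: float = 0.0):
        pose = ExtrinsicPose.identity()
        pose.t_hat = np.array([self.delta[0], self.delta[1], 0.0])
        return compose_error_transform(
            self.M_prime, DeflectionParams(self.theta_deg), self.axis, pose,
            beta_deg=beta_deg,
        )

    def to_json(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "M_prime": self.M_prime,
            "delta_x": self.delta[0],
            "delta_y": self.delta[1],
            "theta_deg": self.theta_deg,
            "axis_errors": {k: getattr(self.axis, k)
                            for k in ("dxp", "dxm", "dyp", "dym")},
            "mode": self.mode,
            "M_nominal": self.M_nominal,
            "pixel_pitch_um": self.pixel_pitch_um,
        }
        if self.intr is not None:
            d["intrinsics"] = {"fx": self.intr.fx, "fy": self.intr.fy,
                               "u0": self.intr.u0, "v0": self.intr.v0,
                               "k": self.intr.k}
        return d

    @classmethod
    def from_json(cls, d: dict) -> "CompensationModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"unknown schema_version {d.get('schema_version')!r}"
            )
        for key in ("M_prime", "delta_x", "delta_y", "theta_deg", "axis_errors"):
            if key not in d:
                raise SchemaError(f"missing field {key!r}")
        intr = None
        if "intrinsics" in d:
            intr = IntrinsicParams(**d["intrinsics"])
        return cls(
            M_prime=d["M_prime"],
            delta=(d["delta_x"], d["delta_y"]),
            theta_deg=d["theta_deg"],
            axis=AxisErrors(**d["axis_errors"]),
            mode=d.get("mode", "coherent"),
            intr=intr,
            M_nominal=d.get("M_nominal", 20.0),
            pixel_pitch_um=d.get("pixel_pitch_um", 20.0),
        )


@dataclass
class TrialReport:
    """Outcome of one closed-loop evaluation."""

    residual_x: float
    residual_y: float
    compensated: bool
    meta: dict = field(default_factory=dict)

    @property
    def residual_norm(self) -> float:
        return float(np.hypot(self.residual_x, self.residual_y))


def build_compensation_model(calib: dict, theta_deg: float, axis: AxisErrors,
                             mode: str = "coherent", M_nominal: float = 20.0,
                             pixel_pitch_um: float = 20.0) -> CompensationModel:
    """Assemble a model from a distortion-calibration JSON block plus the
    deflection and axis-error estimates."""
    for key in _REQUIRED_CALIB:
        if key not in calib:
            raise SchemaError(f"calibration block missing field {key!r}")
    intr = IntrinsicParams(fx=calib["fx"], fy=calib["fy"], u0=calib["u0"],
                           v0=calib["v0"], k=calib["k"])
    return CompensationModel(
        M_prime=calib["M_prime"],
        delta=(calib["delta_x"], calib["delta_y"]),
        theta_deg=theta_deg,
        axis=axis,
        mode=mode,
        intr=intr,
        M_nominal=M_nominal,
        pixel_pitch_um=pixel_pitch_um,
    )


def compensate_move(model: CompensationModel, desired, apply_delta: bool = False):
    """Convert a desired displacement (µm) into a corrected stage command.

    Returns ``(command, predicted)`` where ``predicted`` is the displacement
    the model expects the commanded move to achieve (equal to ``desired`` in
    coherent mode by construction).
    """
    d = np.asarray(desired, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InvalidArgumentError("desired displacement must be finite")
    if model.mode == "paper_literal":
        s = float(np.hypot(d[0], d[1]))
        if s == 0:
            return np.zeros(2), np.zeros(2)
        beta = float(np.degrees(np.arctan2(d[1], d[0]))) % 360.0
        g = mech_mu(beta, model.axis, mode="scalar")
        th = np.radians(model.theta_deg)
        cmd = d + model.M_prime * np.array(model.delta) * g * s * np.array(
            [np.cos(th), np.sin(th)]
        )
        return cmd, d
    # coherent mode
    if apply_delta:
        d = d + np.asarray(model.delta, dtype=float)
    th = np.radians(model.theta_deg)
    c, s = np.cos(th), np.sin(th)
    stage = np.array([c * d[0] + s * d[1], -s * d[0] + c * d[1]]) / model.M_prime
    dx, dy = model.axis.select(stage[0], stage[1])
    if abs(1.0 + dx) < 0.5 or abs(1.0 + dy) < 0.5:
        raise InvalidArgumentError("implausible calibration: |1 + delta| < 0.5")
    cmd = np.array([stage[0] / (1.0 + dx), stage[1] / (1.0 + dy)])
    return cmd, d.copy()


def _project_to_image_um(truth: GroundTruth, stage_disp) -> np.ndarray:
    """Displacement as measured on the image (µm at nominal magnification)."""
    th = np.radians(truth.theta_true_deg)
    c, s = np.cos(th), np.sin(th)
    v = np.asarray(stage_disp, dtype=float)
    rotated = np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])
    return rotated * (truth.M_true / truth.M_nominal)


def single_shot_trial(model: CompensationModel, truth: GroundTruth,
                      target_px, seed: int = 0,
                      compensated: bool = True) -> TrialReport:
    """One single-shot positioning test on the synthetic rig.

    A target pixel is converted to a desired displacement that should bring
    it to the image center (undistort, scale, negate), the (optionally
    compensated) command is pushed through the forward stage model, and the
    residual between the target's physical position and the realized travel
    is reported in µm.
    """
    p = np.asarray(target_px, dtype=float)
    c0 = np.array([truth.u0, truth.v0])

    # --- what the operator computes from the image, using the calibration
    if compensated and model.intr is not None:
        p_theo = undistort_point(p, model.intr)
    else:
        p_theo = p
    offset_px = p_theo - c0
    desired = -offset_px / model.px_per_um_nominal  # µm at nominal scale
    if compensated:
        command, _ = compensate_move(model, desired)
    else:
        command = desired

    # --- ground truth: where the target really is, what the stage really does
    p_theo_true = undistort_point(p, truth.intr)
    target_stage = _stage_coords(truth, p_theo_true - c0)
    actual = forward_stage_model(truth, command)
    residual_stage = target_stage + actual  # perfect move: actual = -target
    residual_img = _project_to_image_um(truth, residual_stage)
    return TrialReport(residual_x=float(residual_img[0]),
                       residual_y=float(residual_img[1]),
                       compensated=compensated,
                       meta={"target_px": p.tolist(), "seed": seed,
                             "command_um": command.tolist()})


def _stage_coords(truth: GroundTruth, offset_px) -> np.ndarray:
    """Theoretical pixel offset -> physical stage-frame offset (µm)."""
    th = np.radians(truth.theta_true_deg)
    c, s = np.cos(th), np.sin(th)
    v = np.asarray(offset_px, dtype=float) / truth.px_per_um
    return np.array([c * v[0] + s * v[1], -s * v[0] + c * v[1]])


@lru_cache(maxsize=4)
def _cached_undistorter(intr_key: tuple, shape: tuple):
    from .distortion import ImageUndistorter

    fx, fy, u0, v0, k = intr_key
    return ImageUndistorter(IntrinsicParams(fx=fx, fy=fy, u0=u0, v0=v0, k=k),
                            shape)


def rectangle_plan(plan_class: int, step_um: float = 600.0) -> np.ndarray:
    """Commanded steps of the closed stepping rectangle for one class.

    Class ``k`` walks ``k`` steps of 600 µm along +X, +Y, -X, -Y in turn
    (4k + 1 frames including the start), returning to the origin.
    """
    if not 1 <= plan_class <= 5:
        raise InvalidArgumentError("plan_class must be in 1..5")
    n = plan_class
    steps = []
    for d in ([1, 0], [0, 1], [-1, 0], [0, -1]):
        steps += [np.array(d, dtype=float) * step_um] * n
    return np.asarray(steps)


def cumulative_trial(model: CompensationModel, truth: GroundTruth,
                     plan_class: int, seed: int = 0, compensated: bool = True,
                     spec: GridSpec | None = None) -> TrialReport:
    """Closed-rectangle cumulative-error test.

    The stage walks the stepping rectangle of the given class; in theory the
    first and last frames coincide, so their stitching offset measures the
    accumulated positioning error.  Residuals are reported in µm.
    """
    if spec is None:
        spec = GridSpec()
    steps = rectangle_plan(plan_class)
    truth_local = GroundTruth(**{**truth.to_json(), "seed": seed})
    pos = np.zeros(2)
    for step in steps:
        desired = step
        if compensated:
            command, _ = compensate_move(model, desired)
        else:
            command = desired
        pos = pos + forward_stage_model(truth_local, command)
    first = render_grid_image(truth_local, spec, stage_pos=(0.0, 0.0),
                              noise_key=0)
    last = render_grid_image(truth_local, spec, stage_pos=tuple(pos),
                             noise_key=len(steps))
    if model.intr is not None:
        warp = _cached_undistorter(
            (model.intr.fx, model.intr.fy, model.intr.u0, model.intr.v0,
             model.intr.k), first.shape)
        first, last = warp(first), warp(last)
    r = estimate_offset(first, last, expected=(0.0, 0.0), search_radius=20.0)
    err_um = np.array([r.dx, r.dy]) / truth_local.px_per_um
    path_um = float(np.abs(steps).sum())
    return TrialReport(residual_x=float(err_um[0]), residual_y=float(err_um[1]),
                       compensated=compensated,
                       meta={"plan_class": plan_class, "seed": seed,
                             "path_um": path_um,
                             "n_images": len(steps) + 1})


class StageCompensator(BaseEstimator, TransformerMixin):
    """sklearn-style facade: fit a compensation model, transform commands.

    ``fit(X)`` accepts a dict with keys ``calibration`` (the distortion
    calibration block), ``theta_deg`` and ``axis_errors`` (an
    :class:`AxisErrors` or its dict) — e.g. assembled from
    :class:`~stagecal.distortion.DistortionCalibrator`,
    :class:`~stagecal.registration.DeflectionEstimator` and
    :class:`~stagecal.mech.AxisErrorEstimator`.  ``transform(D)`` maps rows
    of desired displacements (N, 2) in µm to stage commands (N, 2).
    """

    def __init__(self, mode: str = "coherent", M_nominal: float = 20.0,
                 pixel_pitch_um: float = 20.0, apply_delta: bool = False):
        self.mode = mode
        self.M_nominal = M_nominal
        self.pixel_pitch_um = pixel_pitch_um
        self.apply_delta = apply_delta

    def fit(self, X, y=None):
        if not isinstance(X, dict):
            raise InvalidArgumentError("fit expects a calibration dict")
        axis = X.get("axis_errors")
        if isinstance(axis, dict):
            axis = AxisErrors(**axis)
        if axis is None:
            raise SchemaError("missing field 'axis_errors'")
        if "theta_deg" not in X:
            raise SchemaError("missing field 'theta_deg'")
        self.model_ = build_compensation_model(
            X["calibration"], X["theta_deg"], axis, mode=self.mode,
            M_nominal=self.M_nominal, pixel_pitch_um=self.pixel_pitch_um,
        )
        return self

    def transform(self, D):
        D = np.atleast_2d(np.asarray(D, dtype=float))
        out = np.empty_like(D)
        for i, d in enumerate(D):
            out[i], _ = compensate_move(self.model_, d,
                                        apply_delta=self.apply_delta)
        return out

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.model_.to_json(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "StageCompensator":
        with open(path) as fh:
            model = CompensationModel.from_json(json.load(fh))
        est = cls(mode=model.mode, M_nominal=model.M_nominal,
                  pixel_pitch_um=model.pixel_pitch_um)
        est.model_ = model
        return est
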
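"""End-to-end calibration pipeline.

Runs the stages in their natural order — centerline extraction, plumb-line
distortion optimization, homography estimation and decomposition, deflection
estimation by stitching, per-axis mechanical error estimation — and
assembles the compensation model.  Each stage logs one tagged entry.

Two entry points: :func:`calibrate_synthetic` runs the whole chain against
the synthetic rig (used by the closed-loop evaluations and the tests), and
:func:`run_pipeline` drives it from a YAML-style config of image paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compensate import CompensationModel, StageCompensator
from .distortion import DistortionCalibrator
from .errors import ConfigurationError
from .io import load_calibration_file, read_raster, save_calibration_file
from .mech import AxisErrorEstimator
from .registration import DeflectionEstimator
from .simulate import DisplacementPlan, GridSpec, GroundTruth, simulate_series

logger = logging.getLogger("stagecal")

STAGES = ("extract", "distortion", "homography", "deflection", "mechanical",
          "model")

__all__ = ["CalibrationResult", "calibrate_synthetic", "run_pipeline"]


@dataclass
class CalibrationResult:
    """All calibrated quantities plus the assembled model."""

    calibrator: DistortionCalibrator
    deflection: DeflectionEstimator
    axis: AxisErrorEstimator
    model: CompensationModel

    def sections(self) -> dict:
        c = self.calibrator
        return {
            "intrinsics": {"fx": c.fx_, "fy": c.fy_, "u0": c.u0_,
                           "v0": c.v0_, "k": c.k_},
            "magnification": {"M": c.M_, "M_prime": c.M_prime_,
                              "Lu": c.Lu, "Lv": c.Lv,
                              "M_nominal": c.M_nominal},
            "distortion_fit": {"objective_px2": c.objective_px2_,
                               "converged": bool(c.converged_),
                               "delta_x": c.delta_[0],
                               "delta_y": c.delta_[1]},
            "deflection": {"theta_deg": self.deflection.theta_deg_,
                           "pairs": self.deflection.table()},
            "axis_errors": {
                **{k: getattr(self.model.axis, k)
                   for k in ("dxp", "dxm", "dyp", "dym")},
                "raw_px": self.axis.raw_px_,
            },
        }


def _log(stage: str, msg: str):
    logger.info("[%s] %s", stage, msg)


def calibrate_synthetic(truth: GroundTruth, n_mech_steps: int = 10,
                        step_um: float = 600.0, mode: str = "coherent",
                        grid_spec: GridSpec | None = None) -> CalibrationResult:
    """Calibrate the full model from synthetic fixtures of ``truth``.

    Renders one bounded grid raster for the distortion stage, then four
    stepped series (±X, ±Y over a periodic grid) for the deflection and
    mechanical stages, exactly mirroring the physical procedure.
    """
    if grid_spec is None:
        grid_spec = GridSpec()
    from .simulate import render_grid_image

    grid_img = render_grid_image(truth, grid_spec, stage_pos=(0.0, 0.0))
    _log("extract", f"grid raster {grid_img.shape}")
    calib = DistortionCalibrator(
        pitch_um=grid_spec.pitch_um, Lu=truth.pixel_pitch_um,
        Lv=truth.pixel_pitch_um, M_nominal=truth.M_nominal,
        line_width_px=grid_spec.line_width_px,
    ).fit(grid_img)
    _log("distortion", f"k={calib.k_:.3e} u0={calib.u0_:.2f} v0={calib.v0_:.2f} "
                       f"objective={calib.objective_px2_:.3e}")
    _log("homography", f"M'={calib.M_prime_:.5f} delta={calib.delta_}")

    px = calib.M_ / truth.pixel_pitch_um  # calibrated px/µm
    px_nom = truth.M_nominal / truth.pixel_pitch_um
    # half-frame overlap: X series step half the width, Y half the height
    step_y = round(grid_spec.image_h / (2.0 * px_nom))
    steps = {"x+": step_um, "x-": step_um, "y+": step_y, "y-": step_y}
    series = {}
    # stepping series run on the blank substrate beside the scale: with a
    # step an exact multiple of the pitch, grid-rich frames would bias the
    # measured offsets toward the nominal step
    start = {"x": (0.0, 1600.0), "y": (1600.0, 0.0)}
    for label, axis, direction in (("x+", "x", 1), ("x-", "x", -1),
                                   ("y+", "y", 1), ("y-", "y", -1)):
        plan = DisplacementPlan(axis=axis, direction=direction,
                                n_steps=n_mech_steps, step_um=steps[label],
                                start_um=start[axis])
        frames, _ = simulate_series(truth, grid_spec, plan)
        series[label] = frames

    defl = DeflectionEstimator(axis="x", step_px=step_um * px,
                               intr=calib.intr_).fit(series["x+"])
    _log("deflection", f"theta={defl.theta_deg_:.4f} deg over "
                       f"{len(defl.results_)} pairs")
    mech = AxisErrorEstimator(step_um=steps, px_per_um=px,
                              theta_deg=defl.theta_deg_,
                              intr=calib.intr_).fit(series)
    _log("mechanical", f"axis errors {mech.raw_px_}")

    comp = StageCompensator(mode=mode, M_nominal=truth.M_nominal,
                            pixel_pitch_um=truth.pixel_pitch_um).fit(
        {"calibration": calib.calibration_block(),
         "theta_deg": defl.theta_deg_,
         "axis_errors": mech.axis_errors_}
    )
    _log("model", "compensation model assembled")
    return CalibrationResult(calibrator=calib, deflection=defl, axis=mech,
                             model=comp.model_)


def run_pipeline(config: dict, out_path=None) -> dict:
    """Run the calibration chain from a config of file paths.

    Config keys: ``grid_images`` (list of raster paths), ``series`` (mapping
    of "x+","x-","y+","y-" to lists of paths), ``pitch_um``, ``Lu``, ``Lv``,
    ``M_nominal``, ``step_um``, optional ``line_width_px``.  Missing series
    directions make the mechanical section incomplete and raise
    :class:`ConfigurationError`.
    """
    for key in ("grid_images", "series"):
        if key not in config:
            raise ConfigurationError(f"config missing {key!r}")
    missing = {"x+", "x-", "y+", "y-"} - set(config["series"])
    if missing:
        raise ConfigurationError(
            f"mechanical section incomplete: missing series {sorted(missing)}"
        )
    pitch = float(config.get("pitch_um", 50.0))
    Lu = float(config.get("Lu", 20.0))
    Lv = float(config.get("Lv", 20.0))
    M_nominal = float(config.get("M_nominal", 20.0))
    step_um = float(config.get("step_um", 600.0))
    lw = float(config.get("line_width_px", 3.0))

    rasters = [read_raster(p) for p in config["grid_images"]]
    _log("extract", f"{len(rasters)} grid raster(s)")
    calib = DistortionCalibrator(pitch_um=pitch, Lu=Lu, Lv=Lv,
                                 M_nominal=M_nominal,
                                 line_width_px=lw).fit(rasters)
    _log("distortion", f"k={calib.k_:.3e}")
    _log("homography", f"M'={calib.M_prime_:.5f}")
    series = {label: [read_raster(p) for p in paths]
              for label, paths in config["series"].items()}
    px = calib.M_ / Lu
    defl = DeflectionEstimator(axis="x", step_px=step_um * px,
                               intr=calib.intr_).fit(series["x+"])
    _log("deflection", f"theta={defl.theta_deg_:.4f}")
    mech = AxisErrorEstimator(step_um=step_um, px_per_um=px,
                              theta_deg=defl.theta_deg_,
                              intr=calib.intr_).fit(series)
    _log("mechanical", f"{mech.raw_px_}")
    comp = StageCompensator(M_nominal=M_nominal, pixel_pitch_um=Lu).fit(
        {"calibration": calib.calibration_block(),
         "theta_deg": defl.theta_deg_,
         "axis_errors": mech.axis_errors_}
    )
    _log("model", "compensation model assembled")
    result = CalibrationResult(calibrator=calib, deflection=defl, axis=mech,
                               model=comp.model_)
    sections = result.sections()
    sections["model"] = comp.model_.to_json()
    if out_path is not None:
        save_calibration_file(out_path, sections,
                              provenance={"config": {k: v for k, v in
                                                     config.items()
                                                     if k != "series"},
                                          "seed": config.get("seed")})
    return sections
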
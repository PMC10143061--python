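"""Mechanical displacement-error estimation and the quadrant gain.

A motorized stage systematically over- or under-travels by a small fraction
of each commanded step, with different magnitudes per axis and per direction
(lead-screw backlash is sign-dependent).  Stepping the stage n times along
one direction and registering consecutive frames gives n measured offsets;
the mean shortfall against the nominal step, divided by the step, is the
relative displacement error for that axis/direction.

For an arbitrary motion direction ``beta`` the applicable (dx, dy) error
pair is selected by the quadrant of ``beta`` (half-open: [0,90), [90,180),
[180,270), [270,360)).  Two gain conventions are exposed:

``per_axis`` (default)
    returns ``(1 + dx_sel, 1 + dy_sel)`` — the reading under which zero
    measured error implies zero correction; used by the compensation model.

``scalar``
    the literal single-coefficient form
    ``mu = (1 + dx_sel) cos(beta) + (1 + dy_sel) sin(beta)`` with magnitude
    trig factors, retained for auditing the printed arithmetic (note that at
    zero error and beta = 45 deg it evaluates to sqrt(2), not 1).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import InvalidArgumentError, RegistrationError
from .model import AxisErrors
from .registration import estimate_offset
from .simulate import DisplacementPlan

__all__ = ["axis_error_from_series", "pairwise_offset_errors", "mu",
           "AxisErrorEstimator"]


def pairwise_offset_errors(frames, plan: DisplacementPlan, px_per_um: float,
                           theta_deg: float = 0.0) -> np.ndarray:
    """Per-pair displacement errors in pixels along the motion axis.

    Each consecutive pair is registered (peak search centered on the
    commanded step), the measured offset is rotated back by the deflection
    angle, projected on the motion axis, and compared with the nominal step
    in pixels.  Negative values mean under-travel.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise InvalidArgumentError("need at least two frames")
    step_px = plan.step_um * px_per_um
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    # unit motion direction in image coords = Rot(theta) @ axis unit
    if plan.axis == "x":
        unit = np.array([c, s]) * plan.direction
    else:
        unit = np.array([-s, c]) * plan.direction
    expected = unit * step_px

    def register_all(exp, radius):
        offsets = []
        for i in range(len(frames) - 1):
            try:
                r = estimate_offset(frames[i], frames[i + 1], expected=exp,
                                    search_radius=radius)
            except RegistrationError as e:
                raise RegistrationError(f"pair {i}->{i + 1}: {e}") from e
            offsets.append((r.dx, r.dy))
        return np.asarray(offsets)

    offsets = register_all(expected, 12.0)
    if len(offsets) >= 3:
        # consensus pass: when the step is near a whole number of grid
        # periods, a grid-rich pair can lock onto the lattice alias inside
        # the wide window; re-register around the median pair offset
        med = np.median(offsets, axis=0)
        offsets = register_all(med, 3.5)
    along = offsets @ unit
    return along - step_px


def axis_error_from_series(frames, plan: DisplacementPlan, px_per_um: float,
                           theta_deg: float = 0.0):
    """Mean relative displacement error for one axis/direction series.

    Returns ``(delta_relative, mean_offset_px)`` where
    ``delta_relative = mean_offset_px / (step_um * px_per_um)``.
    """
    errors = pairwise_offset_errors(frames, plan, px_per_um, theta_deg)
    raw = float(np.mean(errors))
    return raw / (plan.step_um * px_per_um), raw


_QUADRANT = {0: ("dxp", "dyp"), 1: ("dxm", "dyp"),
             2: ("dxm", "dym"), 3: ("dxp", "dym")}


def mu(beta_deg: float, axis: AxisErrors, mode: str = "per_axis"):
    """Direction-dependent mechanical compensation gain.

    Parameters
    ----------
    beta_deg : float
        Motion direction measured from +X, in [0, 360).
    mode : {"per_axis", "scalar"}

    Returns
    -------
    (mu_x, mu_y) in per_axis mode, a scalar in scalar mode.
    """
    if not np.isfinite(beta_deg) or not (0.0 <= beta_deg < 360.0):
        raise InvalidArgumentError("beta must lie in [0, 360) degrees")
    q = int(beta_deg // 90.0)
    nx, ny = _QUADRANT[q]
    dx, dy = getattr(axis, nx), getattr(axis, ny)
    if mode == "per_axis":
        return (1.0 + dx, 1.0 + dy)
    if mode == "scalar":
        b = np.radians(beta_deg)
        return float((1.0 + dx) * abs(np.cos(b)) + (1.0 + dy) * abs(np.sin(b)))
    raise InvalidArgumentError(f"unknown mode {mode!r}")


class AxisErrorEstimator(BaseEstimator):
    """Estimate all four per-axis relative displacement errors.

    ``fit`` takes a mapping of direction labels to frame series,
    ``{"x+": frames, "x-": frames, "y+": frames, "y-": frames}`` (any subset
    with at least one entry), registered with the given pixel scale and
    deflection compensation.  ``step_um`` may be a scalar or a per-label
    mapping (X and Y series typically step half the frame width and height
    respectively, which differ on a non-square sensor).

    Attributes
    ----------
    axis_errors_ : AxisErrors
    raw_px_ : dict of mean per-step pixel offsets per direction.
    table_ : dict of per-group pixel offsets per direction (Table-3 layout).
    """

    def __init__(self, step_um=600.0, px_per_um: float = 1.0,
                 theta_deg: float = 0.0, intr=None):
        self.step_um = step_um
        self.px_per_um = px_per_um
        self.theta_deg = theta_deg
        self.intr = intr

    def fit(self, X, y=None):
        if not X:
            raise InvalidArgumentError("no series given")
        warp = None
        if self.intr is not None:
            from .distortion import ImageUndistorter

            first = next(iter(X.values()))
            warp = ImageUndistorter(self.intr, np.asarray(first[0]).shape)
        key_map = {"x+": ("x", 1, "dxp"), "x-": ("x", -1, "dxm"),
                   "y+": ("y", 1, "dyp"), "y-": ("y", -1, "dym")}
        deltas = {"dxp": 0.0, "dxm": 0.0, "dyp": 0.0, "dym": 0.0}
        self.raw_px_ = {}
        self.table_ = {}
        steps = self.step_um if isinstance(self.step_um, dict) else \
            {lab: self.step_um for lab in key_map}
        for label, frames in X.items():
            if warp is not None:
                frames = [warp(f) for f in frames]
            if label not in key_map:
                raise InvalidArgumentError(f"unknown series label {label!r}")
            ax, direction, attr = key_map[label]
            step = float(steps[label])
            plan = DisplacementPlan(axis=ax, direction=direction,
                                    n_steps=len(frames) - 1, step_um=step)
            errs = pairwise_offset_errors(frames, plan, self.px_per_um,
                                          self.theta_deg)
            raw = float(np.mean(errs))
            deltas[attr] = raw / (step * self.px_per_um)
            self.raw_px_[label] = raw
            self.table_[label] = errs.tolist()
        self.axis_errors_ = AxisErrors(**deltas, raw_px=dict(self.raw_px_),
                                       step_um=(dict(steps)
                                                if isinstance(self.step_um, dict)
                                                else self.step_um))
        return self
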
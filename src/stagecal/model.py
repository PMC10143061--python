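"""Domain types and the forward imaging / error model.

The microscope vision system is modeled as a planar projective camera with a
second-order radial distortion term, mounted with a small in-plane deflection
angle ``theta`` relative to the motorized-stage axes, above an X-Y stage whose
travel carries a signed, direction-dependent relative displacement error per
axis.  All estimators in the package recover parameters of this model.

Coordinate convention (used consistently across the package): image
coordinates are 0-based ``(u, v) = (column, row)`` with the origin at the
top-left; physical stage coordinates are expressed in the same handedness,
``+X`` rightward and ``+Y`` along the image ``v`` axis.  Angles follow
``theta = arctan(dy/dx)`` on image offsets and are stored in degrees at API
boundaries, radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, NumericalError

__all__ = [
    "IntrinsicParams",
    "ExtrinsicPose",
    "Homography",
    "MagnificationResult",
    "DeflectionParams",
    "AxisErrors",
    "ErrorTransform",
    "undistort_point",
    "distort_point",
    "compose_error_transform",
]


def _require_finite(name, *values):
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} must be finite, got {values!r}")


@dataclass
class IntrinsicParams:
    """Camera intrinsics.

    Parameters
    ----------
    fx, fy : float
        Focal scales along u and v (pixel per µm of specimen travel).
    u0, v0 : float
        Principal point (pixel); the radial distortion correction vanishes
        there.
    k : float
        Second-order radial distortion factor (pixel^-2).  The correction
        displacing an observed point to its theoretical position is
        ``k * (p - c) * r^2`` with ``r`` the distance to the principal point.
    """

    fx: float
    fy: float
    u0: float
    v0: float
    k: float = 0.0
    image_shape: tuple | None = None  # (height, width), for extrapolation flag

    def __post_init__(self):
        _require_finite("intrinsics", self.fx, self.fy, self.u0, self.v0, self.k)
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidArgumentError("fx and fy must be positive")

    @property
    def principal_point_extrapolated(self) -> bool:
        """True when (u0, v0) lies outside the declared image frame."""
        if self.image_shape is None:
            return False
        h, w = self.image_shape
        return not (0 <= self.u0 < w and 0 <= self.v0 < h)

    @property
    def A(self) -> np.ndarray:
        """Internal parameter matrix [[fx,0,u0],[0,fy,v0],[0,0,1]]."""
        return np.array(
            [[self.fx, 0.0, self.u0], [0.0, self.fy, self.v0], [0.0, 0.0, 1.0]]
        )


@dataclass
class ExtrinsicPose:
    """Rigid pose of the calibration plane: rotation ``R`` and translation.

    ``t`` is the raw translation of the plane origin (µm); ``t_hat`` is the
    pixel-pitch-corrected translation used by the compensation model.
    """

    R: np.ndarray
    t: np.ndarray
    t_hat: np.ndarray | None = None
    _ORTHO_TOL = 1e-9

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.R.shape != (3, 3) or self.t.shape != (3,):
            raise InvalidArgumentError("R must be 3x3 and t a 3-vector")
        if self.t_hat is None:
            self.t_hat = self.t.copy()
        self.t_hat = np.asarray(self.t_hat, dtype=float)
        err = np.abs(self.R.T @ self.R - np.eye(3)).max()
        if err > 1e-6:
            raise InvalidArgumentError(f"R not orthonormal (max deviation {err:.2e})")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-6:
            raise InvalidArgumentError("R must be a proper rotation (det +1)")

    @classmethod
    def identity(cls) -> "ExtrinsicPose":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class Homography:
    """3x3 projective map between the world plane and the image.

    Scale-free: normalized so the Frobenius norm is 1 and the
    largest-magnitude entry is positive.  Applied as ``p ~ H P`` on
    homogeneous points and ``L ~ H^T l`` on homogeneous lines.
    """

    H: np.ndarray

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        if H.shape != (3, 3):
            raise InvalidArgumentError("H must be 3x3")
        if not np.all(np.isfinite(H)):
            raise InvalidArgumentError("H must be finite")
        if np.linalg.matrix_rank(H) < 3:
            raise InvalidArgumentError("H must have rank 3")
        self.H = self._normalize(H)

    @staticmethod
    def _normalize(H: np.ndarray) -> np.ndarray:
        H = H / np.linalg.norm(H)
        flat = H.ravel()
        if flat[np.argmax(np.abs(flat))] < 0:
            H = -H
        return H

    def apply(self, P: np.ndarray) -> np.ndarray:
        """Map world points (N,2) to image points (N,2)."""
        P = np.asarray(P, dtype=float)
        Ph = np.column_stack([P, np.ones(len(P))])
        q = Ph @ self.H.T
        return q[:, :2] / q[:, 2:3]


@dataclass
class MagnificationResult:
    """Per-axis and mean magnification with the nominal-ratio M'.

    ``M = (Mu + Mv)/2 = (fx*Lu + fy*Lv)/2`` and ``M_prime = M / M_nominal``.
    """

    Mu: float
    Mv: float
    Lu: float
    Lv: float
    M_nominal: float
    M: float = field(init=False)
    M_prime: float = field(init=False)

    def __post_init__(self):
        _require_finite("magnification", self.Mu, self.Mv, self.Lu, self.Lv, self.M_nominal)
        if min(self.Mu, self.Mv, self.Lu, self.Lv, self.M_nominal) <= 0:
            raise InvalidArgumentError("magnification components must be positive")
        self.M = (self.Mu + self.Mv) / 2.0
        self.M_prime = self.M / self.M_nominal

    @classmethod
    def from_focal(cls, fx, fy, Lu, Lv, M_nominal) -> "MagnificationResult":
        """Build from focal scales: Mu = fx*Lu, Mv = fy*Lv."""
        return cls(Mu=fx * Lu, Mv=fy * Lv, Lu=Lu, Lv=Lv, M_nominal=M_nominal)


@dataclass
class DeflectionParams:
    """Camera-mounting deflection between image and stage axes.

    ``eps_x = -eps_y = sin(theta)`` under the small-angle rotation reading of
    the installation-error transform; both are exposed separately so a
    non-orthogonality term can be injected in tests.
    """

    theta_deg: float
    eps_x: float | None = None
    eps_y: float | None = None

    def __post_init__(self):
        _require_finite("deflection", self.theta_deg)
        if abs(self.theta_deg) >= 45.0:
            raise InvalidArgumentError("|theta| must be < 45 degrees")
        s = float(np.sin(np.radians(self.theta_deg)))
        if self.eps_x is None:
            self.eps_x = s
        if self.eps_y is None:
            self.eps_y = -s
        _require_finite("deflection eps", self.eps_x, self.eps_y)

    @classmethod
    def zero(cls) -> "DeflectionParams":
        return cls(0.0)


@dataclass
class AxisErrors:
    """Signed relative mechanical displacement errors per axis and direction.

    ``dxp/dxm/dyp/dym`` are the mean relative errors for +X, -X, +Y, -Y
    motion (dimensionless: error per unit commanded displacement).
    ``raw_px`` optionally keeps the underlying mean pixel offsets per step and
    ``step_um`` the nominal step used during estimation, for traceability.
    """

    dxp: float = 0.0
    dxm: float = 0.0
    dyp: float = 0.0
    dym: float = 0.0
    raw_px: dict | None = None
    step_um: float | None = None

    def __post_init__(self):
        _require_finite("axis errors", self.dxp, self.dxm, self.dyp, self.dym)
        for name in ("dxp", "dxm", "dyp", "dym"):
            if abs(getattr(self, name)) >= 0.1:
                raise InvalidArgumentError(
                    f"|{name}| >= 0.1: implausible for a functioning stage"
                )

    @classmethod
    def zero(cls) -> "AxisErrors":
        return cls()

    def select(self, dx_sign: float, dy_sign: float) -> tuple[float, float]:
        """Pick the (dx, dy) error pair for a motion direction.

        Quadrant convention (half-open): the +X error applies for
        ``dx_sign >= 0``, the -X error otherwise; same for Y.
        """
        return (
            self.dxp if dx_sign >= 0 else self.dxm,
            self.dyp if dy_sign >= 0 else self.dym,
        )


@dataclass
class ErrorTransform:
    """Combined 3x3 homogeneous error transform T.

    ``T = M' * [[1, eps_y, dx], [eps_x, 1, dy], [0, 0, 1]] * [R2 | t_hat]``
    where ``[R2 | t_hat]`` is the homogeneous 2-D map built from the pose.
    With M'=1, eps=0, d=0, R=I, t_hat=0 the upper-left 2x2 block is the
    identity and the offset column is zero.
    """

    T: np.ndarray

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (3, 3) or not np.all(np.isfinite(self.T)):
            raise InvalidArgumentError("T must be a finite 3x3 matrix")

    def apply(self, s: np.ndarray) -> np.ndarray:
        """Apply T to a 2-D displacement vector."""
        v = self.T @ np.array([s[0], s[1], 1.0])
        return v[:2] / v[2]


def undistort_point(p, intr: IntrinsicParams):
    """Map observed image point(s) to theoretical (distortion-free) points.

    Implements the second-order radial model: with offsets
    ``du = u - u0``, ``dv = v - v0`` and ``r^2 = du^2 + dv^2``,

        u_theo = u + k * du * r^2
        v_theo = v + k * dv * r^2

    Accepts a single (u, v) pair or an (N, 2) array.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidArgumentError("point coordinates must be finite")
    du = p[..., 0] - intr.u0
    dv = p[..., 1] - intr.v0
    r2 = du * du + dv * dv
    out = np.empty_like(p)
    out[..., 0] = p[..., 0] + intr.k * du * r2
    out[..., 1] = p[..., 1] + intr.k * dv * r2
    return out


def distort_point(p_theoretical, intr: IntrinsicParams, tol=1e-12, max_iter=50):
    """Numerically invert :func:`undistort_point` (theoretical -> observed).

    The forward map is cubic in the radial offset, so the inverse is solved
    per point by damped Newton iteration on the radius, starting from the
    theoretical point.  Converges when the squared pixel error falls below
    ``tol``; points outside the monotone radius of the distortion map
    (``|3 k r^2| >= 1``) are rejected.
    """
    p = np.asarray(p_theoretical, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidArgumentError("point coordinates must be finite")
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    c = np.array([intr.u0, intr.v0])
    k = intr.k
    out = np.empty_like(pts)
    for i, pt in enumerate(pts):
        d_target = pt - c
        rt = np.hypot(*d_target)
        if rt == 0.0 or k == 0.0:
            out[i] = pt
            continue
        # Radial problem: observed radius r satisfies r + k r^3 = rt.
        r = rt
        ok = False
        for _ in range(max_iter):
            f = r + k * r**3 - rt
            fp = 1.0 + 3.0 * k * r * r
            if abs(3.0 * k * r * r) >= 1.0 and fp <= 0:
                raise NumericalError(
                    f"point {tuple(pt)} outside the monotone radius of the "
                    f"distortion map (k={k:g})"
                )
            step = f / fp
            # damping: keep the radius positive
            while r - step <= 0:
                step *= 0.5
            r -= step
            if f * f <= tol:
                ok = True
                break
        if not ok:
            raise NumericalError(f"distort_point failed to converge for {tuple(pt)}")
        out[i] = c + d_target * (r / rt)
    return out[0] if single else out


def compose_error_transform(
    M_prime: float,
    deflection: DeflectionParams,
    axis: AxisErrors,
    pose: ExtrinsicPose,
    beta_deg: float = 0.0,
) -> ErrorTransform:
    """Assemble the combined error transform T.

    ``beta_deg`` selects which (dx, dy) pair of the direction-dependent axis
    errors occupies the offset column (quadrant convention of
    :meth:`AxisErrors.select`); the default uses the first-quadrant pair.
    """
    _require_finite("M_prime", M_prime)
    b = np.radians(beta_deg)
    dx, dy = axis.select(np.cos(b), np.sin(b))
    E = np.array(
        [
            [1.0, deflection.eps_y, dx],
            [deflection.eps_x, 1.0, dy],
            [0.0, 0.0, 1.0],
        ]
    )
    K = np.eye(3)
    K[:2, :2] = pose.R[:2, :2]
    K[:2, 2] = pose.t_hat[:2]
    T = M_prime * (E @ K)
    T[2, :] = [0.0, 0.0, 1.0]
    return ErrorTransform(T)
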
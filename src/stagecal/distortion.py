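"""Plumb-line distortion calibration and single-plane homography decomposition.

The radial distortion of the microscope optics is estimated without any
pose information, from the single constraint that images of straight grid
lines must be straight after correction.  Subpixel centerline points are
extracted from the grid raster, and the straightness objective

    F(k, u0, v0, {alpha_i, phi_i}) =
        sum_i sum_j ( u^_ij cos(alpha_i) + v^_ij sin(alpha_i) + phi_i )^2

is minimized by Levenberg-Marquardt, where ``(u^, v^)`` are the observed
points pushed through the radial correction about ``(u0, v0)`` and
``(alpha_i, phi_i)`` parameterize each line in Hessian normal form (the
printed objective omits the unit-normal constraint; the angle
parameterization imposes it, avoiding the trivial zero solution).

The metric part of the calibration then comes from a direct linear transform
on point and line correspondences between the known 50 µm grid and the
undistorted image, followed by decomposition of the homography into
magnification, in-plane rotation, and translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateGeometryError,
    ExtractionError,
    IllConditionedGeometryError,
    InvalidArgumentError,
)
from .model import (
    ExtrinsicPose,
    Homography,
    IntrinsicParams,
    MagnificationResult,
    undistort_point,
)

__all__ = [
    "CenterLine",
    "CenterLineSet",
    "DistortionFit",
    "Correspondences",
    "extract_center_lines",
    "straightness_residuals",
    "fit_distortion",
    "estimate_homography",
    "decompose_imaging",
    "grid_correspondences",
    "ImageUndistorter",
    "DistortionCalibrator",
]


@dataclass
class CenterLine:
    """One extracted grid centerline: ordered subpixel (u, v) samples plus a
    Hessian-form line fit ``u cos(alpha) + v sin(alpha) + phi = 0``."""

    points: np.ndarray  # (m_i, 2) of (u, v)
    orientation: str  # "vertical" | "horizontal"
    alpha: float = 0.0
    phi: float = 0.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise InvalidArgumentError("a centerline needs at least 3 points")
        axis = 1 if self.orientation == "vertical" else 0
        order = np.argsort(self.points[:, axis])
        self.points = self.points[order]

    @property
    def m(self) -> int:
        return len(self.points)

    def fit_line(self) -> None:
        """Total-least-squares line fit; updates (alpha, phi)."""
        self.alpha, self.phi = _tls_line(self.points)


def _tls_line(pts: np.ndarray) -> tuple[float, float]:
    """TLS Hessian-form fit: returns (alpha, phi) with alpha in (-pi/2, pi/2]."""
    c = pts.mean(axis=0)
    d = pts - c
    # normal = smallest principal direction
    _, _, Vt = np.linalg.svd(d, full_matrices=False)
    n = Vt[-1]
    alpha = float(np.arctan2(n[1], n[0]))
    if alpha <= -np.pi / 2 or alpha > np.pi / 2:
        n = -n
        alpha = float(np.arctan2(n[1], n[0]))
    phi = float(-(n @ c))
    return alpha, phi


@dataclass
class CenterLineSet:
    """Extracted centerlines grouped into the two grid families."""

    vertical: list
    horizontal: list
    image_shape: tuple | None = None

    @property
    def lines(self) -> list:
        return list(self.vertical) + list(self.horizontal)

    @property
    def n_lines(self) -> int:
        return len(self.vertical) + len(self.horizontal)

    def tilt_deg(self, family: str = "vertical") -> float:
        """Mean tilt of one family away from its nominal axis (degrees).

        For the vertical family this equals the in-plane rotation of the grid
        in image coordinates; the horizontal family is referenced to
        alpha = 90 deg.
        """
        lines = self.vertical if family == "vertical" else self.horizontal
        if not lines:
            raise InvalidArgumentError(f"no {family} lines")
        tilts = []
        for ln in lines:
            a = np.degrees(ln.alpha)
            if family == "horizontal":
                a = a - 90.0 if a > 0 else a + 90.0
            tilts.append(a)
        return float(np.mean(tilts))


@dataclass
class DistortionFit:
    """Result of the plumb-line optimization."""

    intr: IntrinsicParams
    lines: CenterLineSet
    objective_value: float
    converged: bool
    n_iterations: int
    message: str = ""


@dataclass
class Correspondences:
    """Point and line pairs between the world plane (µm) and the undistorted
    image (px), in inhomogeneous points and homogeneous lines."""

    world_points: np.ndarray  # (Np, 2)
    image_points: np.ndarray  # (Np, 2)
    world_lines: np.ndarray  # (Nl, 3)
    image_lines: np.ndarray  # (Nl, 3)

    def __post_init__(self):
        self.world_points = np.asarray(self.world_points, dtype=float)
        self.image_points = np.asarray(self.image_points, dtype=float)
        self.world_lines = np.asarray(self.world_lines, dtype=float)
        self.image_lines = np.asarray(self.image_lines, dtype=float)
        if len(self.world_points) != len(self.image_points):
            raise InvalidArgumentError("point pair count mismatch")
        if len(self.world_lines) != len(self.image_lines):
            raise InvalidArgumentError("line pair count mismatch")
        if len(self.world_points) + len(self.world_lines) < 5:
            raise InvalidArgumentError("need at least 4+4 (or 5 mixed) pairs")


# ---------------------------------------------------------------------------
# centerline extraction


def _scan_family(img_inv: np.ndarray, depth: float, win: int,
                 min_points: int, row_step: int):
    """Extract subpixel line centers by scanning rows of ``img_inv`` (dark
    lines appear as positive peaks).  Returns tracks of (row, col) samples.

    Peaks are located per scanline, refined by intensity-weighted centroids
    over a ±win window, and rejected near line crossings (window edges still
    dark).  Tracks are grown by nearest-prediction association so tilted and
    gently curved (distorted) lines are followed.
    """
    h, w = img_inv.shape
    thresh = 0.45 * depth
    edge_max = 0.30 * depth
    tracks: list[dict] = []
    cols = np.arange(w, dtype=float)
    for row in range(0, h, row_step):
        line = img_inv[row]
        core = line[1:-1]
        is_peak = (core >= thresh) & (core >= line[:-2]) & (core >= line[2:])
        idx = np.flatnonzero(is_peak) + 1
        if len(idx) == 0:
            continue
        # merge plateau neighbours
        keep = np.ones(len(idx), dtype=bool)
        keep[1:] = np.diff(idx) > 2
        idx = idx[keep]
        peaks = []
        for j in idx:
            lo, hi = j - win, j + win + 1
            if lo < 0 or hi > w:
                continue
            if line[lo] > edge_max or line[hi - 1] > edge_max:
                continue  # crossing or clutter
            wgt = line[lo:hi]
            tot = wgt.sum()
            if tot <= 0:
                continue
            peaks.append(float((cols[lo:hi] * wgt).sum() / tot))
        # associate with tracks
        for u in peaks:
            best, best_err = None, 6.0
            for tr in tracks:
                if row - tr["last_row"] > 12 * row_step:
                    continue
                pred = tr["last_u"] + tr["slope"] * (row - tr["last_row"])
                err = abs(u - pred)
                if err < best_err:
                    best, best_err = tr, err
            if best is None:
                tracks.append(
                    {"rows": [row], "us": [u], "last_row": row, "last_u": u,
                     "slope": 0.0}
                )
            else:
                best["rows"].append(row)
                best["us"].append(u)
                n = len(best["us"])
                if n >= 2:
                    r0, u0 = best["rows"][0], best["us"][0]
                    best["slope"] = (u - u0) / max(row - r0, 1)
                best["last_row"], best["last_u"] = row, u
    return [t for t in tracks if len(t["us"]) >= min_points]


def extract_center_lines(raster, line_width_px: float = 3.0,
                         row_step: int = 2, min_points: int = 30) -> CenterLineSet:
    """Extract subpixel grid centerlines from a raster.

    Scanlines run perpendicular to each family: image rows for the
    near-vertical lines, columns for the near-horizontal ones.  Raises
    :class:`ExtractionError` when the raster has no usable contrast or no
    line survives.
    """
    img = np.asarray(raster, dtype=float)
    if img.ndim != 2:
        raise InvalidArgumentError("raster must be 2-D grayscale")
    bg = np.percentile(img, 90)
    # line cores can be well under 1% of pixels on a sparse grid
    depth = bg - np.percentile(img, 0.2)
    if depth < 20:
        raise ExtractionError(
            f"insufficient contrast: dynamic range {depth:.1f} below 20"
        )
    inv = np.clip(bg - img, 0.0, None)
    win = max(3, int(round(2 * line_width_px)))

    def build(tracks, orientation):
        lines = []
        for tr in tracks:
            if orientation == "vertical":
                pts = np.column_stack([tr["us"], tr["rows"]])
            else:
                pts = np.column_stack([tr["rows"], tr["us"]])
            ln = CenterLine(points=pts, orientation=orientation)
            ln.fit_line()
            lines.append(ln)
        key = (lambda l: l.points[:, 0].mean()) if orientation == "vertical" \
            else (lambda l: l.points[:, 1].mean())
        return sorted(lines, key=key)

    vertical = build(_scan_family(inv, depth, win, min_points, row_step), "vertical")
    horizontal = build(_scan_family(inv.T, depth, win, min_points, row_step),
                       "horizontal")
    if not vertical and not horizontal:
        raise ExtractionError("no grid lines found")
    return CenterLineSet(vertical=vertical, horizontal=horizontal,
                         image_shape=img.shape)


# ---------------------------------------------------------------------------
# plumb-line LM optimization


def _pack(k, u0, v0, alphas, phis):
    return np.concatenate([[k, u0, v0], alphas, phis])


def _unpack(x, n):
    return x[0], x[1], x[2], x[3 : 3 + n], x[3 + n : 3 + 2 * n]


def straightness_residuals(params, lines) -> np.ndarray:
    """Residual vector of the plumb-line objective.

    ``params`` is ``(k, u0, v0, alphas, phis)`` with per-line arrays;
    residual (i, j) is the signed distance of the corrected point j of line i
    from its line.  The objective of the optimization is the sum of squares.
    """
    k, u0, v0, alphas, phis = params
    out = []
    for ln, a, p in zip(_as_lines(lines), alphas, phis):
        u, v = ln.points[:, 0], ln.points[:, 1]
        du, dv = u - u0, v - v0
        r2 = du * du + dv * dv
        uh = u + k * du * r2
        vh = v + k * dv * r2
        out.append(uh * np.cos(a) + vh * np.sin(a) + p)
    return np.concatenate(out)


def _as_lines(lines):
    if isinstance(lines, CenterLineSet):
        return lines.lines
    return list(lines)


def _residuals_and_jac(x, lines, counts):
    n = len(counts)
    k, u0, v0, alphas, phis = _unpack(x, n)
    m_total = int(np.sum(counts))
    r = np.empty(m_total)
    J = np.zeros((m_total, 3 + 2 * n))
    pos = 0
    for i, ln in enumerate(lines):
        u, v = ln.points[:, 0], ln.points[:, 1]
        m = len(u)
        a, p = alphas[i], phis[i]
        ca, sa = np.cos(a), np.sin(a)
        du, dv = u - u0, v - v0
        r2 = du * du + dv * dv
        uh = u + k * du * r2
        vh = v + k * dv * r2
        sl = slice(pos, pos + m)
        r[sl] = uh * ca + vh * sa + p
        J[sl, 0] = du * r2 * ca + dv * r2 * sa
        J[sl, 1] = k * ((-r2 - 2 * du * du) * ca + (-2 * du * dv) * sa)
        J[sl, 2] = k * ((-2 * du * dv) * ca + (-r2 - 2 * dv * dv) * sa)
        J[sl, 3 + i] = -uh * sa + vh * ca
        J[sl, 3 + n + i] = 1.0
        pos += m
    return r, J


def fit_distortion(lines, init=None, image_shape=None) -> DistortionFit:
    """Levenberg-Marquardt fit of (k, u0, v0) and all line parameters.

    Per-line (alpha, phi) are initialized from total-least-squares fits to
    the raw points; (u0, v0) starts at the raster center and k at 0 unless
    ``init=(k, u0, v0)`` is given.  Needs lines from both families — with a
    single pencil of lines the principal point is unconstrained along them.
    """
    lset = lines if isinstance(lines, CenterLineSet) else None
    line_list = _as_lines(lines)
    n = len(line_list)
    if n < 4:
        raise DegenerateGeometryError("need at least 4 lines")
    if lset is not None and (not lset.vertical or not lset.horizontal):
        raise DegenerateGeometryError("need lines from both grid families")
    counts = np.array([ln.m for ln in line_list])
    if counts.sum() < 3 + 2 * n:
        raise DegenerateGeometryError("fewer points than parameters")
    for ln in line_list:
        if ln.alpha == 0.0 and ln.phi == 0.0:
            ln.fit_line()
    alphas = np.array([ln.alpha for ln in line_list])
    phis = np.array([ln.phi for ln in line_list])
    if init is not None:
        k0, u00, v00 = init
    else:
        k0 = 0.0
        if image_shape is None and lset is not None:
            image_shape = lset.image_shape
        if image_shape is not None:
            v00, u00 = image_shape[0] / 2.0, image_shape[1] / 2.0
        else:
            allpts = np.vstack([ln.points for ln in line_list])
            u00, v00 = allpts.mean(axis=0)

    x0 = _pack(k0, u00, v00, alphas, phis)
    res = least_squares(
        lambda x: _residuals_and_jac(x, line_list, counts)[0],
        x0,
        jac=lambda x: _residuals_and_jac(x, line_list, counts)[1],
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=400,
    )
    k, u0, v0, alphas, phis = _unpack(res.x, n)
    for ln, a, p in zip(line_list, alphas, phis):
        ln.alpha, ln.phi = float(a), float(p)
    intr = IntrinsicParams(fx=1.0, fy=1.0, u0=float(u0), v0=float(v0),
                           k=float(k),
                           image_shape=lset.image_shape if lset else image_shape)
    out_set = lset if lset is not None else CenterLineSet(
        vertical=[l for l in line_list if l.orientation == "vertical"],
        horizontal=[l for l in line_list if l.orientation == "horizontal"],
    )
    return DistortionFit(
        intr=intr,
        lines=out_set,
        objective_value=float(2 * res.cost),
        converged=bool(res.success),
        n_iterations=int(res.nfev),
        message=res.message,
    )


# ---------------------------------------------------------------------------
# homography (DLT on points and lines)


def _cross_matrix(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def _normalizer(pts: np.ndarray) -> np.ndarray:
    """Hartley similarity normalization matrix for (N,2) points."""
    c = pts.mean(axis=0)
    s = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
    return np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])


def estimate_homography(c: Correspondences) -> Homography:
    """Direct linear transform from point and line pairs.

    Point pairs contribute ``p x (H P) = 0`` rows; line pairs contribute
    ``L x (H^T l) = 0`` (the world->image convention ``p ~ H P`` with its
    contravariant line map).  The stacked homogeneous system is solved by
    singular value decomposition after Hartley normalization on both frames.
    """
    Pw = c.world_points
    pi = c.image_points
    if len(Pw) >= 4:
        # any 4-subset fully collinear is degenerate; cheap necessary check
        _check_not_all_collinear(Pw)
        _check_not_all_collinear(pi)
    norm_pts = np.vstack([Pw, _line_anchor_points(c.world_lines)]) \
        if len(c.world_lines) else Pw
    Tw = _normalizer(norm_pts if len(norm_pts) else Pw)
    Ti = _normalizer(
        np.vstack([pi, _line_anchor_points(c.image_lines)])
        if len(c.image_lines) else pi
    )
    rows = []
    for P, p in zip(Pw, pi):
        Ph = Tw @ np.array([P[0], P[1], 1.0])
        ph = Ti @ np.array([p[0], p[1], 1.0])
        Cx = _cross_matrix(ph)
        for rrow in Cx[:2]:
            rows.append(np.kron(rrow, Ph))
    Tw_inv_T = np.linalg.inv(Tw).T
    Ti_inv_T = np.linalg.inv(Ti).T
    for L, l in zip(c.world_lines, c.image_lines):
        Ln = Tw_inv_T @ L
        ln = Ti_inv_T @ l
        Cx = _cross_matrix(Ln / np.linalg.norm(Ln))
        for rrow in Cx[:2]:
            rows.append(np.kron(ln / np.linalg.norm(ln), rrow))
    Amat = np.asarray(rows)
    if len(Amat) < 8:
        raise DegenerateGeometryError("not enough constraints for H")
    _, svals, Vt = np.linalg.svd(Amat)
    if len(svals) < 9:
        raise DegenerateGeometryError("constraint matrix rank-deficient")
    if svals[-2] <= 1e-12 * svals[0]:
        raise DegenerateGeometryError(
            "nullspace dimension > 1: correspondence geometry degenerate"
        )
    if svals[-1] / svals[-2] > 0.1:
        raise IllConditionedGeometryError(
            f"smallest/second-smallest singular value ratio "
            f"{svals[-1] / svals[-2]:.3f} > 0.1"
        )
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Ti) @ Hn @ Tw
    return Homography(H)


def _line_anchor_points(lines: np.ndarray) -> np.ndarray:
    """A representative finite point on each homogeneous line (for the
    normalization statistics)."""
    pts = []
    for l in lines:
        n = l[:2]
        nn = n @ n
        if nn < 1e-18:
            continue
        pts.append(-l[2] * n / nn)
    return np.asarray(pts) if pts else np.empty((0, 2))


def _check_not_all_collinear(pts: np.ndarray):
    d = pts - pts.mean(axis=0)
    s = np.linalg.svd(d, compute_uv=False)
    if s[-1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear")


def decompose_imaging(H: Homography, intr: IntrinsicParams, Lu: float,
                      Lv: float, M_nominal: float, estimate_focal: bool = True):
    """Split a plane-to-image homography into pose and magnification.

    With ``estimate_focal=True`` (pipeline default) the focal scales are
    taken as the column norms of the upper-left 2x2 of ``H`` normalized to
    ``H[2,2] = 1`` — for the fronto-parallel calibration plane of a stage
    they equal the metric pixel scale (px/µm, the known grid pitch having
    provided world units); a single plane cannot separate focal length from
    plane distance, so the unit third-row convention fixes the scale.  With
    ``estimate_focal=False`` the given ``intr.fx, intr.fy`` are trusted and
    ``[r1 r2 t] = A^-1 H / lambda`` with lambda chosen so ``|r1| = 1``,
    which also recovers the plane offset ``t3``.

    The rotation is recovered as the nearest proper rotation, ``t`` from the
    third column, and ``t_hat = Lu * t`` applies the pixel-pitch correction.
    Returns ``(pose, magnification, (delta_x, delta_y))`` with delta the
    translation components of the first and second rows of ``[R | t_hat]``.
    """
    Hm = H.H if isinstance(H, Homography) else np.asarray(H, dtype=float)
    if estimate_focal:
        if abs(Hm[2, 2]) < 1e-15:
            raise DegenerateGeometryError("H[2,2] ~ 0: plane through the camera")
        Hm = Hm / Hm[2, 2]
        fx = float(np.hypot(Hm[0, 0], Hm[1, 0]))
        fy = float(np.hypot(Hm[0, 1], Hm[1, 1]))
    else:
        fx, fy = float(intr.fx), float(intr.fy)
    if fx <= 0 or fy <= 0:
        raise DegenerateGeometryError("vanishing focal scale")
    A = np.array([[fx, 0, intr.u0], [0, fy, intr.v0], [0, 0, 1.0]])
    B = np.linalg.solve(A, Hm)
    lam = 0.5 * (np.linalg.norm(B[:, 0]) + np.linalg.norm(B[:, 1]))
    if B[2, 2] < 0:  # keep t3 >= 0 convention
        B = -B
    b1, b2, t = B[:, 0] / lam, B[:, 1] / lam, B[:, 2] / lam
    r3 = np.cross(b1, b2)
    Rraw = np.column_stack([b1, b2, r3])
    U, _, Vt = np.linalg.svd(Rraw)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ D @ Vt
    t_hat = Lu * t
    pose = ExtrinsicPose(R=R, t=t, t_hat=t_hat)
    mag = MagnificationResult.from_focal(fx, fy, Lu, Lv, M_nominal)
    delta = (float(t_hat[0]), float(t_hat[1]))
    return pose, mag, delta


def grid_correspondences(lines: CenterLineSet, intr: IntrinsicParams,
                         pitch_um: float, max_points: int | None = None
                         ) -> Correspondences:
    """Build world<->image correspondences from fitted grid centerlines.

    Line points are undistorted with the fitted intrinsics and refit as
    straight lines; crossings of the two families give point pairs.  World
    coordinates assign consecutive detected lines consecutive multiples of
    the pitch, centered on the detected set — the arbitrary origin choice is
    absorbed by the translation of the recovered pose.
    """
    if len(lines.vertical) < 2 or len(lines.horizontal) < 2:
        raise DegenerateGeometryError("need >= 2 lines per family")

    def undistorted_line(ln):
        pts = undistort_point(ln.points, intr)
        a, p = _tls_line(pts)
        return np.array([np.cos(a), np.sin(a), p])

    vlines = [undistorted_line(l) for l in lines.vertical]
    hlines = [undistorted_line(l) for l in lines.horizontal]
    nv, nh = len(vlines), len(hlines)
    Xs = (np.arange(nv) - (nv - 1) / 2.0) * pitch_um
    Ys = (np.arange(nh) - (nh - 1) / 2.0) * pitch_um
    wlines = [np.array([1.0, 0.0, -x]) for x in Xs] + \
             [np.array([0.0, 1.0, -y]) for y in Ys]
    ilines = vlines + hlines
    wpts, ipts = [], []
    for i, lv in enumerate(vlines):
        for j, lh in enumerate(hlines):
            M = np.array([lv[:2], lh[:2]])
            rhs = -np.array([lv[2], lh[2]])
            det = np.linalg.det(M)
            if abs(det) < 1e-12:
                continue
            ipts.append(np.linalg.solve(M, rhs))
            wpts.append([Xs[i], Ys[j]])
    wpts, ipts = np.asarray(wpts), np.asarray(ipts)
    if max_points is not None and len(wpts) > max_points:
        sel = np.linspace(0, len(wpts) - 1, max_points).astype(int)
        wpts, ipts = wpts[sel], ipts[sel]
    return Correspondences(world_points=wpts, image_points=ipts,
                           world_lines=np.asarray(wlines),
                           image_lines=np.asarray(ilines))


class ImageUndistorter:
    """Resample observed rasters into theoretical (distortion-free) space.

    For every theoretical pixel the corresponding observed position is
    solved once (vectorized Newton on the radial cubic) and cached, so a
    whole series is warped with one coordinate map.  Used to compensate the
    image distortion before stitching-based estimates, which would otherwise
    inherit a field-dependent bias from the distortion gradient.
    """

    def __init__(self, intr: IntrinsicParams, shape: tuple, order: int = 3):
        self.intr = intr
        self.shape = tuple(shape)
        self.order = order
        h, w = self.shape
        v, u = np.mgrid[0:h, 0:w].astype(float)
        du, dv = u - intr.u0, v - intr.v0
        r_theo = np.hypot(du, dv)
        k = intr.k
        r = r_theo.copy()
        for _ in range(30):  # Newton on r + k r^3 = r_theo
            f = r + k * r**3 - r_theo
            r = r - f / (1.0 + 3.0 * k * r * r)
        scale = np.ones_like(r)
        np.divide(r, r_theo, out=scale, where=r_theo > 0)
        self._coords = np.stack([intr.v0 + dv * scale, intr.u0 + du * scale])

    def __call__(self, img: np.ndarray) -> np.ndarray:
        from scipy.ndimage import map_coordinates

        return map_coordinates(np.asarray(img, dtype=float), self._coords,
                               order=self.order, mode="nearest")


# ---------------------------------------------------------------------------
# estimator facade


class DistortionCalibrator(BaseEstimator, TransformerMixin):
    """Fit the full image-distortion compensation from grid rasters.

    ``fit`` runs centerline extraction, the plumb-line LM optimization
    (jointly over several rasters with shared ``(k, u0, v0)`` when more than
    one is given), homography estimation, and decomposition into
    magnification and pose.  ``transform`` maps observed pixel coordinates to
    theoretical (undistorted) ones with the fitted intrinsics.

    Parameters
    ----------
    pitch_um : float
        Grid square side length (µm) — the metric scale of the target.
    Lu, Lv : float
        Physical pixel side lengths (µm/pixel).
    M_nominal : float
        Rated objective magnification.
    line_width_px : float
        Approximate rendered/printed line thickness for the extractor.

    Attributes
    ----------
    k_, u0_, v0_ : fitted radial distortion factor and principal point.
    fx_, fy_ : focal scales (px/µm).
    M_, M_prime_ : mean magnification and its ratio to nominal.
    R_, t_, t_hat_ : plane pose.
    delta_ : (delta_x, delta_y) distortion compensation offsets (µm).
    objective_px2_, converged_ : plumb-line optimization diagnostics.
    """

    def __init__(self, pitch_um: float = 50.0, Lu: float = 20.0,
                 Lv: float = 20.0, M_nominal: float = 20.0,
                 line_width_px: float = 3.0):
        self.pitch_um = pitch_um
        self.Lu = Lu
        self.Lv = Lv
        self.M_nominal = M_nominal
        self.line_width_px = line_width_px

    def fit(self, X, y=None):
        rasters = X if isinstance(X, (list, tuple)) else [X]
        sets = [extract_center_lines(r, line_width_px=self.line_width_px)
                for r in rasters]
        all_lines = [ln for s in sets for ln in s.lines]
        merged = CenterLineSet(
            vertical=[l for l in all_lines if l.orientation == "vertical"],
            horizontal=[l for l in all_lines if l.orientation == "horizontal"],
            image_shape=sets[0].image_shape,
        )
        fitres = fit_distortion(merged)
        self.fit_ = fitres
        self.lines_ = sets[0]
        self.k_ = fitres.intr.k
        self.u0_ = fitres.intr.u0
        self.v0_ = fitres.intr.v0
        self.objective_px2_ = fitres.objective_value
        self.converged_ = fitres.converged
        corr = grid_correspondences(sets[0], fitres.intr, self.pitch_um,
                                    max_points=120)
        H = estimate_homography(corr)
        pose, mag, delta = decompose_imaging(H, fitres.intr, self.Lu, self.Lv,
                                             self.M_nominal)
        self.H_ = H
        self.fx_ = mag.Mu / self.Lu
        self.fy_ = mag.Mv / self.Lv
        self.M_ = mag.M
        self.M_prime_ = mag.M_prime
        self.R_ = pose.R
        self.t_ = pose.t
        self.t_hat_ = pose.t_hat
        self.delta_ = delta
        self.magnification_ = mag
        self.pose_ = pose
        self.intr_ = IntrinsicParams(fx=self.fx_, fy=self.fy_, u0=self.u0_,
                                     v0=self.v0_, k=self.k_,
                                     image_shape=merged.image_shape)
        return self

    def transform(self, X):
        """Undistort observed pixel coordinates (N, 2)."""
        return undistort_point(np.asarray(X, dtype=float), self.intr_)

    def calibration_block(self) -> dict:
        """JSON-ready calibration summary."""
        return {
            "k": self.k_, "u0": self.u0_, "v0": self.v0_,
            "fx": self.fx_, "fy": self.fy_,
            "M": self.M_, "M_prime": self.M_prime_,
            "delta_x": self.delta_[0], "delta_y": self.delta_[1],
            "R": self.R_.tolist(), "t_hat": self.t_hat_.tolist(),
            "objective": self.objective_px2_, "converged": self.converged_,
        }
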
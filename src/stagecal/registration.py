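"""Pairwise translation registration and deflection-angle estimation.

The camera-mounting deflection angle between image and stage axes is
estimated by stepping the stage along one axis with ~half-frame overlap and
stitching consecutive frames: for an X series the offset ``(dx, dy)`` of the
later frame yields ``theta = arctan(dy/dx)`` (degrees).

Two translation backends are provided:

``fft``
    Phase correlation (cross-power spectrum) with an integer peak search and
    local upsampled-DFT subpixel refinement.  Because a calibration grid is
    periodic, the correlation surface has near-identical peaks at every
    lattice offset; when the commanded step is known (it always is in this
    tool) the ``expected`` argument restricts the peak search to the
    half-period window around it.

``sift``
    SIFT feature matching with a 1-px translation consensus (RANSAC over
    1-point translation hypotheses), falling back to phase correlation when
    fewer than 8 inliers survive.  Mostly useful as an independent
    cross-check (``backend="cross-check"`` runs both and raises
    :class:`AmbiguousOffsetError` if they disagree by more than half a grid
    period).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import (
    AmbiguousOffsetError,
    InvalidArgumentError,
    RegistrationError,
)

__all__ = [
    "StitchResult",
    "estimate_offset",
    "deflection_angle",
    "average_deflection",
    "DeflectionEstimator",
]


@dataclass
class StitchResult:
    """Translation of frame B relative to frame A, in signed pixels."""

    dx: float
    dy: float
    n_inliers: int = 0
    method: str = "fft"
    theta_deg: float | None = None

    def with_theta(self, axis: str = "x") -> "StitchResult":
        self.theta_deg = deflection_angle(self.dx, self.dy, axis=axis)
        return self


def deflection_angle(dx: float, dy: float, axis: str = "x") -> float:
    """Deflection angle (degrees) from a stitching offset.

    For an X-direction series ``theta = arctan(dy/dx)``; for a Y-direction
    series the roles transpose (``-arctan(dx/dy)``) so both axes estimate the
    same mounting angle with the same sign.
    """
    if axis == "x":
        if dx == 0:
            raise InvalidArgumentError("deflection angle undefined for dx = 0")
        return float(np.degrees(np.arctan(dy / dx)))
    if axis == "y":
        if dy == 0:
            raise InvalidArgumentError("deflection angle undefined for dy = 0")
        return float(-np.degrees(np.arctan(dx / dy)))
    raise InvalidArgumentError("axis must be 'x' or 'y'")


def average_deflection(results) -> float:
    """Arithmetic mean of per-pair deflection angles (degrees).

    Accepts floats or :class:`StitchResult` objects with ``theta_deg``
    populated.  This is a mean of angles, not the angle of summed offsets.
    """
    thetas = []
    for r in results:
        if isinstance(r, StitchResult):
            if r.theta_deg is None:
                raise InvalidArgumentError("StitchResult without theta_deg")
            thetas.append(r.theta_deg)
        else:
            thetas.append(float(r))
    if not thetas:
        raise InvalidArgumentError("average_deflection needs at least one result")
    return float(np.mean(thetas))


def _upsampled_peak(F: np.ndarray, peak: np.ndarray, radius: float = 1.5,
                    factor: int = 100) -> np.ndarray:
    """Refine a correlation peak by evaluating the cross-power inverse DFT on
    a fine local grid (matrix-multiply DFT around ``peak``)."""
    h, w = F.shape
    fy = np.fft.fftfreq(h)
    fx = np.fft.fftfreq(w)
    n = int(2 * radius * factor) + 1
    dy = peak[0] + np.linspace(-radius, radius, n)
    dx = peak[1] + np.linspace(-radius, radius, n)
    Ey = np.exp(2j * np.pi * np.outer(dy, fy))  # (n, h)
    Ex = np.exp(2j * np.pi * np.outer(fx, dx))  # (w, n)
    cc = np.real(Ey @ F @ Ex)
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    return np.array([dy[iy], dx[ix]])


def _fft_offset(a: np.ndarray, b: np.ndarray, expected=None,
                search_radius: float | None = None, eps_frac: float = 0.5):
    """Regularized phase-correlation translation of b relative to a.

    A Hann window suppresses the wrap-around discontinuities of the FFT
    (frame borders cut grid lines mid-period, which otherwise correlate at
    spurious offsets), and the cross-power spectrum is soft-whitened,
    ``R / (|R| + eps_frac * mean|R|)`` — full whitening would weight the
    noise-only frequencies between the grid harmonics as strongly as the
    signal and smear the peak along the line-direction ridges.
    """
    win = np.hanning(a.shape[0])[:, None] * np.hanning(a.shape[1])[None, :]
    A = np.fft.fft2((a - a.mean()) * win)
    B = np.fft.fft2((b - b.mean()) * win)
    R = B * np.conj(A)
    mag = np.abs(R)
    R = R / (mag + eps_frac * mag.mean() + 1e-300)
    cc = np.real(np.fft.ifft2(R))
    h, w = cc.shape
    yy = np.fft.fftfreq(h) * h  # signed shift per row index
    xx = np.fft.fftfreq(w) * w
    if expected is not None and search_radius is not None:
        rx, ry = (search_radius if np.ndim(search_radius) else
                  (search_radius, search_radius))
        ey, ex = float(expected[1]), float(expected[0])  # expected (dx,dy)->(row,col)
        mask = (np.abs(((yy - ey + h / 2) % h) - h / 2)[:, None] <= ry) & (
            np.abs(((xx - ex + w / 2) % w) - w / 2)[None, :] <= rx
        )
        cc = np.where(mask, cc, -np.inf)
        if not np.isfinite(cc).any():
            raise RegistrationError("no correlation support in the expected window")
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    peak = np.array([yy[iy], xx[ix]])
    ref = _upsampled_peak(R, peak, radius=1.0, factor=15)
    ref = _upsampled_peak(R, ref, radius=0.05, factor=400)
    if expected is not None:
        # a shift and its frame-period complement are indistinguishable in
        # the FFT; report the representative nearest the expected offset
        ref[0] = expected[1] + ((ref[0] - expected[1] + h / 2) % h) - h / 2
        ref[1] = expected[0] + ((ref[1] - expected[0] + w / 2) % w) - w / 2
    quality = float(cc[iy, ix])
    return float(ref[1]), float(ref[0]), quality  # dx, dy


def _overlap_refine(a: np.ndarray, b: np.ndarray, dx: float, dy: float,
                    inset: int = 4, min_size: int = 64):
    """Re-estimate the subpixel offset on the overlap crop only.

    At large shifts the non-shared image regions leave a small (~0.1 px at
    half-frame overlap) bias in the full-frame correlation; cropping both
    frames to their common region makes the pair fully shared content and
    the residual-shift estimate nearly exact.
    """
    h, w = a.shape
    ix, iy = int(round(dx)), int(round(dy))
    ax0, ax1 = max(0, -ix) + inset, w + min(0, -ix) - inset
    ay0, ay1 = max(0, -iy) + inset, h + min(0, -iy) - inset
    if ax1 - ax0 < min_size or ay1 - ay0 < min_size:
        return dx, dy
    a_crop = a[ay0:ay1, ax0:ax1]
    b_crop = b[ay0 + iy:ay1 + iy, ax0 + ix:ax1 + ix]
    frac = (dx - ix, dy - iy)
    rx, ry, _ = _fft_offset(a_crop, b_crop, expected=frac, search_radius=2.0)
    return ix + rx, iy + ry


def _sift_offset(a: np.ndarray, b: np.ndarray, expected=None,
                 search_radius: float | None = None):
    from skimage.feature import SIFT, match_descriptors

    det_a, det_b = SIFT(), SIFT()
    try:
        det_a.detect_and_extract(a.astype(float))
        det_b.detect_and_extract(b.astype(float))
    except RuntimeError as e:  # no features
        raise RegistrationError(f"SIFT found no features: {e}") from None
    matches = match_descriptors(det_a.descriptors, det_b.descriptors,
                                max_ratio=0.9, cross_check=True)
    if len(matches) == 0:
        raise RegistrationError("SIFT produced no matches")
    # displacement (dx, dy) implied by each match: keypoints are (row, col)
    disp = det_a.keypoints[matches[:, 0]] - det_b.keypoints[matches[:, 1]]
    disp = disp[:, ::-1] * -1.0  # -> (dx, dy) of b relative to a
    if expected is not None and search_radius is not None:
        rad = np.asarray(search_radius, dtype=float)
        if rad.ndim == 0:
            rad = np.array([rad, rad])
        keep = np.all(np.abs(disp - np.asarray(expected, float)) <= rad, axis=1)
        disp = disp[keep]
        if len(disp) == 0:
            raise RegistrationError("no SIFT matches inside the expected window")
    # 1-point RANSAC: each displacement is a translation hypothesis
    best_inl = np.zeros(len(disp), dtype=bool)
    for cand in disp:
        inl = np.all(np.abs(disp - cand) <= 1.0, axis=1)
        if inl.sum() > best_inl.sum():
            best_inl = inl
    n_inl = int(best_inl.sum())
    if n_inl < 8:
        return None, n_inl
    dxy = disp[best_inl].mean(axis=0)
    return (float(dxy[0]), float(dxy[1])), n_inl


def estimate_offset(img_a, img_b, expected=None, backend: str = "fft",
                    search_radius: float | None = None) -> StitchResult:
    """Estimate the translation of ``img_b`` relative to ``img_a``.

    Parameters
    ----------
    expected : (dx, dy) or None
        Approximate offset in pixels (e.g. from the commanded stage step).
        When given together with ``search_radius``, the correlation peak is
        searched only within that window — the cure for lattice aliasing on
        periodic grid targets.
    backend : {"fft", "sift", "cross-check"}
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidArgumentError("images must be 2-D and the same shape")
    if expected is not None and search_radius is None:
        search_radius = 12.0
    if backend == "fft":
        dx, dy, _ = _fft_offset(a, b, expected, search_radius)
        dx, dy = _overlap_refine(a, b, dx, dy)
        return StitchResult(dx=dx, dy=dy, method="fft")
    if backend == "sift":
        got, n_inl = _sift_offset(a, b, expected, search_radius)
        if got is None:  # fallback per contract
            dx, dy, _ = _fft_offset(a, b, expected, search_radius)
            return StitchResult(dx=dx, dy=dy, n_inliers=n_inl, method="fft-fallback")
        return StitchResult(dx=got[0], dy=got[1], n_inliers=n_inl, method="sift")
    if backend == "cross-check":
        r1 = estimate_offset(a, b, expected, "fft", search_radius)
        r2 = estimate_offset(a, b, expected, "sift", search_radius)
        period = search_radius * 2 if search_radius else 25.0
        if max(abs(r1.dx - r2.dx), abs(r1.dy - r2.dy)) > period / 2:
            raise AmbiguousOffsetError(
                f"backends disagree: fft=({r1.dx:.2f},{r1.dy:.2f}) "
                f"sift=({r2.dx:.2f},{r2.dy:.2f})"
            )
        return r1
    raise InvalidArgumentError(f"unknown backend {backend!r}")


class DeflectionEstimator(BaseEstimator):
    """Estimate the camera-mounting deflection angle from a stepped series.

    Parameters
    ----------
    axis : {"x", "y"}
        Stage axis the series stepped along.
    step_px : float or None
        Expected per-step content offset in pixels (commanded step times the
        pixel scale), used to disambiguate the periodic grid.
    backend : registration backend passed to :func:`estimate_offset`.
    intr : IntrinsicParams or None
        When given, frames are resampled into distortion-free coordinates
        before stitching (image-distortion compensation precedes the
        deflection estimate in the calibration chain).

    Attributes
    ----------
    theta_deg_ : float
        Mean deflection angle over consecutive pairs (degrees).
    results_ : list of StitchResult
        Per-pair offsets and angles (Table-2-like layout).
    """

    def __init__(self, axis: str = "x", step_px: float | None = None,
                 backend: str = "fft", search_radius: float = 12.0,
                 intr=None):
        self.axis = axis
        self.step_px = step_px
        self.backend = backend
        self.search_radius = search_radius
        self.intr = intr

    def fit(self, frames, y=None):
        frames = list(frames)
        if self.intr is not None:
            from .distortion import ImageUndistorter

            warp = ImageUndistorter(self.intr, np.asarray(frames[0]).shape)
            frames = [warp(f) for f in frames]
        if len(frames) < 2:
            raise InvalidArgumentError("need at least two frames")
        if self.step_px is not None:
            # the deflection is unknown at this stage: the cross-axis search
            # window must admit any plausible mounting angle (~<6.5 deg)
            cross = 0.12 * abs(self.step_px) + self.search_radius
            if self.axis == "x":
                expected, radius = (self.step_px, 0.0), (self.search_radius, cross)
            else:
                expected, radius = (0.0, self.step_px), (cross, self.search_radius)
        else:
            expected, radius = None, None

        def register_all(exp, rad):
            return [
                estimate_offset(frames[i], frames[i + 1], expected=exp,
                                backend=self.backend, search_radius=rad)
                for i in range(len(frames) - 1)
            ]

        self.results_ = register_all(expected, radius)
        if expected is not None and len(self.results_) >= 3:
            # consensus pass: a wide window can let a single pair lock onto
            # a grid-lattice alias; re-register around the median offset
            med = (float(np.median([r.dx for r in self.results_])),
                   float(np.median([r.dy for r in self.results_])))
            self.results_ = register_all(med, self.search_radius)
        for r in self.results_:
            r.with_theta(axis=self.axis)
        self.theta_deg_ = average_deflection(self.results_)
        return self

    def table(self):
        """Per-pair (group, dy, dx, theta) rows plus the average."""
        rows = [
            {"group": i + 1, "dy": r.dy, "dx": r.dx, "theta_deg": r.theta_deg}
            for i, r in enumerate(self.results_)
        ]
        rows.append({"group": "average", "dy": None, "dx": None,
                     "theta_deg": self.theta_deg_})
        return rows
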
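"""Raster and calibration-file I/O.

Rasters are TIFF or PNG; internally images are 2-D float arrays in [0, 1]
when normalized reading is requested, or raw integer arrays otherwise.
Calibration artifacts are versioned JSON so runs can be diffed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import SchemaError, StageCalError

__all__ = ["read_raster", "write_raster", "save_calibration_file",
           "load_calibration_file", "CALIB_SCHEMA_VERSION"]

CALIB_SCHEMA_VERSION = "1"


class RasterIOError(StageCalError, IOError):
    pass


def read_raster(path, normalize: bool = False) -> np.ndarray:
    """Read a TIFF/PNG raster as a 2-D grayscale array.

    RGB inputs are converted by luminance (Rec. 601 weights).  With
    ``normalize=True`` integer bit depths are scaled into [0, 1] so that
    full scale (255 or 65535) maps to exactly 1.
    """
    p = Path(path)
    if not p.exists():
        raise RasterIOError(f"no such raster: {p}")
    suffix = p.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            img = tifffile.imread(p)
        elif suffix == ".png":
            import imageio.v3 as iio

            img = iio.imread(p)
        else:
            raise RasterIOError(f"unsupported raster format: {p}")
    except RasterIOError:
        raise
    except Exception as e:
        raise RasterIOError(f"failed to read {p}: {e}") from e
    img = np.asarray(img)
    if img.ndim == 3:
        img = (
            0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        )
        if np.issubdtype(np.asarray(img).dtype, np.floating):
            img = img.astype(float)
    if img.ndim != 2:
        raise RasterIOError(f"{p}: expected 2-D grayscale, got shape {img.shape}")
    if normalize:
        if img.dtype == np.uint8 or (img.ndim == 2 and img.max() <= 255
                                     and np.issubdtype(img.dtype, np.integer)
                                     and img.dtype.itemsize == 1):
            return img.astype(float) / 255.0
        if np.issubdtype(img.dtype, np.integer):
            full = np.iinfo(img.dtype).max
            return img.astype(float) / full
        return img.astype(float)
    return img


def write_raster(path, img: np.ndarray) -> Path:
    """Write a 2-D array as TIFF or PNG (by extension)."""
    p = Path(path)
    arr = np.asarray(img)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(p, arr)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(p, arr)
    else:
        raise RasterIOError(f"unsupported raster format: {p}")
    return p


def save_calibration_file(path, sections: dict, provenance: dict | None = None):
    """Write the versioned calibration file.

    ``sections`` holds the calibration blocks (intrinsics, magnification,
    deflection, axis_errors, ...); ``provenance`` input paths/seeds.
    """
    doc = {"schema_version": CALIB_SCHEMA_VERSION}
    doc.update(sections)
    doc["provenance"] = provenance or {}
    _check_finite(doc)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
    return Path(path)


def load_calibration_file(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != CALIB_SCHEMA_VERSION:
        raise SchemaError(f"unknown schema_version {doc.get('schema_version')!r}")
    _check_finite(doc)
    return doc


def _check_finite(obj, keypath=""):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{keypath}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{keypath}[{i}]")
    elif isinstance(obj, float) and not np.isfinite(obj):
        raise SchemaError(f"non-finite value at {keypath}")
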
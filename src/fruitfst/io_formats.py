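"""Raster and tabular I/O with explicit unit and coordinate conventions.

All rasters are row-major numpy arrays with a 0-based (row, col) origin at
the top-left.  RGB images hold normalized channel intensities in [0, 1];
thermal rasters hold surface temperature in degrees Celsius, with NaN
marking pixels that are undefined (e.g. shifted out of frame during
registration).  Temperatures are never rescaled on load: a CSV cell
``37.25`` is exactly 37.25 degC.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

#: Radiometric sensor measurement range, degC.
SENSOR_RANGE_C = (-20.0, 400.0)

#: Working raster resolution (rows, cols) shared by the thermal sensor and
#: the downscaled RGB frame.
WORKING_SHAPE = (120, 160)


class FormatError(ValueError):
    """Raised for unreadable or structurally invalid image files."""


class ValidationError(ValueError):
    """Raised for readable files whose values violate domain invariants."""


@dataclass(frozen=True)
class RGBImage:
    """An RGB frame with channels normalized to [0, 1].

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3)
        Channel intensities in [0, 1], float64.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"RGBImage requires an HxWx3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("RGBImage dimensions must be >= 1")
        if np.nanmin(px) < 0.0 or np.nanmax(px) > 1.0:
            raise ValidationError("RGB intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ThermalImage:
    """A radiometric thermal raster of per-pixel temperatures in degC.

    Missing pixels (out of frame after registration) are NaN — never a
    silent zero.  Defined values must lie inside the sensor measurement
    range of -20 to 400 degC.
    """

    temps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=np.float64)
        if t.ndim != 2:
            raise FormatError(f"ThermalImage requires an HxW array, got {t.shape}")
        finite = t[np.isfinite(t)]
        lo, hi = SENSOR_RANGE_C
        if finite.size and (finite.min() < lo or finite.max() > hi):
            bad = np.argwhere(np.isfinite(t) & ((t < lo) | (t > hi)))[0]
            raise ValidationError(
                f"temperature {t[tuple(bad)]:.2f} degC at (row={bad[0]}, "
                f"col={bad[1]}) outside sensor range {lo}..{hi} degC"
            )
        object.__setattr__(self, "temps", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps.shape

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of undefined pixels."""
        return ~np.isfinite(self.temps)


@dataclass(frozen=True)
class CapturePair:
    """A co-captured RGB image and radiometric thermal raster plus metadata."""

    rgb: RGBImage
    thermal: ThermalImage
    imaging_distance_cm: float = 20.0
    latitude: float = 0.0
    longitude: float = 0.0
    timestamp: datetime | None = None
    capture_id: str = ""

    def __post_init__(self) -> None:
        if self.imaging_distance_cm <= 0:
            raise ValidationError("imaging distance must be > 0 cm")


def load_rgb(path: str | Path) -> RGBImage:
    """Load a PNG/JPEG as an RGBImage with channels mapped to [0, 1].

    8-bit channel values are divided by 255.  Grayscale or RGBA inputs are
    rejected: the segmentation chain is defined on 3-channel color frames.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # pragma: no cover - PIL error text varies
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    if img.mode != "RGB":
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got mode {img.mode!r}"
        )
    arr = np.asarray(img, dtype=np.float64) / 255.0
    return RGBImage(arr)


def save_rgb(rgb: RGBImage, path: str | Path) -> None:
    """Write an RGBImage as an 8-bit PNG (values rounded to nearest byte)."""
    arr = np.clip(np.rint(rgb.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def load_thermal(path: str | Path, dialect: str | None = None) -> ThermalImage:
    """Load a thermal raster (degC) from a single-band TIFF or a CSV grid.

    The CSV dialect is a headerless comma-separated grid, one row per
    raster row.  ``dialect`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tiff"
    if dialect == "tiff":
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise FormatError(
                f"{path}: expected a single-band raster, got shape {arr.shape}"
            )
        arr = arr.astype(np.float64)
    elif dialect == "csv":
        rows: list[list[float]] = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row:
                    continue
                try:
                    rows.append([float(c) for c in row])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}: non-numeric cell in row {i}: {exc}"
                    ) from exc
        if not rows or len({len(r) for r in rows}) != 1:
            raise FormatError(f"{path}: ragged or empty CSV grid")
        arr = np.asarray(rows, dtype=np.float64)
    else:
        raise ValueError(f"unknown thermal dialect {dialect!r}")
    return ThermalImage(arr)


def save_thermal(thermal: ThermalImage, path: str | Path) -> None:
    """Write a thermal raster as float TIFF or CSV grid (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, thermal.temps, delimiter=",", fmt="%.6f")
    else:
        tifffile.imwrite(path, thermal.temps.astype(np.float32))


def _box_weights(n_src: int, n_dst: int) -> np.ndarray:
    """Exact box-overlap weight matrix mapping n_src samples to n_dst.

    Row i holds the fractional overlap of destination cell i (width
    n_src/n_dst in source units) with each source cell; rows sum to 1.
    This is area-averaging resampling (the cv2.INTER_AREA scheme), exact
    for arbitrary, non-integer ratios.
    """
    w = np.zeros((n_dst, n_src))
    scale = n_src / n_dst
    for i in range(n_dst):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_src)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / scale


def resize_to_working(
    rgb: RGBImage, target_h: int = WORKING_SHAPE[0], target_w: int = WORKING_SHAPE[1]
) -> RGBImage:
    """Resize an RGB frame to the working resolution by area averaging.

    Downscaling 1440x1080 to 160x120 is a 9x reduction; box (area)
    averaging avoids the aliasing a point-sampling interpolator would
    introduce, and preserves the image mean exactly.
    """
    if target_h < 1 or target_w < 1:
        raise ValueError("target dimensions must be >= 1")
    if (rgb.height, rgb.width) == (target_h, target_w):
        return rgb
    wr = _box_weights(rgb.height, target_h)
    wc = _box_weights(rgb.width, target_w)
    out = np.einsum("ij,jkc,lk->ilc", wr, rgb.pixels, wc)
    return RGBImage(np.clip(out, 0.0, 1.0))


#: Canonical result-row schema, in deterministic column order.
RESULT_COLUMNS = [
    "capture_id",
    "timestamp",
    "latitude",
    "longitude",
    "mean_fst_c",
    "max_fst_c",
    "weather_fst_c",
    "air_temp_c",
    "risk_class",
    "flag",
]


def export_results(records: list[dict], path: str | Path, fmt: str | None = None) -> None:
    """Write analysis result rows as CSV (default) or JSON.

    Column order is fixed by RESULT_COLUMNS; numeric cells round-trip to at
    least 4 decimal places.  An empty record list yields a header-only CSV.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    df = pd.DataFrame(records, columns=RESULT_COLUMNS)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.4f")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=str)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by export_results."""
    return pd.read_csv(path)
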
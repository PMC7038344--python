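"""Thermal-RGB registration, radiometric calibration and masked FST statistics.

The thermal and RGB sensors sit a few millimetres apart in the housing, so
their frames are offset by a distance-dependent translation (about 40
pixels at the typical 20 cm imaging distance).  Registration here is an
integer pixel translation — no interpolation of temperatures, pixels
shifted out of frame become missing.  A single global linear calibration
(reference = slope * sensor + intercept), fitted against a trusted
thermometer over the 10-50 degC range typical of fruit surfaces, corrects
the radiometric values before fruit-mask statistics are taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import CapturePair, RGBImage, ThermalImage, resize_to_working
from .segmentation import (
    BinaryMask,
    SegmentationParams,
    SegmentationResult,
    segment_fruit,
)


class NoFruitPixelsError(ValueError):
    """Raised when the fruit mask covers no defined thermal pixels."""


@dataclass(frozen=True)
class RegistrationTransform:
    """Integer translation taking the thermal frame into the RGB frame.

    dx shifts columns (positive = right), dy shifts rows (positive =
    down).  The offset scales with imaging distance; the stored
    imaging_distance_cm documents the geometry it was measured at.  The
    default is the nominal 40 px offset along the sensor baseline (x)
    axis at 20 cm.
    """

    dx: int = 40
    dy: int = 0
    imaging_distance_cm: float = 20.0

    def validate_for(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if abs(self.dx) >= w or abs(self.dy) >= h:
            raise ValueError(
                f"transform ({self.dx}, {self.dy}) out of bounds for raster {shape}"
            )


@dataclass(frozen=True)
class CalibrationModel:
    """Global linear radiometric correction: reference = slope*sensor + intercept."""

    slope: float
    intercept: float
    r_squared: float
    rmse_c: float
    valid_range_c: tuple[float, float] = (10.0, 50.0)
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.rmse_c < 0:
            raise ValueError("rmse must be >= 0")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(slope=1.0, intercept=0.0, r_squared=1.0, rmse_c=0.0, n_pairs=0)

    def invert(self) -> "CalibrationModel":
        """The algebraic inverse map (reference -> sensor scale)."""
        return CalibrationModel(
            slope=1.0 / self.slope,
            intercept=-self.intercept / self.slope,
            r_squared=self.r_squared,
            rmse_c=self.rmse_c,
            valid_range_c=self.valid_range_c,
            n_pairs=self.n_pairs,
        )


@dataclass(frozen=True)
class FSTEstimate:
    """Mean and maximum fruit surface temperature over the fruit blob, degC."""

    mean_fst: float
    max_fst: float
    n_pixels: int
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise NoFruitPixelsError("FST estimate requires > 0 fruit pixels")
        if self.max_fst < self.mean_fst - 1e-12:
            raise ValueError("max FST cannot be below mean FST")


def register_thermal(
    thermal: ThermalImage, transform: RegistrationTransform
) -> ThermalImage:
    """Translate the thermal raster into the RGB frame by (dx, dy).

    out[r, c] = in[r - dy, c - dx]; pixels with no source become NaN.
    No interpolation: the multiset of defined temperatures is preserved
    (minus those shifted out of frame).
    """
    transform.validate_for(thermal.shape)
    h, w = thermal.shape
    out = np.full((h, w), np.nan)
    dy, dx = transform.dy, transform.dx
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = thermal.temps[src_r, src_c]
    return ThermalImage(out)


def fit_calibration(
    sensor_c: np.ndarray | list,
    reference_c: np.ndarray | list,
    valid_range_c: tuple[float, float] = (10.0, 50.0),
) -> CalibrationModel:
    """Ordinary least squares fit reference = slope * sensor + intercept.

    Reports the coefficient of determination and the RMSE of the
    residuals in degC.  Requires at least 3 pairs and non-degenerate
    sensor values.
    """
    x = np.asarray(sensor_c, dtype=np.float64)
    y = np.asarray(reference_c, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sensor and reference must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("calibration requires at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("sensor values are collinear (zero variance); cannot fit")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rmse_c=rmse,
        valid_range_c=valid_range_c,
        n_pairs=int(x.size),
    )


def apply_calibration(thermal: ThermalImage, model: CalibrationModel) -> ThermalImage:
    """Correct a thermal raster per pixel with the fitted affine model.

    Missing pixels stay missing.  Temperatures outside the fitted range
    are still corrected — field FSTs exceed 50 degC exactly when sunburn
    matters — but a warning is emitted since the model is extrapolating.
    """
    t = thermal.temps
    lo, hi = model.valid_range_c
    defined = np.isfinite(t)
    if defined.any() and ((t[defined] < lo).any() or (t[defined] > hi).any()):
        warnings.warn(
            f"thermal values outside the calibration range {lo}-{hi} degC; "
            "correction is extrapolated",
            stacklevel=2,
        )
    return ThermalImage(np.where(defined, model.slope * t + model.intercept, np.nan))


def masked_fst(thermal: ThermalImage, mask: BinaryMask) -> FSTEstimate:
    """Mean and maximum temperature over masked, non-missing pixels."""
    if thermal.shape != mask.shape:
        raise ValueError("thermal raster and mask must share a shape")
    sel = mask.mask & np.isfinite(thermal.temps)
    n = int(sel.sum())
    if n == 0:
        raise NoFruitPixelsError("no fruit pixels: mask covers no defined temperatures")
    vals = thermal.temps[sel]
    return FSTEstimate(
        mean_fst=float(vals.mean()), max_fst=float(vals.max()), n_pixels=n
    )


@dataclass(frozen=True)
class CaptureAnalysis:
    """Full audit trail of a capture-pair FST analysis."""

    segmentation: SegmentationResult
    registered: ThermalImage
    calibrated: ThermalImage
    fst: FSTEstimate | None

    @property
    def fruit_detected(self) -> bool:
        return self.fst is not None


def capture_to_fst(
    pair: CapturePair,
    params: SegmentationParams | None = None,
    transform: RegistrationTransform | None = None,
    model: CalibrationModel | None = None,
) -> CaptureAnalysis:
    """Run the imagery FST chain on one capture pair.

    resize -> segment_fruit -> register_thermal -> apply_calibration ->
    masked_fst.  All intermediates are returned for audit.  A frame with
    no fruit yields fst=None rather than an error.
    """
    params = params or SegmentationParams()
    transform = transform or RegistrationTransform()
    model = model or CalibrationModel.identity()
    h, w = pair.thermal.shape
    rgb = resize_to_working(pair.rgb, h, w)
    seg = segment_fruit(rgb, params)
    reg = register_thermal(pair.thermal, transform)
    cal = apply_calibration(reg, model)
    if not seg.fruit_detected:
        return CaptureAnalysis(seg, reg, cal, None)
    try:
        fst = masked_fst(cal, seg.blob_mask)
        fst = FSTEstimate(fst.mean_fst, fst.max_fst, fst.n_pixels, calibrated=True)
    except NoFruitPixelsError:
        return CaptureAnalysis(seg, reg, cal, None)
    return CaptureAnalysis(seg, reg, cal, fst)
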
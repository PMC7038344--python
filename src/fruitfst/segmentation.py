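"""Chrominance-threshold fruit segmentation.

The largest apple in an RGB frame is isolated in four stages: a linear
RGB-to-YUV transform, a box threshold on the two chrominance channels
(luma is discarded — it mostly carries illumination), a square median
filter that removes speckle mis-classifications from branches and leaves,
and extraction of the maximum connected pixel domain as the fruit blob.

The transform uses the analog BT.601 YUV matrix on [0, 1] RGB, so U spans
[-0.436, 0.436] and V spans [-0.615, 0.615]; the default thresholds were
fitted on that scale from manually segmented mature apples:
U in (-0.07, 0.18), V in (-0.12, 0.58), strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import RGBImage

#: Analog BT.601 RGB -> YUV matrix (rows: Y, U, V; columns: R, G, B).
YUV_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.14713, -0.28886, 0.436],
        [0.615, -0.51499, -0.10001],
    ]
)


@dataclass(frozen=True)
class YUVImage:
    """Per-pixel luma (Y) and chrominance (U: red, V: blue projection)."""

    Y: np.ndarray
    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        if not (self.Y.shape == self.U.shape == self.V.shape):
            raise ValueError("Y, U, V must share a shape")


@dataclass(frozen=True)
class SegmentationParams:
    """Chrominance thresholds and cleanup settings.

    u1 < u2 and v1 < v2 bound the accepted chrominance box; blur_size is
    the (odd) side of the square median filter; connectivity selects 4- or
    8-neighbour blob extraction.
    """

    u1: float = -0.07
    u2: float = 0.18
    v1: float = -0.12
    v2: float = 0.58
    blur_size: int = 25
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (self.u1 < self.u2 and self.v1 < self.v2):
            raise ValueError("thresholds must satisfy u1 < u2 and v1 < v2")
        if self.blur_size < 1 or self.blur_size % 2 == 0:
            raise ValueError("blur_size must be odd and >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class BinaryMask:
    """A boolean H x W mask; area is the count of true pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            m = m.astype(bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class SegmentationResult:
    """The per-stage masks of the segmentation pipeline."""

    threshold_mask: BinaryMask
    blurred_mask: BinaryMask
    blob_mask: BinaryMask

    @property
    def stage_areas(self) -> dict[str, int]:
        return {
            "threshold": self.threshold_mask.area,
            "blurred": self.blurred_mask.area,
            "blob": self.blob_mask.area,
        }

    @property
    def fruit_detected(self) -> bool:
        return self.blob_mask.area > 0


def rgb_to_yuv(rgb: RGBImage) -> YUVImage:
    """Apply the linear RGB -> YUV transform per pixel.

    Y = 0.299 R + 0.587 G + 0.114 B
    U = -0.14713 R - 0.28886 G + 0.436 B
    V = 0.615 R - 0.51499 G - 0.10001 B
    """
    yuv = np.einsum("cd,hwd->hwc", YUV_MATRIX, rgb.pixels)
    return YUVImage(Y=yuv[..., 0], U=yuv[..., 1], V=yuv[..., 2])


def threshold_uv(yuv: YUVImage, params: SegmentationParams | None = None) -> BinaryMask:
    """Box-threshold the chrominance plane: keep pixels with
    u1 < U < u2 and v1 < V < v2 (strict inequalities); Y is ignored."""
    p = params or SegmentationParams()
    m = (
        (yuv.U > p.u1)
        & (yuv.U < p.u2)
        & (yuv.V > p.v1)
        & (yuv.V < p.v2)
    )
    return BinaryMask(m)


def median_filter_mask(mask: BinaryMask, blur_size: int = 25) -> BinaryMask:
    """Median-blur the mask (rendered {0, 255}) with a square kernel.

    Border handling is replication; the filtered image is re-binarized.
    On a binary field the median is a majority vote over the
    blur_size x blur_size neighbourhood, which deletes isolated speckles
    and fills pinholes.
    """
    if blur_size < 1 or blur_size % 2 == 0:
        raise ValueError("blur_size must be odd and >= 1")
    img = mask.mask.astype(np.uint8) * 255
    out = ndimage.median_filter(img, size=blur_size, mode="nearest")
    return BinaryMask(out >= 128)


def largest_component(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Keep only the maximum connected pixel domain; reject the rest.

    An empty mask yields an empty mask.  Area ties are broken toward the
    component whose first pixel comes earliest in row-major scan order
    (scipy labels components in order of first encounter, so the lowest
    label among the tied maxima is that component).
    """
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask.mask, structure=structure)
    if n == 0:
        return BinaryMask(np.zeros(mask.shape, dtype=bool))
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    return BinaryMask(labels == best)


def segment_fruit(
    rgb: RGBImage, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Run the full segmentation chain on a working-resolution RGB frame.

    Stages: rgb_to_yuv -> threshold_uv -> median_filter_mask ->
    largest_component.  A frame where no pixel passes the chrominance box
    yields an empty result (fruit_detected is False), not an error: a
    field tool must degrade gracefully.
    """
    p = params or SegmentationParams()
    thresh = threshold_uv(rgb_to_yuv(rgb), p)
    blurred = median_filter_mask(thresh, p.blur_size)
    blob = largest_component(blurred, p.connectivity)
    return SegmentationResult(thresh, blurred, blob)


def segmentation_accuracy(pred: BinaryMask, truth: BinaryMask) -> dict[str, float]:
    """Score a predicted mask against ground truth.

    Returns the area-ratio accuracy area(pred & truth) / area(truth) in
    percent (the intersection in the numerator keeps the score <= 100%
    and stops over-segmentation from being rewarded), plus IoU in percent
    as a supplementary metric.
    """
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a shape")
    if truth.area == 0:
        raise ValueError("truth mask is empty")
    inter = int((pred.mask & truth.mask).sum())
    union = int((pred.mask | truth.mask).sum())
    return {
        "accuracy_pct": 100.0 * inter / truth.area,
        "iou_pct": 100.0 * inter / union if union else 0.0,
    }


def stage_accuracy_summary(per_image: np.ndarray | list) -> dict[str, np.ndarray]:
    """Summarize per-image, per-stage accuracies (rows: images, cols: stages).

    Returns stage-wise means and sample standard deviations, each rounded
    to one decimal place as conventionally reported.
    """
    a = np.asarray(per_image, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected an images x stages table")
    return {
        "mean": np.round(a.mean(axis=0), 1),
        "sd": np.round(a.std(axis=0, ddof=1), 1),
    }
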
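"""Synthetic paired RGB/thermal orchard scenes with ground truth.

No public dataset of co-registered smartphone thermal-RGB apple captures
exists, so every pipeline stage is exercised against generated scenes
whose ground truth is known by construction: fruit-colored elliptical
blobs on foliage clutter, an optional specular glare spot, a correlated
surface-temperature field hottest at the fruit's upper neck, Gaussian
sensor noise, and a fixed thermal-vs-RGB translation offset injected
exactly as the registration step removes it.

Colors are synthesized in chrominance space and inverted to RGB: fruit
pixels sample U, V from a box strictly inside the default segmentation
thresholds, foliage samples U below the lower threshold (saturated
greens), and glare spots are bright bluish sky reflections whose V falls
below the lower V threshold — specular highlights reflect the illuminant,
not the fruit's body color, which is what makes glare break a pure
chrominance segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np

from .io_formats import CapturePair, RGBImage, ThermalImage, WORKING_SHAPE
from .weather_model import WeatherRecord

#: Inverse of the analog YUV transform (columns applied to [Y, U, V]).
_R_FROM_YUV = (1.0, 0.0, 1.13983)
_G_FROM_YUV = (1.0, -0.39465, -0.58060)
_B_FROM_YUV = (1.0, 2.03211, 0.0)


@dataclass(frozen=True)
class FruitSpec:
    """One elliptical fruit: center (row, col), semi-axes in pixels."""

    center: tuple[float, float]
    radius_row: float
    radius_col: float

    def __post_init__(self) -> None:
        if self.radius_row <= 0 or self.radius_col <= 0:
            raise ValueError("fruit radii must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic capture.

    Chrominance boxes are (u_lo, u_hi, v_lo, v_hi); the fruit box must sit
    inside the segmentation thresholds and the foliage box outside (left
    of the lower U threshold), which is validated at construction.
    Temperatures are degC; the fruit surface runs air_temp_c +
    fruit_excess_c at the upper-neck hot spot, decaying over the fruit.
    offset (dx, dy) is the translation the thermal frame lags the RGB
    frame by; registration with the same (dx, dy) removes it.
    """

    shape: tuple[int, int] = WORKING_SHAPE
    fruits: tuple[FruitSpec, ...] = (FruitSpec((60.0, 78.0), 48.0, 44.0),)
    fruit_uv_box: tuple[float, float, float, float] = (-0.02, 0.12, 0.10, 0.40)
    foliage_uv_box: tuple[float, float, float, float] = (-0.18, -0.11, -0.05, 0.25)
    clutter_density: float = 0.004   # clutter ellipses per pixel area
    speckle_fraction: float = 0.06   # fruit pinholes + foliage false positives
    glare_spots: int = 0
    glare_radius_px: float = 11.0
    air_temp_c: float = 25.0
    fruit_excess_c: float = 14.0
    neck_sharpness: float = 0.5      # hot-spot Gaussian sigma as fraction of radius
    thermal_noise_sigma_c: float = 0.3
    offset: tuple[int, int] = (40, 0)  # (dx, dy)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        for f in self.fruits:
            r, c = f.center
            if not (0 <= r - f.radius_row and r + f.radius_row < h):
                raise ValueError(f"fruit at {f.center} extends beyond frame rows")
            if not (0 <= c - f.radius_col and c + f.radius_col < w):
                raise ValueError(f"fruit at {f.center} extends beyond frame cols")
        if self.thermal_noise_sigma_c < 0:
            raise ValueError("thermal noise sigma must be >= 0")
        u_lo, u_hi, v_lo, v_hi = self.fruit_uv_box
        if not (-0.07 < u_lo < u_hi < 0.18 and -0.12 < v_lo < v_hi < 0.58):
            raise ValueError("fruit chrominance box must lie inside the segmentation thresholds")
        if self.foliage_uv_box[1] >= -0.07:
            raise ValueError("foliage chrominance must lie below the lower U threshold")


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for a generated scene."""

    fruit_masks: tuple[np.ndarray, ...]   # boolean, working grid, disjoint
    true_field: ThermalImage              # pre-offset, aligned to the RGB frame
    hottest_c: tuple[float, ...]          # per-fruit hottest-point temperature
    hottest_px: tuple[tuple[int, int], ...]

    @property
    def largest_fruit_mask(self) -> np.ndarray:
        areas = [m.sum() for m in self.fruit_masks]
        return self.fruit_masks[int(np.argmax(areas))]


def _yuv_to_rgb(y: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    r = _R_FROM_YUV[0] * y + _R_FROM_YUV[2] * v
    g = _G_FROM_YUV[0] * y + _G_FROM_YUV[1] * u + _G_FROM_YUV[2] * v
    b = _B_FROM_YUV[0] * y + _B_FROM_YUV[1] * u
    return np.stack([r, g, b], axis=-1)


def _ellipse_mask(shape, center, r_row, r_col) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / r_row) ** 2 + ((cc - center[1]) / r_col) ** 2 <= 1.0


def _sample_uv(rng, box, shape):
    u = rng.uniform(box[0], box[1], shape)
    v = rng.uniform(box[2], box[3], shape)
    return u, v


def generate_scene(spec: SceneSpec) -> tuple[CapturePair, SceneTruth]:
    """Render one capture pair plus ground truth, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    dx, dy = spec.offset

    # --- RGB frame: foliage base, clutter, fruits, speckle, glare -------
    u = np.empty((h, w))
    v = np.empty((h, w))
    y = rng.uniform(0.40, 0.60, (h, w))
    u[:], v[:] = _sample_uv(rng, spec.foliage_uv_box, (h, w))

    n_clutter = rng.poisson(spec.clutter_density * h * w)
    for _ in range(n_clutter):
        cr, cc = rng.uniform(0, h), rng.uniform(0, w)
        m = _ellipse_mask((h, w), (cr, cc), rng.uniform(3, 10), rng.uniform(3, 10))
        y[m] = rng.uniform(0.30, 0.65)
        u[m], v[m] = (x[m] for x in _sample_uv(rng, spec.foliage_uv_box, (h, w)))

    fruit_masks = []
    for f in spec.fruits:
        m = _ellipse_mask((h, w), f.center, f.radius_row, f.radius_col)
        for prev in fruit_masks:
            m &= ~prev
        fruit_masks.append(m)
        fu, fv = _sample_uv(rng, spec.fruit_uv_box, (h, w))
        u[m], v[m] = fu[m], fv[m]
        y[m] = rng.uniform(0.42, 0.50)

    # Speckle: pinholes inside fruit (foliage-colored) and brown-ish false
    # positives on foliage whose chrominance falls inside the thresholds —
    # the residual errors the median blur exists to remove.
    any_fruit = np.logical_or.reduce(fruit_masks) if fruit_masks else np.zeros((h, w), bool)
    speckle = rng.random((h, w)) < spec.speckle_fraction
    pin = speckle & any_fruit
    u[pin], v[pin] = (x[pin] for x in _sample_uv(rng, spec.foliage_uv_box, (h, w)))
    fp = speckle & ~any_fruit
    fpu, fpv = _sample_uv(rng, (0.00, 0.10, 0.05, 0.30), (h, w))
    u[fp], v[fp] = fpu[fp], fpv[fp]
    y[fp] = rng.uniform(0.35, 0.50)

    # Glare: bright bluish specular highlights on the largest fruit's upper
    # half; V below the lower threshold, so a chrominance segmenter drops
    # them (the "color illusion" failure mode).
    if spec.glare_spots and fruit_masks:
        big = spec.fruits[int(np.argmax([m.sum() for m in fruit_masks]))]
        for _ in range(spec.glare_spots):
            gr = big.center[0] - rng.uniform(0.2, 0.6) * big.radius_row
            gc = big.center[1] + rng.uniform(-0.4, 0.4) * big.radius_col
            g = _ellipse_mask((h, w), (gr, gc), spec.glare_radius_px, spec.glare_radius_px)
            u[g] = rng.uniform(0.04, 0.07)
            v[g] = rng.uniform(-0.20, -0.14)
            y[g] = rng.uniform(0.75, 0.82)

    rgb = RGBImage(np.clip(_yuv_to_rgb(y, u, v), 0.0, 1.0))

    # --- Thermal field on a padded canvas so the offset crop is defined --
    pr, pc = abs(dy), abs(dx)
    ch, cw = h + 2 * pr, w + 2 * pc
    canvas = spec.air_temp_c + 1.0 * np.sin(
        np.add.outer(np.arange(ch) / 17.0, np.arange(cw) / 23.0)
    )
    hottest_c, hottest_px = [], []
    for f, m in zip(spec.fruits, fruit_masks):
        neck = (f.center[0] - 0.6 * f.radius_row, f.center[1])
        rr, cc = np.mgrid[:ch, :cw]
        d2 = (rr - pr - neck[0]) ** 2 + (cc - pc - neck[1]) ** 2
        sigma = spec.neck_sharpness * max(f.radius_row, f.radius_col)
        profile = np.exp(-d2 / (2.0 * sigma**2))
        fruit_canvas = _ellipse_mask(
            (ch, cw), (f.center[0] + pr, f.center[1] + pc), f.radius_row, f.radius_col
        )
        fruit_t = spec.air_temp_c + spec.fruit_excess_c * profile
        canvas[fruit_canvas] = fruit_t[fruit_canvas]
        neck_px = (int(round(neck[0])), int(round(neck[1])))
        hottest_px.append(neck_px)
        hottest_c.append(float(canvas[neck_px[0] + pr, neck_px[1] + pc]))

    true_field = canvas[pr : pr + h, pc : pc + w].copy()
    # Observed raster lags the RGB frame by (dx, dy): registration with the
    # same transform shifts it back onto the true field.
    obs = canvas[pr + dy : pr + dy + h, pc + dx : pc + dx + w].copy()
    obs += rng.normal(0.0, spec.thermal_noise_sigma_c, obs.shape)

    ts = datetime(2020, 7, 15, 13, 0, tzinfo=timezone.utc)
    pair = CapturePair(
        rgb=rgb,
        thermal=ThermalImage(obs),
        imaging_distance_cm=20.0,
        latitude=46.6249,
        longitude=-120.6187,
        timestamp=ts,
        capture_id=f"scene-{spec.seed}",
    )
    truth = SceneTruth(
        fruit_masks=tuple(fruit_masks),
        true_field=ThermalImage(true_field),
        hottest_c=tuple(hottest_c),
        hottest_px=tuple(hottest_px),
    )
    return pair, truth


def clean_scene_spec(seed: int = 0, **overrides) -> SceneSpec:
    """A glare-free scene the segmentation chain should nail (>= 95%)."""
    return replace(SceneSpec(seed=seed), **overrides)


def hard_scene_spec(seed: int = 0, **overrides) -> SceneSpec:
    """The clean scene plus specular glare and denser clutter."""
    base = SceneSpec(
        seed=seed,
        glare_spots=2,
        glare_radius_px=11.0,
        clutter_density=0.008,
        speckle_fraction=0.06,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class DayProfile:
    """A diurnal weather profile for a clear summer day.

    Solar follows a half-sine between 06:00 and 18:00 local (solar noon at
    12:00); air temperature a sinusoid peaking mid-afternoon; dew point is
    constant (clamped below air); ground runs hotter than air in
    proportion to insolation; wind is Gaussian about a mean, floored at 0.
    """

    date: datetime = datetime(2020, 7, 15, tzinfo=timezone.utc)
    air_min_c: float = 16.0
    air_max_c: float = 32.0
    dew_point_c: float = 10.0
    solar_max_wm2: float = 900.0
    ground_excess_max_c: float = 20.0
    wind_mean_ms: float = 1.0
    wind_sigma_ms: float = 0.4
    cadence_min: int = 15

    def __post_init__(self) -> None:
        if self.dew_point_c > self.air_min_c:
            raise ValueError("dew point must not exceed the daily minimum air temperature")


def generate_weather_series(
    profile: DayProfile | None = None, seed: int = 0, hours: float = 24.0
) -> list[WeatherRecord]:
    """Generate a cadence-regular synthetic weather series (default 96 records/day)."""
    p = profile or DayProfile()
    rng = np.random.default_rng(seed)
    n = int(round(hours * 60 / p.cadence_min))
    # Records are 15-min *means*: instantaneous gusts average out, so the
    # wind series is a gust draw smoothed over a ~1 h window.
    gusts = rng.normal(p.wind_mean_ms, p.wind_sigma_ms, n + 4)
    kernel = np.ones(5) / 5.0
    wind_series = np.convolve(gusts, kernel, mode="valid")
    records = []
    for i in range(n):
        t = i * p.cadence_min / 60.0  # hours since local midnight
        solar = (
            p.solar_max_wm2 * np.sin(np.pi * (t - 6.0) / 12.0)
            if 6.0 < t < 18.0
            else 0.0
        )
        air = p.air_min_c + (p.air_max_c - p.air_min_c) * 0.5 * (
            1.0 + np.sin(2 * np.pi * (t - 9.0) / 24.0)
        )
        ground = air + p.ground_excess_max_c * solar / p.solar_max_wm2
        wind = max(0.0, float(wind_series[i]))
        records.append(
            WeatherRecord(
                timestamp=p.date + timedelta(hours=t),
                air_temp_c=round(float(air), 3),
                dew_point_c=min(p.dew_point_c, round(float(air), 3)),
                ground_temp_c=round(float(ground), 3),
                solar_rad_wm2=round(float(max(0.0, solar)), 2),
                wind_speed_ms=round(float(wind), 3),
            )
        )
    return records


def generate_calibration_set(
    true_slope: float = 1.05,
    true_intercept: float = -1.2,
    sigma_c: float = 0.5,
    n: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sensor/reference pairs emulating a water-bath calibration run.

    Reference temperatures are uniform on 10-50 degC; the sensor reading
    inverts the true line reference = slope * sensor + intercept and adds
    Gaussian noise of sigma_c degC.  Returns (sensor_c, reference_c).
    """
    if n < 3:
        raise ValueError("need at least 3 calibration pairs")
    rng = np.random.default_rng(seed)
    reference = rng.uniform(10.0, 50.0, n)
    sensor = (reference - true_intercept) / true_slope + rng.normal(0.0, sigma_c, n)
    return sensor, reference
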
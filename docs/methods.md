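# Methods

`fruitfst` estimates apple fruit surface temperature (FST) — the peel
temperature that governs sunburn onset — by two independent routes, and
maps the result to a physiological sunburn-risk class. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic test bed does and does not demonstrate.

## 1. Imagery route (FST_i)

### Color transform and chrominance thresholding

RGB frames are normalized to [0, 1] and mapped to analog BT.601 YUV:

```
Y =  0.299  R + 0.587  G + 0.114  B
U = -0.14713 R - 0.28886 G + 0.436 B      (red-projection chrominance)
V =  0.615  R - 0.51499 G - 0.10001 B     (blue-projection chrominance)
```

Luma is discarded — it mostly carries illumination, the component least
stable across field captures. A pixel is classified as fruit when its
chrominance falls strictly inside a box fitted on manually segmented
mature apples:

```
U1 < U < U2  and  V1 < V < V2,   defaults (-0.07, 0.18, -0.12, 0.58)
```

The inequalities are strict; the thresholds only make sense on the
analog YUV scale of [0, 1] inputs (hence the /255 normalization at
load). Note the box contains the chrominance origin, so neutral
(gray/white) pixels pass: it is *saturated* foliage green (U below
U1) that the rule rejects.

### Cleanup and blob extraction

Branches and stems can fall near apple chrominance, producing speckle.
A square median filter (default 25 px, applied to the mask rendered as
{0, 255} with replicated borders, then re-binarized) removes isolated
speckle and fills pinholes; on a binary field the median is a majority
vote. The paper of record for this kernel size states only "size = 25
pixels"; the square-kernel, replicated-border reading is this package's
choice. Finally the maximum connected pixel domain (8-connected by
default) is kept as the fruit blob; ties break toward the component
first reached in row-major scan order, which is deterministic.

Segmentation accuracy is scored as area(pred ∩ truth)/area(truth) in
percent. A raw area quotient could exceed 100 % and reward
over-segmentation, so the intersection form is used, with IoU reported
alongside.

### Registration, calibration, masked statistics

The RGB frame is resized to the 160×120 thermal resolution by exact
box-overlap area averaging (a 9× reduction from 1440×1080; area
averaging avoids aliasing and preserves the frame mean exactly). The
thermal raster is aligned by an integer translation — the two sensors
are eccentric in the housing, and the offset is about 40 px at the
typical 20 cm imaging distance. The offset scales with distance, so the
transform is stored per capture with (dx = 40, dy = 0) as the documented
default; no interpolation is performed and pixels shifted out of frame
become NaN, never silent zeros.

Radiometric correction is one global linear model, reference =
slope·sensor + intercept, fitted by ordinary least squares against a
trusted thermometer over 10–50 °C (the water-bath design; water
emissivity ≈ fruit emissivity). Temperatures outside that range are
still corrected, with a warning — field FSTs exceed 50 °C precisely when
sunburn matters. Mean and maximum FST are then plain arithmetic over
masked, defined pixels. The affine correction commutes with masking;
it is applied before masking here.

## 2. Weather route (FST_w)

A steady-state energy balance for a spherical fruit, per unit surface
area, driven by five station variables (air temperature, dew point,
solar radiation, wind speed, ground temperature):

```
residual(T_f) = a_s·S/4
              + ε_f σ (F_sky ε_sky T_air⁴ + F_gnd T_gnd⁴)
              - ε_f σ (F_sky + F_gnd) T_f⁴
              - (h_free + h_base u^b)(T_f - T_air)
              - g_et (e_sat(T_f) - e(T_dew))
```

The S/4 factor is the projected-to-surface area ratio of a sphere.
Sky emissivity ε_sky comes from a Brunt-type clear-sky correlation on
the vapour pressure at the dew point (Magnus form), overridable.
Internal heat storage is zero at steady state. Every term is decreasing
in T_f, so the residual is strictly decreasing and the root unique; it
is found by Brent's method on [T_air − 15, T_air + 40] °C with an x
tolerance of 10⁻⁶ °C (the residual slope is O(30 W m⁻² K⁻¹), so the
residual at the returned root is far below 0.01 W m⁻²). A bracket
without sign change is reported as a configuration error naming the
record.

Defaults, with units and rationale:

| parameter | default | unit | why |
|---|---|---|---|
| shortwave absorptivity a_s | 0.6 | – | mid-range for red apple peel |
| fruit emissivity ε_f | 0.95 | – | fruit ≈ water ≈ leaf emissivity |
| fruit diameter | 0.08 | m | mature dessert apple |
| h_base | 13 | W m⁻² K⁻¹ | sphere forced convection at 1 m s⁻¹ (Nu ≈ 2 + 0.6 Re^½ Pr^⅓, d = 8 cm) |
| wind exponent b | 0.5 | – | forced-convection Re^½ scaling |
| h_free | 5 | W m⁻² K⁻¹ | free-convection floor in calm air |
| g_et | 0 | W m⁻² kPa⁻¹ | waxy mature apples transpire little |
| F_sky, F_gnd | 0.5, 0.5 | – | fruit sees half sky, half canopy/ground |

These coefficients are exposed rather than asserted: the published
formulation this route emulates is cited but not printed in the source
study, so the contract here is the solver behavior — the equilibrium
limit (no sun, blackbody surroundings at air temperature → FST = T_air),
monotone response to solar and wind, and a midday excess inside the
5–18 °C band reported from orchard studies — not coefficient fidelity.
Under clear midday sun (S ≈ 900 W m⁻², low wind, hot orchard floor) the
defaults put FST 5–10 °C above air. Note FST can fall *below* air under
low sun and a clear (cold) sky; that radiative deficit is physical, so
the "FST ≥ T_air" property is only asserted for S ≥ 400 W m⁻² with
ground at or above air temperature.

Station lookup is a brute-force argmin of the haversine great-circle
distance (Earth radius 6371 km); ties break by list order.

## 3. Risk classification

Sunburn browning sets in at 46–49 °C and necrosis at 52 ± 1 °C.
Classification is monotone: necrosis at FST ≥ 52 °C (central value; the
±1 is surfaced as a configurable uncertainty band, not a class),
browning at 46 ≤ FST < 52 °C — the unnamed (49, 52) interval is folded
into browning, the conservative call for a grower-alerting tool — and
none below, with the headroom to the next threshold reported.
Photo-oxidative sunburn needs light-exposure history, not FST alone,
and is out of scope. In batch reports, risk is assessed on the larger
of the imagery *maximum* and the weather estimate: the blob mean
systematically underestimates the hottest point (the upper neck), while
the blob maximum tracks contact-probe measurements.

## 4. Synthetic test bed

No deposited thermal-RGB capture set exists, so scenes are generated
with known truth at the 120×160 working grid:

- **Fruit**: elliptical blobs whose chrominance is sampled from a box
  strictly inside the segmentation thresholds and inverted to RGB (the
  segmentation contract depends only on chrominance structure, not on
  reflectance physics). The default single fruit spans ~35 % of the
  frame, consistent with a 20 cm close-up.
- **Foliage**: saturated greens (U ≤ −0.11) with clutter ellipses, plus
  a speckle fraction: pinholes inside the fruit and brown-ish false
  positives outside whose chrominance lands inside the box — the
  residual errors the median blur exists to remove, and the reason the
  blur stage *raises* accuracy on clean scenes despite eroding the blob
  boundary by under a pixel.
- **Glare** (hard preset): bright bluish specular highlights on the
  fruit's upper half, with V pushed below the lower threshold. Specular
  highlights reflect the illuminant (sky), not the body color; the V
  threshold therefore rejects them, punching holes in the mask and
  reproducing the documented glare failure mode. Pure white would pass
  the thresholds (the box contains the origin), so a white-glare model
  could not degrade segmentation.
- **Thermal field**: air temperature plus a smooth background ripple;
  inside each fruit a Gaussian hot spot centred on the upper neck
  (hottest point = air + excess, default 25 + 14 °C), with spatial
  sigma of half the fruit radius. The observed raster is the true field
  translated by the configured (dx, dy) — exactly the transform the
  registration step removes — plus i.i.d. Gaussian sensor noise
  (σ = 0.3 °C default).
- **Weather series**: 15-min cadence; half-sine solar between 06:00 and
  18:00, sinusoidal air temperature peaking mid-afternoon, constant dew
  point clamped below air, ground excess proportional to insolation,
  and wind smoothed over ~1 h (records are 15-min means; instantaneous
  gust noise averages out).
- **Calibration sets**: reference uniform on 10–50 °C, sensor readings
  inverted through the true line plus Gaussian noise.

What passing these tests shows: the pipeline recovers known truth when
its own modelling assumptions hold (chrominance separability, pure
translation offset, affine sensor error, steady-state balance). What it
does not show: robustness to real canopy reflectance, mixed pixels at
fruit edges, distance-dependent parallax, emissivity variation, or
microclimate differences between a station kilometres away and the
orchard row — the main caveats a field deployment must budget for.

## 5. Numerical and degenerate-input choices

- Coordinates are 0-based (row, col), origin top-left, everywhere.
- Thermal CSV is a headerless comma-separated grid; values are °C and
  never rescaled on load; the sensor range [−20, 400] °C is enforced.
- Empty segmentation is a reported condition ("no fruit detected"),
  not an exception; batch rows with problems are flagged, never dropped.
- Calibration requires ≥ 3 pairs and non-degenerate sensor variance.
- Problem sizes in the test suite (oracle instances ≤ 64×64, 100-seed
  recovery studies, 1000-record solver sweeps, 3–10 scenes per preset)
  were chosen to give stable statistics at interactive runtimes.

## 6. Known limitations

Single-scalar translation registration (no parallax model, no sub-pixel
alignment); one global calibration line (no per-pixel non-uniformity
correction); a generic energy balance in place of the unpublished
coefficient set it emulates; no cultivar-specific thresholds; no
photo-oxidative pathway. Live weather-network polling is deliberately
behind a file-based provider — orchard connectivity is exactly the
constraint that motivates an offline tool.
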
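# Methods

## Scale construction and inversion

A reference chart is an ordered list of anchors (value, 8-bit RGB) with
strictly increasing values. The continuous scale interpolates each channel
**piecewise-linearly in raw RGB** between adjacent anchors and discretizes
at a value step Δv (default 0.1, matching the 0.1-division reading
precision the scale is meant to deliver); interpolated channels are rounded
to the nearest integer in [0, 255]. No gamma linearization or white-balance
normalization is applied: the scale operates on stored pixel values, and
quantitative reading presumes the chart and the sample were captured under
the same illumination (drift is measured, not corrected — see the
illumination tooling below).

Inversion is exhaustive nearest-neighbor over the discretized entries.
Two metrics are available:

- `rgb_euclidean` (default): Euclidean distance on raw 8-bit RGB;
- `cielab_de`: ΔE*ab (CIE76) after sRGB → L\*a\*b\* conversion (D65,
  via scikit-image), for perceptual work.

Numerical conventions, all deterministic:

- distance ties resolve to the **lower** value;
- a reading is **out-of-gamut** when the best distance exceeds 60
  RGB-Euclidean units (configurable) — roughly a quarter of the channel
  range, enough to reject non-chart colors such as bare white paper;
- because an indicator's color path can approach itself between distant
  values, a **second candidate** is reported (and the reading flagged
  ambiguous) when the best match among entries more than 5Δv away lies
  within 1.25× the best distance;
- `value_to_color` picks the nearest entry, ties toward the lower value,
  so `color_to_value(value_to_color(v)) = v` holds for every entry of a
  well-separated scale.

The bundled `default_ph_chart()` is a **synthetic** stand-in for a printed
universal-indicator chart (the red→orange→yellow→green→blue→violet
progression); no real chart is deposited with the package. Its anchor
colors were designed so that all 131 entries of the 0.1-step scale are
distinct, which makes the scale exactly invertible — the `scale_linearity`
diagnostic returns the identity line for it, whereas charts with flat or
self-approaching segments show plateaus and ambiguity flags.

## Sampling

Coordinates are 0-based (x = column, y = row), origin top-left; lines
include both endpoints. Line sampling walks the classic integer raster
(Bresenham; one sample per step along the major axis) because the measured
quantity is the stored pixel, not a resampled estimate. Widened lines
(odd width) average perpendicular offsets and round once at the end.
Region statistics (mean, min, max, range, mode, population std; per R, G,
B and the unweighted grayscale mean) are computed on the exact pixel set,
so a mask and its bounding rectangle over the same pixels agree; mode ties
resolve to the smallest value.

## Kymographs

A frame sequence must have uniform dimensions and an explicit, constant
fps; frame i is assigned time t₀ + i/fps, and t₀ may be negative so that
time zero can mark an event (solution contact) inside the recording.
Kymograph row i is bit-identical to the line sample of frame i — the
representation adds no interpolation or compression, so a 26 s, 30 fps
recording yields a 780-row image at 33.3 ms per row. Ordered directories
of zero-padded PNG frames are the canonical input; container video is
decoded best-effort and documented as non-bit-exact (decoder-dependent),
and variable-frame-rate input is rejected by construction (fps is a single
number).

## Front detection and kinetics

Per row, the detector computes the RGB-Euclidean distance of each pixel
from the unreacted background color (supplied, or estimated as the median
of pre-event rows), smooths it with a 3-px moving mean (edge-replicated),
takes the farthest position along the travel direction where the smoothed
profile still reaches the threshold, and refines the crossing by linear
interpolation between the bracketing pixels. Absence of a crossing is a
value (no front), not an error.

The default threshold is 30 RGB-Euclidean units — a permissive setting
that catches faint reactions. For *localizing* a high-contrast step edge,
the package's analyses use a threshold at **half the background↔reacted
contrast**: the half-maximum crossing of a symmetric smoothed step sits at
the true edge, making the locator unbiased (error bounded by the ±0.5 px
quantization of the rendered front). With the smoothing window of 3 this
keeps every detection within 1 px of the programmed ground truth on
noiseless synthetic videos.

Front positions convert to mm from a configurable origin pixel via
`mm_per_px` (no automatic ruler-tick detection). Average speed over a
window is the difference quotient of positions linearly interpolated
between detected rows; requesting a time outside the detected range is an
error rather than an extrapolation. Wicking kinetics are modeled as
x = k·√(t − t_onset) with t_onset pinned to the first detection; since the
model is linear in k, the least-squares solution is the closed form
k = Σ x√t′ / Σ t′ (clamped at 0), with RMSE reported in mm. Note the fit
assumes the front is still advancing: if the front saturates (reaches the
strip end, or the liquid is depleted), restrict the trace to the advancing
segment before fitting — the default 26 s synthetic scenario saturates at
~13 mm around t ≈ 14 s, which would bias a whole-trace fit low.

## Synthetic data

The generators emulate the study conditions rather than any deposited
footage (none exists):

- **Chart image**: uniform patches carrying the anchor colors bit-exactly,
  with a patch-coordinate table for sampling.
- **Reacted strip**: columns carry scale colors for a value span (default
  spans mirror realistic strip readings, e.g. 2.2–2.9), with the values
  snapped to the scale grid so the ground truth is exactly readable;
  optional i.i.d. Gaussian channel noise, clipped to [0, 255].
- **Wicking video**: defaults are the study's recording geometry — 26 s at
  30 fps with a 4 s pre-event roll (780 frames), 0.05 mm/px (a
  USB-microscope scale; 20 px per mm), a 260×21 px strip, and
  k = 11/√10 mm·s^−1/2 so the front covers 11 mm in the first 10 s
  (average speed 1.1 mm/s). Pixels behind x(t) carry the reacted color;
  the trailing 3 px form a darker reaction band (color × 0.85), rendering
  the darker chemistry-in-progress front; ahead is dry background.
- **Illumination video**: a static base image scaled per frame by
  multiplicative per-channel gains (brightness × RGB ramps). Hue drift as
  channel gains is deliberately simpler than chromatic adaptation: it is
  exactly invertible, so point traces can be checked against the
  programmed multiplier series to within rounding.

All generators are seeded (`numpy.random.default_rng`) and bit-reproducible;
every generated channel value stays in [0, 255].

What passing on these generators does **not** show: robustness to camera
gamma and demosaicing, JPEG/codec artifacts, specular glare, uneven
wetting, chart print variation, or indicator chemistry beyond the color
mapping. The synthetic chart is an emulation; readings on a real kit
require calibrating a chart file (JSON anchors) from a photographed chart.

## Problem sizes

The test suite and the acceptance script run the pipelines at the sizes
the methods are specified at — 131-entry scales, 780- and 2430-frame
sequences (26 s and 81 s at 30 fps), 220–260 px lines, 600-row kinetic
traces at σ = 0.5 px — chosen as the natural desk scale of the experiments;
the whole suite completes in seconds.
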
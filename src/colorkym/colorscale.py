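"""Continuous value↔color scales built from discrete reference charts.

A printed reference chart (for instance the 14-patch pH chart shipped with
litmus strips) gives one color per whole value.  Reading a reacted strip
against such a chart is accurate to the nearest whole number at best.  This
module interpolates the discrete anchors into a continuous scale — by
default 0.1-value steps, so a 1–14 pH chart becomes 131 reference colors —
and inverts observed colors back to fractional values by nearest-color
lookup under a configurable color-distance metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from skimage import color as _skcolor

from .errors import RangeError, ValidationError

RGB = Tuple[int, int, int]

#: Metrics accepted by :func:`color_to_value`.
METRICS = ("rgb_euclidean", "cielab_de")

#: Default color-distance above which a reading is flagged out-of-gamut
#: (RGB-Euclidean units; roughly a quarter of the channel range).
DEFAULT_GAMUT_THRESHOLD = 60.0

#: A second candidate within this ratio of the best distance, at a value
#: more than 5 scale steps away, marks the reading ambiguous.
DEFAULT_AMBIGUITY_RATIO = 1.25


def _check_rgb(c: Sequence[float], what: str = "color") -> RGB:
    if len(c) != 3:
        raise ValidationError(f"{what} must have 3 channels, got {len(c)}")
    r, g, b = (int(v) for v in c)
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValidationError(f"{what} channel {v} outside [0, 255]")
    return (r, g, b)


@dataclass(frozen=True)
class ReferenceChart:
    """Ordered calibration anchors: (assay value, printed RGB color).

    Parameters
    ----------
    anchors:
        Sequence of ``(value, (r, g, b))`` pairs with strictly increasing
        values and 8-bit channels.
    name:
        Free-text label (e.g. ``"pH 1-14"``).
    """

    anchors: Tuple[Tuple[float, RGB], ...]
    name: str = ""

    def __post_init__(self) -> None:
        anchors = tuple(
            (float(v), _check_rgb(c, f"anchor {v!r} color")) for v, c in self.anchors
        )
        if len(anchors) < 2:
            raise ValidationError("a chart needs at least 2 anchors")
        values = [v for v, _ in anchors]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValidationError("anchor values must be strictly increasing")
        object.__setattr__(self, "anchors", anchors)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for v, _ in self.anchors], dtype=float)

    @property
    def colors(self) -> np.ndarray:
        return np.array([c for _, c in self.anchors], dtype=np.uint8)

    @property
    def vmin(self) -> float:
        return self.anchors[0][0]

    @property
    def vmax(self) -> float:
        return self.anchors[-1][0]


@dataclass
class ContinuousScale:
    """Discretized interpolated color scale.

    ``values[i]`` runs from the chart minimum to maximum in ``step``
    increments; ``colors[i]`` is the 8-bit RGB of that value on the
    piecewise-linear color path through the anchors.
    """

    step: float
    values: np.ndarray
    colors: np.ndarray  # (n, 3) uint8
    source: ReferenceChart
    _lab: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def vmin(self) -> float:
        return float(self.values[0])

    @property
    def vmax(self) -> float:
        return float(self.values[-1])

    @property
    def entries(self) -> list[tuple[float, RGB]]:
        return [
            (float(v), tuple(int(x) for x in c))
            for v, c in zip(self.values, self.colors)
        ]

    @property
    def grayscale(self) -> np.ndarray:
        """Unweighted per-entry mean of R, G, B (the chart's gray curve)."""
        return self.colors.astype(float).mean(axis=1)

    def lab(self) -> np.ndarray:
        """CIE L*a*b* coordinates of the scale colors (sRGB, D65), cached."""
        if self._lab is None:
            self._lab = _skcolor.rgb2lab(self.colors[np.newaxis, :, :] / 255.0)[0]
        return self._lab


@dataclass(frozen=True)
class ValueReading:
    """One inverted color reading.

    ``value`` is reported at scale-step precision; ``distance`` is the
    metric distance of the best match.  ``ambiguous`` is set when the color
    path nearly revisits itself at a distant value, or when the query is
    out-of-gamut (farther from every scale color than the gamut threshold).
    """

    value: float
    distance: float
    ambiguous: bool = False
    out_of_gamut: bool = False
    second_candidate: Optional[Tuple[float, float]] = None


def build_continuous_scale(chart: ReferenceChart, step: float = 0.1) -> ContinuousScale:
    """Interpolate a discrete chart into a continuous scale.

    Interpolation is piecewise-linear per channel in 8-bit RGB between
    adjacent anchors; interpolated channels are rounded to the nearest
    integer.  ``step`` must evenly divide the chart's value range.
    """
    if step <= 0:
        raise ValidationError(f"step must be positive, got {step}")
    span = chart.vmax - chart.vmin
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, n_steps):
        raise ValidationError(
            f"step {step} does not divide the value range [{chart.vmin}, {chart.vmax}]"
        )
    n = int(round(n_steps)) + 1
    values = np.round(chart.vmin + step * np.arange(n), 10)
    values[-1] = chart.vmax  # guard against accumulation error
    channels = [
        np.interp(values, chart.values, chart.colors[:, ch].astype(float))
        for ch in range(3)
    ]
    colors = np.clip(np.rint(np.stack(channels, axis=1)), 0, 255).astype(np.uint8)
    return ContinuousScale(step=float(step), values=values, colors=colors, source=chart)


def color_distance(a: Sequence[float], b: Sequence[float], metric: str = "rgb_euclidean") -> float:
    """Scalar dissimilarity between two 8-bit RGB colors under ``metric``."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    pa = np.asarray(a, dtype=float)
    pb = np.asarray(b, dtype=float)
    if metric == "cielab_de":
        pa, pb = _skcolor.rgb2lab(np.stack([pa, pb])[np.newaxis] / 255.0)[0]
    return float(np.sqrt(((pa - pb) ** 2).sum()))


def scale_distances(
    scale: ContinuousScale, colors: np.ndarray, metric: str = "rgb_euclidean"
) -> np.ndarray:
    """Distance of each query color to every scale entry.

    Parameters
    ----------
    colors:
        Array of shape ``(..., 3)``, 8-bit RGB.
    metric:
        ``"rgb_euclidean"`` — Euclidean distance in raw RGB;
        ``"cielab_de"`` — ΔE*ab (CIE76) after sRGB→Lab conversion (D65).

    Returns
    -------
    Array of shape ``(..., n_entries)``.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    q = np.asarray(colors, dtype=float)
    if metric == "rgb_euclidean":
        ref = scale.colors.astype(float)
        diff = q[..., np.newaxis, :] - ref
    else:
        q_lab = _skcolor.rgb2lab(q[np.newaxis, ...] / 255.0)[0]
        diff = q_lab[..., np.newaxis, :] - scale.lab()
    return np.sqrt((diff * diff).sum(axis=-1))


def invert_colors(
    scale: ContinuousScale,
    colors: np.ndarray,
    metric: str = "rgb_euclidean",
    gamut_threshold: float = DEFAULT_GAMUT_THRESHOLD,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
):
    """Vectorized nearest-entry inversion of many colors at once.

    Returns ``(values, distances, ambiguous, out_of_gamut, second)`` where
    ``second`` is an ``(..., 2)`` array of (value, distance) of the best
    non-adjacent candidate (NaN where none exists).  Ties in distance
    resolve to the lower value.
    """
    if len(scale) == 0:
        raise ValidationError("empty scale")
    dist = scale_distances(scale, colors, metric)
    best_idx = dist.argmin(axis=-1)  # argmin takes the first (lowest value) on ties
    best_val = scale.values[best_idx]
    best_dist = np.take_along_axis(dist, best_idx[..., np.newaxis], axis=-1)[..., 0]

    # best candidate among entries > 5 steps away in value
    far = (
        np.abs(scale.values - best_val[..., np.newaxis]) > 5 * scale.step + 1e-9
    )
    dist_far = np.where(far, dist, np.inf)
    second_idx = dist_far.argmin(axis=-1)
    second_dist = np.take_along_axis(dist_far, second_idx[..., np.newaxis], axis=-1)[
        ..., 0
    ]
    second_val = np.where(np.isfinite(second_dist), scale.values[second_idx], np.nan)

    out_of_gamut = best_dist > gamut_threshold
    ambiguous = out_of_gamut | (
        np.isfinite(second_dist) & (second_dist <= ambiguity_ratio * best_dist)
    )
    second = np.stack(
        [second_val, np.where(np.isfinite(second_dist), second_dist, np.nan)], axis=-1
    )
    return best_val, best_dist, ambiguous, out_of_gamut, second


def color_to_value(
    scale: ContinuousScale,
    color: Sequence[int],
    metric: str = "rgb_euclidean",
    gamut_threshold: float = DEFAULT_GAMUT_THRESHOLD,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
) -> ValueReading:
    """Invert one observed color to an assay value.

    The scale entry minimizing the metric distance wins; equal distances
    resolve to the lower value.  The reading carries the match distance, an
    out-of-gamut flag, and — when the color path nearly revisits itself —
    a second candidate at a distant value.
    """
    rgb = _check_rgb(color, "query color")
    val, d, amb, oog, second = invert_colors(
        scale, np.array(rgb, dtype=float), metric, gamut_threshold, ambiguity_ratio
    )
    sec = None
    if np.isfinite(second[0]) and bool(amb) and not bool(oog):
        sec = (round(float(second[0]), 10), float(second[1]))
    return ValueReading(
        value=round(float(val), 10),
        distance=float(d),
        ambiguous=bool(amb),
        out_of_gamut=bool(oog),
        second_candidate=sec,
    )


def value_to_color(scale: ContinuousScale, value: float) -> RGB:
    """Color of the scale entry nearest ``value`` (tie → lower value)."""
    if not scale.vmin - 1e-9 <= value <= scale.vmax + 1e-9:
        raise RangeError(
            f"value {value} outside scale range [{scale.vmin}, {scale.vmax}]"
        )
    frac = (value - scale.vmin) / scale.step
    idx = int(np.ceil(frac - 0.5 - 1e-9))
    idx = min(max(idx, 0), len(scale) - 1)
    return tuple(int(c) for c in scale.colors[idx])


def scale_linearity(
    scale: ContinuousScale, metric: str = "rgb_euclidean"
) -> list[tuple[float, float]]:
    """Self-consistency diagnostic: re-read every entry's own color.

    Returns ``(input value, recovered value)`` per entry.  A perfectly
    invertible scale gives the identity line; flat segments (anchors that
    share a color) show up as plateaus.
    """
    vals, _, _, _, _ = invert_colors(scale, scale.colors.astype(float), metric)
    return [
        (round(float(v), 10), round(float(r), 10))
        for v, r in zip(scale.values, vals)
    ]
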
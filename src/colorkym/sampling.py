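"""Point, line, and area colorimetric sampling from still images.

Images are ``(height, width, 3)`` uint8 arrays; coordinates are 0-based
``(x=column, y=row)`` with the origin at top-left.  Every pixel is treated
as an independent colorimetric probe: a VGA frame is 307,200 of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from skimage.draw import line as _bresenham

from .colorscale import ContinuousScale, ValueReading, invert_colors
from .errors import RangeError, ValidationError

RasterImage = np.ndarray  # (H, W, 3) uint8
Region = Union[Tuple[int, int, int, int], np.ndarray]  # (x, y, w, h) or bool mask


def as_rgb_image(arr: np.ndarray) -> RasterImage:
    """Coerce an array to (H, W, 3) uint8 RGB; drops alpha, promotes gray."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[2] not in (3, 4):
        raise ValidationError(f"expected (H, W, 3) image, got shape {a.shape}")
    if a.shape[2] == 4:
        a = a[:, :, :3]
    if a.dtype != np.uint8:
        a = np.clip(np.rint(a.astype(float)), 0, 255).astype(np.uint8)
    return np.ascontiguousarray(a)


def pixel_probe_count(img: RasterImage) -> int:
    """Number of per-pixel colorimetric probes an image exposes (H × W)."""
    return int(img.shape[0]) * int(img.shape[1])


@dataclass(frozen=True)
class LineSpec:
    """Inclusive pixel line from (x0, y0) to (x1, y1), optionally widened.

    ``width`` (odd, default 1) averages perpendicular to the line.
    """

    x0: int
    y0: int
    x1: int
    y1: int
    width: int = 1

    def __post_init__(self) -> None:
        if self.width < 1 or self.width % 2 == 0:
            raise ValidationError(f"line width must be an odd integer ≥ 1, got {self.width}")

    @property
    def n_samples(self) -> int:
        return max(abs(self.x1 - self.x0), abs(self.y1 - self.y0)) + 1


@dataclass(frozen=True)
class ChannelStats:
    mean: float
    min: float
    max: float
    range: float
    mode: float
    std: float


@dataclass(frozen=True)
class RegionStats:
    """Per-channel summary statistics of a sampled pixel set.

    Channels are R, G, B plus the unweighted grayscale average.  ``std`` is
    the population standard deviation; ``mode`` is the most frequent value
    (ties resolve to the smallest).
    """

    channels: dict = field(default_factory=dict)  # name -> ChannelStats
    n: int = 0

    def __getitem__(self, name: str) -> ChannelStats:
        return self.channels[name]


def _check_point(img: RasterImage, x: int, y: int) -> None:
    h, w = img.shape[:2]
    if not (0 <= x < w and 0 <= y < h):
        raise RangeError(f"point ({x}, {y}) outside {w}×{h} image")


def sample_point(img: RasterImage, x: int, y: int) -> Tuple[int, int, int]:
    """Stored RGB value at pixel (x, y)."""
    _check_point(img, x, y)
    return tuple(int(c) for c in img[y, x])


def sample_line(img: RasterImage, line: LineSpec) -> np.ndarray:
    """RGB samples along an integer-raster line, endpoints inclusive.

    One sample per step along the major axis (Bresenham traversal, no
    sub-pixel interpolation).  For ``width > 1`` each sample is the rounded
    mean over the perpendicular width, clipped to the image bounds.
    """
    _check_point(img, line.x0, line.y0)
    _check_point(img, line.x1, line.y1)
    rr, cc = _bresenham(line.y0, line.x0, line.y1, line.x1)
    if line.width == 1:
        return img[rr, cc].copy()

    dx, dy = line.x1 - line.x0, line.y1 - line.y0
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        px, py = 0.0, 1.0  # degenerate line: widen vertically
    else:
        px, py = -dy / norm, dx / norm
    h, w = img.shape[:2]
    half = line.width // 2
    acc = np.zeros((len(rr), 3), dtype=float)
    for k in range(-half, half + 1):
        r = np.clip(rr + int(round(k * py)), 0, h - 1)
        c = np.clip(cc + int(round(k * px)), 0, w - 1)
        acc += img[r, c].astype(float)
    return np.clip(np.rint(acc / line.width), 0, 255).astype(np.uint8)


def _region_pixels(img: RasterImage, region: Region) -> np.ndarray:
    """Flatten a rectangle (x, y, w, h) or boolean mask to an (n, 3) array."""
    h, w = img.shape[:2]
    if isinstance(region, np.ndarray):
        if region.dtype != bool or region.shape != img.shape[:2]:
            raise ValidationError("mask must be a boolean array matching the image shape")
        pix = img[region]
    else:
        x, y, rw, rh = (int(v) for v in region)
        if rw < 1 or rh < 1:
            raise ValidationError(f"empty region {region}")
        if x < 0 or y < 0 or x + rw > w or y + rh > h:
            raise RangeError(f"region {region} outside {w}×{h} image")
        pix = img[y : y + rh, x : x + rw].reshape(-1, 3)
    if len(pix) == 0:
        raise ValidationError("region selects no pixels")
    return pix


def _mode(values: np.ndarray) -> float:
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[counts.argmax()])  # argmax → first → smallest value on ties


def region_stats(img: RasterImage, region: Region) -> RegionStats:
    """Summary statistics (mean/min/max/range/mode/std) of a sampled area.

    Computed per channel and on the grayscale average; std is population
    (divide by n).
    """
    pix = _region_pixels(img, region).astype(float)
    series = {
        "R": pix[:, 0],
        "G": pix[:, 1],
        "B": pix[:, 2],
        "gray": pix.mean(axis=1),
    }
    channels = {}
    for name, v in series.items():
        lo, hi = float(v.min()), float(v.max())
        channels[name] = ChannelStats(
            mean=float(v.mean()),
            min=lo,
            max=hi,
            range=hi - lo,
            mode=_mode(v),
            std=float(v.std()),  # population
        )
    return RegionStats(channels=channels, n=len(pix))


def read_values(
    img: RasterImage,
    region: Region,
    scale: ContinuousScale,
    metric: str = "rgb_euclidean",
    **kwargs,
) -> tuple[list[ValueReading], Optional[Tuple[float, float]]]:
    """Invert every pixel of a region to assay values.

    Returns the per-pixel readings and the span (min, max) over unambiguous
    readings, or ``None`` when every pixel is ambiguous/out-of-gamut.
    """
    pix = _region_pixels(img, region)
    vals, dists, amb, oog, second = invert_colors(scale, pix, metric, **kwargs)
    readings = []
    for i in range(len(pix)):
        sec = None
        if amb[i] and not oog[i] and np.isfinite(second[i, 0]):
            sec = (round(float(second[i, 0]), 10), float(second[i, 1]))
        readings.append(
            ValueReading(
                value=round(float(vals[i]), 10),
                distance=float(dists[i]),
                ambiguous=bool(amb[i]),
                out_of_gamut=bool(oog[i]),
                second_candidate=sec,
            )
        )
    good = vals[~amb]
    span = (round(float(good.min()), 10), round(float(good.max()), 10)) if len(good) else None
    return readings, span
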
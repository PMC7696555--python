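"""Synthetic charts, strips, and videos with known ground truth.

Real litmus-strip photographs depend on the printer, camera, and lighting,
so none ship with the package.  Instead this module generates the study
objects from first principles: a printed-style reference chart, reacted
strips carrying a known value gradient, wicking videos whose front follows
x(t) = k·√(t − t_onset) with a darker reaction band, and videos of a static
scene under programmed illumination drift.  Every generator is seeded and
returns its ground truth, so detection and fitting can be validated
end-to-end without any deposited footage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .colorscale import (
    RGB,
    ContinuousScale,
    ReferenceChart,
    value_to_color,
)
from .errors import RangeError, ValidationError
from .kinetics import FrontTrace
from .kymograph import FrameSequence, frame_count
from .sampling import RasterImage

#: Synthetic stand-in for a printed universal-indicator pH chart (1–14).
#: Colors run through the familiar red → orange → yellow → green → blue →
#: violet progression of universal indicator paper; they are an emulation,
#: not a measurement of any particular commercial kit.
_SYNTHETIC_PH_ANCHORS: Tuple[Tuple[float, RGB], ...] = (
    (1.0, (210, 16, 52)),
    (2.0, (226, 58, 46)),
    (3.0, (238, 104, 40)),
    (4.0, (246, 148, 38)),
    (5.0, (250, 190, 46)),
    (6.0, (240, 220, 70)),
    (7.0, (180, 210, 90)),
    (8.0, (120, 190, 100)),
    (9.0, (70, 165, 120)),
    (10.0, (40, 135, 140)),
    (11.0, (30, 100, 150)),
    (12.0, (36, 70, 146)),
    (13.0, (52, 46, 130)),
    (14.0, (72, 30, 104)),
)

#: Dry (unreacted) indicator-paper color used by the video generators.
DEFAULT_BACKGROUND: RGB = (235, 224, 200)

#: Reacted-region color for acidic test solutions (litmus red).
DEFAULT_REACTED: RGB = (196, 80, 60)


def default_ph_chart() -> ReferenceChart:
    """Synthetic 14-anchor pH reference chart (values 1–14).

    A stand-in emulating a printed universal-indicator chart; anchor colors
    are chosen so the interpolated 0.1-step scale is exactly invertible
    (all 131 entry colors distinct).
    """
    return ReferenceChart(anchors=_SYNTHETIC_PH_ANCHORS, name="synthetic pH 1-14")


def make_chart_image(
    chart: ReferenceChart, patch_size: Tuple[int, int] = (40, 40)
) -> Tuple[RasterImage, pd.DataFrame]:
    """Render a chart as a row of uniform color patches.

    Returns the image and a patch table (columns ``value, x, y, w, h``)
    giving each anchor's patch rectangle for sampling.  Patch pixels equal
    the anchor colors bit-exactly.
    """
    pw, ph = (int(v) for v in patch_size)
    if pw < 1 or ph < 1:
        raise ValidationError(f"patch size must be ≥ 1 px, got {patch_size}")
    n = len(chart.anchors)
    img = np.zeros((ph, pw * n, 3), dtype=np.uint8)
    rows = []
    for i, (value, color) in enumerate(chart.anchors):
        img[:, i * pw : (i + 1) * pw] = color
        rows.append({"value": value, "x": i * pw, "y": 0, "w": pw, "h": ph})
    return img, pd.DataFrame(rows)


GradientShape = Union[str, Callable[[np.ndarray], np.ndarray]]


def make_reacted_strip(
    scale: ContinuousScale,
    span: Tuple[float, float],
    length_px: int = 160,
    width_px: int = 24,
    gradient: GradientShape = "linear",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Tuple[RasterImage, np.ndarray]:
    """Strip whose columns carry scale colors for values along ``span``.

    The value at column j follows the gradient shape from span[0] to
    span[1]; each column's value snaps to the nearest scale entry, whose
    color fills the column.  Optional i.i.d. Gaussian channel noise is
    added and clipped to [0, 255].  Returns the image and the per-column
    ground-truth values (post-snap).
    """
    lo, hi = min(span), max(span)
    if lo < scale.vmin - 1e-9 or hi > scale.vmax + 1e-9:
        raise RangeError(f"span {span} outside scale range [{scale.vmin}, {scale.vmax}]")
    if length_px < 1 or width_px < 1:
        raise ValidationError("strip dimensions must be ≥ 1 px")
    u = np.zeros(1) if length_px == 1 else np.arange(length_px) / (length_px - 1)
    if callable(gradient):
        g = np.asarray(gradient(u), dtype=float)
    elif gradient == "linear":
        g = u
    elif gradient == "smoothstep":
        g = u * u * (3 - 2 * u)
    else:
        raise ValidationError(f"unknown gradient shape {gradient!r}")
    values = span[0] + (span[1] - span[0]) * g

    # snap to the scale grid so the ground truth is exactly readable
    idx = np.clip(np.rint((values - scale.vmin) / scale.step).astype(int), 0, len(scale) - 1)
    truth = scale.values[idx]
    img = np.repeat(scale.colors[idx][np.newaxis, :, :], width_px, axis=0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = img.astype(float) + rng.normal(0.0, noise_sigma, img.shape)
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return img, truth


@dataclass(frozen=True)
class DiffusionScenario:
    """Parameters of a synthetic wicking video.

    The front position follows x(t) = k·√(t − t_onset) (in mm from the
    strip's left edge); pixels behind the front carry the reacted color,
    the trailing 3 px of the reacted region form a darker reaction band
    (color × darkening), and pixels ahead of the front stay background.
    """

    k: float = 11.0 / np.sqrt(10.0)  # mm·s^-1/2: front at 11 mm after 10 s
    t_onset: float = 0.0  # seconds
    duration: float = 26.0  # seconds of video
    fps: float = 30.0
    t0_offset: float = -4.0  # pre-event roll before solution contact
    mm_per_px: float = 0.05  # 20 px per mm (USB-microscope working distance)
    length_px: int = 260
    width_px: int = 21
    background: RGB = DEFAULT_BACKGROUND
    reacted_color: RGB = DEFAULT_REACTED
    darkening: float = 0.85  # front-band color multiplier
    noise_sigma: float = 0.0  # Gaussian channel noise, 8-bit units
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k, self.duration, self.fps, self.mm_per_px) <= 0 or min(
            self.length_px, self.width_px
        ) < 1:
            raise ValidationError("all physical scenario quantities must be positive")
        if not 0.0 <= self.darkening <= 1.0:
            raise ValidationError(f"darkening factor must be in [0, 1], got {self.darkening}")


FRONT_BAND_PX = 3


def make_diffusion_video(sc: DiffusionScenario) -> Tuple[FrameSequence, FrontTrace]:
    """Render a wicking video and its ground-truth front trace.

    Frame i (time t = t0_offset + i/fps) shows the reacted region up to
    x(t) = k·√(t − t_onset), a 3-px darker band trailing the front, and
    background beyond; Gaussian noise per the scenario seed.  The returned
    trace gives the exact front position per frame in px and mm (NaN
    before onset).
    """
    n = frame_count(sc.duration, sc.fps)
    times = sc.t0_offset + np.arange(n) / sc.fps
    k_px = sc.k / sc.mm_per_px
    band_color = np.clip(
        np.rint(np.asarray(sc.reacted_color, dtype=float) * sc.darkening), 0, 255
    ).astype(np.uint8)

    frames = np.empty((n, sc.width_px, sc.length_px, 3), dtype=np.uint8)
    frames[:] = np.asarray(sc.background, dtype=np.uint8)
    truth_px = np.full(n, np.nan)
    for i, t in enumerate(times):
        if t < sc.t_onset:
            continue
        front = min(k_px * np.sqrt(t - sc.t_onset), sc.length_px - 1.0)
        truth_px[i] = front
        last = int(np.floor(front))
        frames[i, :, : last + 1] = sc.reacted_color
        frames[i, :, max(last - FRONT_BAND_PX + 1, 0) : last + 1] = band_color
    if sc.noise_sigma > 0:
        rng = np.random.default_rng(sc.seed)
        noisy = frames.astype(float) + rng.normal(0.0, sc.noise_sigma, frames.shape)
        frames = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    detected = ~np.isnan(truth_px)
    truth = FrontTrace(
        times=times,
        positions_px=truth_px,
        positions_mm=truth_px * sc.mm_per_px,
        detected=detected,
        mm_per_px=sc.mm_per_px,
        origin_px=0.0,
    )
    return FrameSequence(frames=frames, fps=sc.fps, t0_offset=sc.t0_offset), truth


@dataclass(frozen=True)
class IlluminationProgram:
    """Linear ramps of brightness and per-channel (hue) gains over a video.

    Frame i's multiplier is ``brightness_i × rgb_gains_i`` per channel,
    each interpolated linearly from the start to the end value.  Hue drift
    is modeled as channel-wise gains — enough to reproduce the apparent
    color shift of a chart under colored lighting, and exactly invertible.
    """

    duration: float
    fps: float
    brightness: Tuple[float, float] = (1.0, 1.0)
    rgb_gains: Tuple[Tuple[float, float, float], Tuple[float, float, float]] = (
        (1.0, 1.0, 1.0),
        (1.0, 1.0, 1.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fps <= 0:
            raise ValidationError("duration and fps must be positive")
        if min(self.brightness) <= 0 or min(min(g) for g in self.rgb_gains) <= 0:
            raise ValidationError("multipliers must be positive")

    def multipliers(self) -> np.ndarray:
        """(n_frames, 3) per-channel multiplier series."""
        n = frame_count(self.duration, self.fps)
        u = np.zeros(1) if n == 1 else np.arange(n) / (n - 1)
        bright = self.brightness[0] + (self.brightness[1] - self.brightness[0]) * u
        g0 = np.asarray(self.rgb_gains[0], dtype=float)
        g1 = np.asarray(self.rgb_gains[1], dtype=float)
        gains = g0 + (g1 - g0) * u[:, np.newaxis]
        return bright[:, np.newaxis] * gains


def make_illumination_video(
    base: RasterImage, prog: IlluminationProgram
) -> Tuple[FrameSequence, np.ndarray]:
    """Video of a static scene under the programmed illumination drift.

    Each frame is ``clip(round(base × multiplier))``; returns the sequence
    and the ground-truth (n_frames, 3) multiplier series.
    """
    m = prog.multipliers()
    base_f = np.asarray(base, dtype=float)
    frames = np.clip(
        np.rint(base_f[np.newaxis, :, :, :] * m[:, np.newaxis, np.newaxis, :]), 0, 255
    ).astype(np.uint8)
    return FrameSequence(frames=frames, fps=prog.fps, t0_offset=0.0), m
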
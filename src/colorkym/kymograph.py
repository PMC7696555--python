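"""Video as an x–y–t colorimetric data cube.

A video is a stack of frames at a fixed frame rate; sampling the same line
from every frame and stacking the profiles row-by-row yields a kymograph
(time cross-section image): x = position along the line, y = time.  A 30 fps
recording gives 33.3 ms per row.  Single points sampled across frames give
per-channel time traces, e.g. for tracing illumination drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .colorscale import ContinuousScale, invert_colors
from .errors import RangeError, ValidationError
from .sampling import LineSpec, RasterImage, as_rgb_image, sample_line


@dataclass
class FrameSequence:
    """Uniformly sized frames at a constant frame rate.

    ``t0_offset`` is the time (seconds) assigned to frame 0; it may be
    negative to place the time origin at an event (e.g. solution contact)
    that happens mid-recording.
    """

    frames: np.ndarray  # (T, H, W, 3) uint8
    fps: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[0] < 1 or f.shape[3] != 3:
            raise ValidationError(f"expected (T, H, W, 3) frame stack, got {f.shape}")
        self.frames = f.astype(np.uint8, copy=False)

    @classmethod
    def from_frames(
        cls, frames: Iterable[np.ndarray], fps: float, t0_offset: float = 0.0
    ) -> "FrameSequence":
        imgs = [as_rgb_image(f) for f in frames]
        if not imgs:
            raise ValidationError("frame sequence is empty")
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise ValidationError(f"frames have mixed dimensions: {sorted(shapes)}")
        return cls(frames=np.stack(imgs), fps=fps, t0_offset=t0_offset)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time of each frame: t0_offset + i / fps."""
        return self.t0_offset + np.arange(len(self)) / self.fps


@dataclass
class Kymograph:
    """Time cross-section image: row i is the line profile of frame i."""

    rows: np.ndarray  # (T, L, 3) uint8
    line: LineSpec
    fps: float
    row_times: np.ndarray  # seconds

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def row_length(self) -> int:
        return self.rows.shape[1]

    def as_image(self) -> RasterImage:
        return self.rows


@dataclass
class TimeTrace:
    """Per-frame channel intensities at one pixel."""

    times: np.ndarray
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    @property
    def gray(self) -> np.ndarray:
        """Unweighted average of the three channels."""
        return (
            self.r.astype(float) + self.g.astype(float) + self.b.astype(float)
        ) / 3.0

    def __len__(self) -> int:
        return len(self.times)


def frame_count(duration: float, fps: float) -> int:
    """Frames in a recording: round(duration × fps); 81 s at 30 fps → 2430."""
    if duration < 0 or fps <= 0:
        raise ValidationError(f"need duration ≥ 0 and fps > 0, got {duration}, {fps}")
    exact = duration * fps
    n = int(round(exact))
    if abs(exact - n) > 1e-9 * max(1.0, exact):
        warnings.warn(
            f"duration × fps = {exact} is not integral; rounding to {n}",
            stacklevel=2,
        )
    return n


def row_time_resolution(fps: float) -> float:
    """Kymograph row spacing in milliseconds (1000/fps), to 0.1 ms."""
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    return round(1000.0 / fps, 1)


def build_kymograph(seq: FrameSequence, line: LineSpec) -> Kymograph:
    """Stack one line sample per frame into a time cross-section image.

    Row i is bit-identical to ``sample_line(frame i, line)`` — no
    resampling or compression in the internal representation.
    """
    rows = np.stack([sample_line(f, line) for f in seq.frames])
    return Kymograph(rows=rows, line=line, fps=seq.fps, row_times=seq.times)


def point_trace(seq: FrameSequence, x: int, y: int) -> TimeTrace:
    """Channel intensities of pixel (x, y) over all frames."""
    t, h, w = seq.frames.shape[:3]
    if not (0 <= x < w and 0 <= y < h):
        raise RangeError(f"point ({x}, {y}) outside {w}×{h} frames")
    series = seq.frames[:, y, x, :]
    return TimeTrace(
        times=seq.times, r=series[:, 0].copy(), g=series[:, 1].copy(), b=series[:, 2].copy()
    )


@dataclass
class ValueMap:
    """Element-wise inversion of a kymograph: assay value at (time, position)."""

    values: np.ndarray  # (T, L) float
    distances: np.ndarray
    ambiguous: np.ndarray  # bool
    out_of_gamut: np.ndarray  # bool
    row_times: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.values.shape


def kymograph_to_values(
    kym: Kymograph, scale: ContinuousScale, metric: str = "rgb_euclidean", **kwargs
) -> ValueMap:
    """Translate every kymograph pixel into an assay value.

    Ambiguous/out-of-gamut pixels are flagged, never fatal; the output
    preserves the kymograph's shape.
    """
    vals, dists, amb, oog, _ = invert_colors(scale, kym.rows, metric, **kwargs)
    return ValueMap(
        values=vals,
        distances=dists,
        ambiguous=amb,
        out_of_gamut=oog,
        row_times=kym.row_times,
    )
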
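"""Reaction/diffusion-front detection and √t wicking kinetics.

When a liquid drop wicks along an indicator strip, the wetted/reacted
region is separated from the dry background by a moving front.  In a
kymograph each row is one instant, so the front appears as a curve; this
module locates it per row (sub-pixel, by thresholding the color distance
from the unreacted background), converts positions to millimetres, and
fits the capillary-wicking law x = k·√(t − t_onset), which formalizes the
parabolic slowing of the distance–time curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .kymograph import Kymograph
from .sampling import RasterImage

#: Default color-distance threshold (RGB-Euclidean) separating reacted
#: pixels from background — suited to the high-contrast litmus transition.
DEFAULT_FRONT_THRESHOLD = 30.0

#: Moving-mean window applied to the per-pixel distance profile.
SMOOTH_WINDOW = 3


@dataclass
class FrontTrace:
    """Per-row front position versus time.

    ``positions_px`` is NaN where no front was detected; ``positions_mm``
    is measured from ``origin_px`` with the scale ``mm_per_px``.
    """

    times: np.ndarray
    positions_px: np.ndarray  # sub-pixel, NaN when undetected
    positions_mm: np.ndarray
    detected: np.ndarray  # bool
    mm_per_px: float = 1.0
    origin_px: float = 0.0

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())


@dataclass(frozen=True)
class DiffusionFit:
    """Least-squares fit of front kinetics x = k·√(t − t_onset)."""

    k: float  # mm·s^-1/2
    t_onset: float  # seconds
    rmse: float  # mm
    n_points: int


def _distance_profile(row: np.ndarray, background: Sequence[int]) -> np.ndarray:
    d = row.astype(float) - np.asarray(background, dtype=float)
    dist = np.sqrt((d * d).sum(axis=-1))
    padded = np.pad(dist, SMOOTH_WINDOW // 2, mode="edge")
    kernel = np.ones(SMOOTH_WINDOW) / SMOOTH_WINDOW
    return np.convolve(padded, kernel, mode="valid")


def detect_front_row(
    row: np.ndarray,
    background: Sequence[int],
    threshold: float = DEFAULT_FRONT_THRESHOLD,
    direction: str = "increasing",
) -> Optional[float]:
    """Sub-pixel front position in one line profile, or None.

    The per-pixel RGB-Euclidean distance from ``background`` is smoothed
    with a 3-pixel moving mean; the front is the farthest position along
    the travel ``direction`` where the smoothed distance still reaches
    ``threshold``, refined by linearly interpolating the threshold crossing
    between the bracketing pixels.
    """
    row = np.asarray(row)
    if row.ndim != 2 or row.shape[0] < 2:
        raise ValidationError("row must be an (L ≥ 2, 3) RGB sequence")
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    if direction not in ("increasing", "decreasing"):
        raise ValidationError(f"direction must be increasing|decreasing, got {direction!r}")

    s = _distance_profile(row, background)
    above = s >= threshold
    if not above.any():
        return None
    if direction == "increasing":
        i = int(np.nonzero(above)[0][-1])
        if i == len(s) - 1:
            return float(i)
        return i + (s[i] - threshold) / (s[i] - s[i + 1])
    i = int(np.nonzero(above)[0][0])
    if i == 0:
        return 0.0
    return i - (s[i] - threshold) / (s[i] - s[i - 1])


def estimate_background(kym: Kymograph) -> np.ndarray:
    """Median color of rows recorded before time 0 (the pre-event roll)."""
    pre = kym.rows[kym.row_times < 0]
    if pre.size == 0:
        raise ValidationError(
            "no pre-event rows (times < 0) to estimate the background from; "
            "supply a background color explicitly"
        )
    return np.median(pre.reshape(-1, 3), axis=0)


def trace_front(
    kym: Kymograph,
    background: Optional[Sequence[int]] = None,
    threshold: float = DEFAULT_FRONT_THRESHOLD,
    direction: str = "increasing",
    mm_per_px: float = 1.0,
    origin_px: float = 0.0,
) -> FrontTrace:
    """Detect the front in every kymograph row.

    ``background`` defaults to the median color of pre-event rows
    (row times < 0).  Positions are reported both in pixels along the line
    and in millimetres from ``origin_px``.
    """
    if mm_per_px <= 0:
        raise ValidationError(f"mm_per_px must be positive, got {mm_per_px}")
    bg = np.asarray(background, dtype=float) if background is not None else estimate_background(kym)
    pos = np.full(kym.n_rows, np.nan)
    for i in range(kym.n_rows):
        p = detect_front_row(kym.rows[i], bg, threshold, direction)
        if p is not None:
            pos[i] = p
    detected = ~np.isnan(pos)
    return FrontTrace(
        times=kym.row_times.copy(),
        positions_px=pos,
        positions_mm=(pos - origin_px) * mm_per_px,
        detected=detected,
        mm_per_px=mm_per_px,
        origin_px=origin_px,
    )


def _position_at(trace: FrontTrace, t: float) -> float:
    """Front position (mm) at time t, interpolated between detected rows."""
    td = trace.times[trace.detected]
    xd = trace.positions_mm[trace.detected]
    if len(td) == 0:
        raise ValidationError("trace has no detections")
    if not td[0] - 1e-9 <= t <= td[-1] + 1e-9:
        raise ValidationError(
            f"time {t} s outside detected range [{td[0]}, {td[-1]}] s"
        )
    return float(np.interp(t, td, xd))


def average_speed(trace: FrontTrace, t_start: float, t_end: float) -> float:
    """Mean front speed (mm/s) between two times.

    Computed as (x(t_end) − x(t_start)) / (t_end − t_start) with positions
    linearly interpolated between neighboring detected rows.
    """
    if t_end <= t_start:
        raise ValidationError(f"need t_end > t_start, got [{t_start}, {t_end}]")
    return (_position_at(trace, t_end) - _position_at(trace, t_start)) / (t_end - t_start)


def fit_sqrt_kinetics(trace: FrontTrace) -> DiffusionFit:
    """Fit x = k·√(t − t_onset) to the detected front positions.

    ``t_onset`` is the time of the first detection; ``k`` has the closed
    form k = Σ x·√t′ / Σ t′ (t′ = t − t_onset), the least-squares solution
    for a model linear in k.  Positions are in mm from the trace origin.
    """
    det = trace.detected
    if det.sum() < 2:
        raise ValidationError("need at least 2 detected rows to fit kinetics")
    t_onset = float(trace.times[det][0])
    tp = trace.times[det] - t_onset
    x = trace.positions_mm[det]
    denom = tp.sum()
    k = float(x @ np.sqrt(tp) / denom) if denom > 0 else 0.0
    k = max(k, 0.0)
    resid = x - k * np.sqrt(tp)
    return DiffusionFit(
        k=k,
        t_onset=t_onset,
        rmse=float(np.sqrt((resid**2).mean())),
        n_points=int(det.sum()),
    )


def annotate_front(
    kym: Kymograph, trace: FrontTrace, highlight: Tuple[int, int, int] = (255, 0, 0)
) -> RasterImage:
    """Copy of the kymograph with each detected front pixel recolored.

    Row i gets its pixel at column round(position_i) set to ``highlight``;
    undetected rows are untouched.
    """
    if len(trace) != kym.n_rows:
        raise ValidationError("trace length does not match kymograph rows")
    out = kym.rows.copy()
    cols = np.rint(trace.positions_px[trace.detected]).astype(int)
    cols = np.clip(cols, 0, kym.row_length - 1)
    out[np.nonzero(trace.detected)[0], cols] = np.asarray(highlight, dtype=np.uint8)
    return out
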
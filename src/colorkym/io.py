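"""Readers and writers: images, frame sequences, chart files, CSV tables.

Lossless PNG is the canonical interchange format for images and
kymographs, and an ordered directory of zero-padded PNG frames is the
bit-exact reference path for video.  Container video files are decoded on
a best-effort basis (pixel values then depend on the codec and decoder).
Tables go to CSV with documented headers; chart definitions and run
metadata are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorscale import ContinuousScale, ReferenceChart, ValueReading
from .errors import ValidationError
from .kinetics import DiffusionFit, FrontTrace
from .kymograph import FrameSequence, Kymograph, TimeTrace
from .sampling import RasterImage, RegionStats, as_rgb_image

PathLike = Union[str, Path]

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


def read_image(path: PathLike) -> RasterImage:
    """Read a still image as 8-bit RGB (alpha dropped, grayscale promoted)."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 — surface the filename
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return as_rgb_image(arr)


def write_image(path: PathLike, img: RasterImage) -> Path:
    """Write an RGB image losslessly (PNG recommended)."""
    path = Path(path)
    iio.imwrite(path, as_rgb_image(img))
    return path


def read_frames(
    source: PathLike, fps: float, t0_offset: float = 0.0
) -> FrameSequence:
    """Load a frame sequence from a directory of images or a video file.

    Directories are read in lexicographic order (zero-padded names keep
    that chronological) and are the bit-exact path; video containers are
    decoded best-effort and require an ffmpeg-capable imageio backend.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise ValidationError(f"no image frames found in directory {source}")
        return FrameSequence.from_frames(
            (read_image(p) for p in files), fps=fps, t0_offset=t0_offset
        )
    if not source.exists():
        raise FileNotFoundError(source)
    try:
        frames = [frame for frame in iio.imiter(source)]
    except Exception as exc:  # noqa: BLE001
        raise IOError(
            f"cannot decode video {source}: {exc}; "
            "a directory of PNG frames is the lossless alternative"
        ) from exc
    return FrameSequence.from_frames(frames, fps=fps, t0_offset=t0_offset)


def write_frames(directory: PathLike, seq: FrameSequence) -> Path:
    """Write a sequence as zero-padded PNG frames (frame_000000.png, …)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame)
    return directory


# -- chart definition files -------------------------------------------------

def read_chart(path: PathLike) -> Tuple[ReferenceChart, dict]:
    """Parse a JSON chart definition.

    Format: ``{"name": ..., "anchors": [{"value": v, "rgb": [r, g, b]},
    ...], "step": 0.1, "metric": "rgb_euclidean"}`` — ``step`` and
    ``metric`` are optional defaults returned in the second element.
    Duplicate anchor values are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    try:
        anchors = [(float(a["value"]), tuple(a["rgb"])) for a in doc["anchors"]]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed chart file {path}: {exc}") from exc
    values = [v for v, _ in anchors]
    if len(set(values)) != len(values):
        raise ValidationError(f"chart file {path} has duplicate anchor values")
    anchors.sort(key=lambda a: a[0])
    chart = ReferenceChart(anchors=tuple(anchors), name=doc.get("name", path.stem))
    defaults = {k: doc[k] for k in ("step", "metric") if k in doc}
    return chart, defaults


def write_chart(path: PathLike, chart: ReferenceChart, **defaults) -> Path:
    path = Path(path)
    doc = {
        "name": chart.name,
        "anchors": [
            {"value": v, "rgb": [int(c) for c in rgb]} for v, rgb in chart.anchors
        ],
        **defaults,
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


# -- tabular writers --------------------------------------------------------

def scale_table(scale: ContinuousScale) -> pd.DataFrame:
    """Scale entries as a table: value, R, G, B, gray."""
    return pd.DataFrame(
        {
            "value": np.round(scale.values, 10),
            "R": scale.colors[:, 0],
            "G": scale.colors[:, 1],
            "B": scale.colors[:, 2],
            "gray": scale.grayscale,
        }
    )


def front_trace_table(trace: FrontTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": trace.times,
            "position_px": trace.positions_px,
            "position_mm": trace.positions_mm,
            "detected": trace.detected,
        }
    )


def time_trace_table(trace: TimeTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_s": trace.times, "R": trace.r, "G": trace.g, "B": trace.b, "gray": trace.gray}
    )


def readings_table(readings: Sequence[ValueReading]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": [r.value for r in readings],
            "distance": [r.distance for r in readings],
            "ambiguous": [r.ambiguous for r in readings],
            "out_of_gamut": [r.out_of_gamut for r in readings],
            "second_value": [
                r.second_candidate[0] if r.second_candidate else np.nan for r in readings
            ],
            "second_distance": [
                r.second_candidate[1] if r.second_candidate else np.nan for r in readings
            ],
        }
    )


def stats_table(stats: RegionStats) -> pd.DataFrame:
    rows = []
    for name, ch in stats.channels.items():
        rows.append(
            {
                "channel": name,
                "mean": ch.mean,
                "min": ch.min,
                "max": ch.max,
                "range": ch.range,
                "mode": ch.mode,
                "std": ch.std,
                "n": stats.n,
            }
        )
    return pd.DataFrame(rows)


def write_csv(path: PathLike, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def write_kymograph(path: PathLike, kym: Kymograph) -> Path:
    """Write the kymograph rows as a lossless PNG (x = position, y = time)."""
    return write_image(path, kym.rows)


def write_metadata(path: PathLike, config: dict) -> Path:
    """Persist the run configuration (seed included) as JSON."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    path.write_text(json.dumps(config, indent=2, default=_default))
    return path


def fit_summary(fit: DiffusionFit) -> dict:
    return {
        "k_mm_per_sqrt_s": fit.k,
        "t_onset_s": fit.t_onset,
        "rmse_mm": fit.rmse,
        "n_points": fit.n_points,
    }
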
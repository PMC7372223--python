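"""Reading and writing movies, truth sidecars and tidy result tables.

Movies are stored as multi-page 16-bit unsigned TIFF in TCYX plane order
(ImageJ hyperstack metadata), with a JSON sidecar of the same basename
carrying the physical calibration and the intensity quantisation scale.
Ground truth travels in a second ``.truth.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .containers import CellObservation, DivisionEvent, GroundTruth, MovieStack

_SCALE_KEY = "intensity_units_per_count"
FLOAT_FMT = "%.6g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def truth_sidecar(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".truth.json")


def write_movie(
    movie: MovieStack, path: str | Path, truth: Optional[GroundTruth] = None
) -> Path:
    """Write a stack as 16-bit TIFF (TCYX) plus JSON metadata sidecar.

    Intensities are quantised to the uint16 range; the scale is recorded
    in the sidecar so :func:`read_movie` restores the same values a second
    write/read cycle reproduces exactly.
    """
    path = Path(path)
    frames = np.asarray(movie.frames, dtype=np.float64)
    peak = float(frames.max())
    scale = peak / 60000.0 if peak > 0 else 1.0
    data = np.clip(np.round(frames / scale), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, imagej=True, metadata={"axes": "TCYX"})
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "channel_names": list(movie.channel_names),
        _SCALE_KEY: scale,
    }
    _sidecar(path).write_text(json.dumps(meta))
    if truth is not None:
        truth.to_json(truth_sidecar(path))
    return path


def read_movie(
    path: str | Path,
    pixel_size_um: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
    channel_names: Optional[Sequence[str]] = None,
) -> MovieStack:
    """Read a TIFF time-lapse stack, normalising plane order to TCYX.

    Metadata comes from the JSON sidecar when present; the keyword
    overrides win when given.  Accepts TCYX, TZCYX with a singleton Z,
    TYX (single channel) and YX (single frame, single channel) layouts.
    Raises an I/O error for unreadable files and an unsupported-format
    error for more than two channels.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes.upper()
            data = series.asarray()
    except Exception as exc:  # noqa: BLE001 - surface as I/O error
        raise IOError(f"could not read TIFF {path}: {exc}") from exc
    # normalise to TCYX
    order = axes
    if "Z" in order:
        zi = order.index("Z")
        if data.shape[zi] != 1:
            raise ValueError(f"unsupported axis Z with size {data.shape[zi]}")
        data = np.take(data, 0, axis=zi)
        order = order.replace("Z", "")
    if order == "YX":
        data = data[None, None]
    elif order == "TYX":
        data = data[:, None]
    elif order == "CYX":
        data = data[None]
    elif order == "TCYX":
        pass
    elif order == "CTYX":
        data = np.moveaxis(data, 1, 0)
    else:
        raise ValueError(f"unsupported TIFF axis order {axes!r}")
    if data.shape[1] > 2:
        raise ValueError(
            f"unsupported channel count {data.shape[1]} on axis C (at most 2)"
        )
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    scale = float(meta.get(_SCALE_KEY, 1.0))
    frames = data.astype(np.float32) * scale
    names = channel_names or meta.get("channel_names")
    if names is None:
        names = ("membrane", "dna")[: data.shape[1]]
    return MovieStack(
        frames=frames,
        pixel_size_um=pixel_size_um or float(meta.get("pixel_size_um", 0.1235)),
        frame_interval_s=frame_interval_s
        or float(meta.get("frame_interval_s", 120.0)),
        channel_names=tuple(names),
    )


def observations_to_frame(
    observations: Sequence[Sequence[CellObservation]],
) -> pd.DataFrame:
    """Flatten per-frame observation lists into a tidy table."""
    rows = []
    for per_frame in observations:
        for o in per_frame:
            rows.append(
                {
                    "frame": o.frame,
                    "label": o.label,
                    "centroid_row": o.centroid[0],
                    "centroid_col": o.centroid[1],
                    "area_px": o.area_px,
                    "area_um2": o.area_um2,
                    "major_len_px": o.major_len_px,
                    "minor_len_px": o.minor_len_px,
                    "orientation_rad": o.orientation_rad,
                    "furrow_width_px": o.furrow_width_px,
                    "n_nucleoids": len(o.nucleoids),
                }
            )
    return pd.DataFrame(rows)


def events_to_frame(events: Sequence[DivisionEvent]) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(events):
        rows.append(
            {
                "event_id": i,
                "parent_track": e.parent_track,
                "onset_frame": e.onset_frame,
                "separation_frame": e.separation_frame,
                "outcome": e.outcome,
                "ghost": e.ghost,
                "daughter_ratio": e.daughter_ratio,
                "division_time_s": e.division_time_s,
            }
        )
    return pd.DataFrame(rows)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
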
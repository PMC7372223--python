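"""In-memory containers shared across the pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: The three nucleoid-organisation classes scored during division: a single
#: diffuse DNA mass, two diffuse masses, and two compact well-defined masses.
DNA_STATES = ("single_diffuse", "two_diffuse", "compact_separated")


@dataclass
class MovieStack:
    """A time-lapse stack ordered (time, channel, row, column) with calibration.

    ``pixel_size_um`` defaults to 0.1235 µm/px (60x objective with 1.5x
    magnification on an sCMOS camera); ``frame_interval_s`` is the time
    between frames in seconds.
    """

    frames: np.ndarray
    pixel_size_um: float = 0.1235
    frame_interval_s: float = 120.0
    channel_names: Tuple[str, ...] = ("membrane", "dna")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4-D (T, C, H, W)")
        t, c, h, w = self.frames.shape
        if t < 1 or c not in (1, 2):
            raise ValueError("need T >= 1 and C in {1, 2}")
        if h < 32 or w < 32:
            raise ValueError("frame size must be at least 32 x 32")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.channel_names) != c:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, H, W) sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.frames[:, idx]


@dataclass
class CellTruth:
    """Simulator ground truth for one cell over its live frames."""

    cell_id: int
    first_frame: int
    centers: np.ndarray          # (n, 2) intrinsic (row, col), drift excluded
    length_px: np.ndarray        # (n,) current long-axis length
    furrow_width_px: np.ndarray  # (n,) current neck width (= short axis pre-onset)
    dna_state: List[str] = field(default_factory=list)

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.centers) - 1


@dataclass
class TruthEvent:
    """One division attempt as the simulator executed it."""

    parent_id: int
    onset_frame: int
    separation_frame: Optional[int]
    outcome: str                  # "success" | "failure"
    offset_frac: float            # signed plane offset as fraction of length
    daughter_ids: Tuple[int, ...] = ()
    ghost: bool = False

    def __post_init__(self) -> None:
        if self.outcome == "success" and self.separation_frame is not None:
            if not self.onset_frame < self.separation_frame:
                raise ValueError("onset must precede separation for a success")


@dataclass
class GroundTruth:
    """Per-cell, per-frame truth sidecar for a simulated movie."""

    cells: Dict[int, CellTruth]
    events: List[TruthEvent]
    drift: np.ndarray  # (T, 2) applied (dy, dx) per frame; row 0 is (0, 0)

    def __post_init__(self) -> None:
        self.drift = np.asarray(self.drift, dtype=float)
        if self.drift.ndim != 2 or self.drift.shape[1] != 2:
            raise ValueError("drift must be (T, 2)")
        if not np.allclose(self.drift[0], 0.0):
            raise ValueError("drift of frame 0 must be (0, 0)")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "drift": self.drift.tolist(),
            "events": [
                {
                    "parent_id": e.parent_id,
                    "onset_frame": e.onset_frame,
                    "separation_frame": e.separation_frame,
                    "outcome": e.outcome,
                    "offset_frac": e.offset_frac,
                    "daughter_ids": list(e.daughter_ids),
                    "ghost": e.ghost,
                }
                for e in self.events
            ],
            "cells": {
                str(cid): {
                    "first_frame": c.first_frame,
                    "centers": c.centers.tolist(),
                    "length_px": c.length_px.tolist(),
                    "furrow_width_px": c.furrow_width_px.tolist(),
                    "dna_state": c.dna_state,
                }
                for cid, c in self.cells.items()
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        cells = {
            int(cid): CellTruth(
                cell_id=int(cid),
                first_frame=c["first_frame"],
                centers=np.asarray(c["centers"], dtype=float),
                length_px=np.asarray(c["length_px"], dtype=float),
                furrow_width_px=np.asarray(c["furrow_width_px"], dtype=float),
                dna_state=list(c["dna_state"]),
            )
            for cid, c in obj["cells"].items()
        }
        events = [
            TruthEvent(
                parent_id=e["parent_id"],
                onset_frame=e["onset_frame"],
                separation_frame=e["separation_frame"],
                outcome=e["outcome"],
                offset_frac=e["offset_frac"],
                daughter_ids=tuple(e["daughter_ids"]),
                ghost=e["ghost"],
            )
            for e in obj["events"]
        ]
        return cls(cells=cells, events=events, drift=np.asarray(obj["drift"]))


@dataclass
class Nucleoid:
    """One segmented DNA mass inside a cell mask."""

    area_px: int
    solidity: float
    centroid: Tuple[float, float]


@dataclass
class CellObservation:
    """Measurements of one segmented cell in one frame.

    ``furrow_width_px`` is the minimum cross-width along the major axis
    within the central portion of the cell; it tracks the constriction and
    is the series the sigmoid is fitted to.  The moment-equivalent ellipse
    minor axis is recorded alongside for comparison.
    """

    frame: int
    label: int
    centroid: Tuple[float, float]
    area_px: int
    area_um2: float
    major_len_px: float
    minor_len_px: float
    orientation_rad: float
    furrow_width_px: float
    nucleoids: List[Nucleoid] = field(default_factory=list)
    dna_measured: bool = False
    # segmentation support carried for tracking; not serialised
    bbox: Tuple[int, int, int, int] = (0, 0, 0, 0)
    mask: Optional[np.ndarray] = None


@dataclass
class Track:
    """A linked sequence of per-frame observations of one cell."""

    track_id: int
    observations: List[CellObservation]
    parent_id: Optional[int] = None
    child_ids: List[int] = field(default_factory=list)
    merged_into: Optional[int] = None
    merge_frame: Optional[int] = None

    @property
    def frames(self) -> List[int]:
        return [o.frame for o in self.observations]

    @property
    def first_frame(self) -> int:
        return self.observations[0].frame

    @property
    def last_frame(self) -> int:
        return self.observations[-1].frame


@dataclass
class DivisionEvent:
    """A classified division attempt recovered from tracks."""

    parent_track: int
    onset_frame: int
    separation_frame: Optional[int]
    outcome: str                 # "success" | "failure"
    daughter_areas_px: Tuple[float, float] = (np.nan, np.nan)
    daughter_ratio: float = np.nan
    ghost: bool = False
    division_time_s: Optional[float] = None
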
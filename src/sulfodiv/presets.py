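"""Strain parameter presets for the synthetic movie generator.

Each :class:`StrainPreset` bundles the empirical magnitudes that distinguish
the wild-type-like background strain (MW001) from the two ESCRT-III deletion
mutants whose division phenotypes the pipeline quantifies:

* ``MW001`` — divisions succeed almost always (failure probability 1.5%)
  and the division plane sits near mid-cell (Gaussian offset, sd 3% of cell
  length).
* ``dCdvB1`` (ΔcdvB1) — constrictions occasionally halt and reverse, the
  nascent daughters fusing back into one cell; 16% of initiated divisions
  fail.  Plane placement stays symmetric.
* ``dCdvB2`` (ΔcdvB2) — divisions complete but the plane position is highly
  variable (uniform offset over a wide range of the cell length), producing
  strongly asymmetric daughters and, at extreme offsets, anucleate "ghost"
  fragments.

Only the 16% and 1–2% failure magnitudes are quantitative published values;
the offset breadths, ghost frequency and kinetic constants are declared,
configurable defaults chosen to reproduce the qualitative phenotypes.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator


class StrainPreset(BaseModel):
    """Parameter bundle describing one strain's division behaviour.

    Parameters
    ----------
    name
        Identifier used in outputs.
    p_fail
        Probability in [0, 1] that an initiated constriction halts and
        reverses (daughters fuse back together).
    offset_sd_frac
        Standard deviation of the division-plane offset, as a fraction of
        cell length, for ``offset_dist == "gaussian"``.
    offset_dist
        Shape of the plane-offset distribution.
    offset_range
        ``(lo, hi)`` bounds of |offset| as a fraction of cell length, for
        ``offset_dist == "uniform"``.
    p_ghost
        Probability that a successful division uses an extreme offset
        producing an anucleate fragment ("ghost cell").
    tau_s
        Logistic time constant of furrow closure, seconds.
    division_rate_per_h
        Expected divisions per cell per hour; sets the fraction of cells
        that attempt a division within a movie.
    dna_state_lead_s
        Mean time before furrow onset at which the nucleoid splits into two
        diffuse structures.
    """

    model_config = {"frozen": True}

    name: str
    p_fail: float = Field(ge=0.0, le=1.0)
    offset_sd_frac: float = Field(default=0.03, ge=0.0, lt=0.5)
    offset_dist: Literal["gaussian", "uniform"] = "gaussian"
    offset_range: Optional[Tuple[float, float]] = None
    p_ghost: float = Field(default=0.0, ge=0.0, le=1.0)
    tau_s: float = Field(default=90.0, gt=0.0)
    division_rate_per_h: float = Field(default=2.0, ge=0.0)
    dna_state_lead_s: float = Field(default=600.0, ge=0.0)

    @model_validator(mode="after")
    def _check_range(self) -> "StrainPreset":
        if self.offset_dist == "uniform":
            if self.offset_range is None:
                raise ValueError("uniform offset_dist requires offset_range")
            lo, hi = self.offset_range
            if not (0.0 <= lo < hi <= 0.5):
                raise ValueError("offset_range must satisfy 0 <= lo < hi <= 0.5")
        return self

    @property
    def effective_offset_sd(self) -> float:
        """Standard deviation of the plane-offset distribution actually drawn."""
        if self.offset_dist == "uniform":
            lo, hi = self.offset_range  # type: ignore[misc]
            return (hi - lo) / math.sqrt(12.0)
        return self.offset_sd_frac


MW001 = StrainPreset(
    name="MW001",
    p_fail=0.015,
    offset_sd_frac=0.03,
    offset_dist="gaussian",
    p_ghost=0.0,
)

DELTA_CDVB1 = StrainPreset(
    name="dCdvB1",
    p_fail=0.16,
    offset_sd_frac=0.03,
    offset_dist="gaussian",
    p_ghost=0.0,
)

DELTA_CDVB2 = StrainPreset(
    name="dCdvB2",
    p_fail=0.02,
    offset_sd_frac=0.03,
    offset_dist="uniform",
    offset_range=(0.05, 0.5),
    p_ghost=0.05,
)

PRESETS = {p.name: p for p in (MW001, DELTA_CDVB1, DELTA_CDVB2)}
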
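"""Forward model of dividing near-spherical cells imaged in time lapse.

The generator renders two-channel movies (membrane stain, DNA stain) of
fields of cells that constrict with logistic furrow kinetics and divide at a
strain-dependent plane offset, with a strain-dependent probability that an
initiated constriction halts and reverses (a division failure).  Every
stochastic choice is recorded in a :class:`~sulfodiv.containers.GroundTruth`
sidecar so downstream measurements can be validated against exact truth.

Geometry model
--------------
A cell is an ellipse (semi-axes ``a`` > ``b``).  Constriction multiplies the
local half-width profile by a Gaussian "waist" centred on the division
plane, so the neck width equals the prescribed logistic ``w(t)`` exactly:

    w(t) = w_end + (w_start - w_end) / (1 + exp((t - t0) / tau))

with ``w_start`` the unconstricted short-axis length and ``w_end = 0``.
Success events separate once the neck falls below 1.5 px: the daughters
are the parent's two lobes cut at the plane, the larger one receding
while the inherited waist relaxes as the newborns round up.  Failure
events follow the logistic down to 0.35 x ``w_start`` and then retrace it
in mirrored time until the cell is whole again.  The membrane channel
draws each outline as a ~2 px perimeter shell (the dye stains the
membrane); the DNA channel draws one or two Gaussian nucleoid blobs whose
spread shrinks at least two-fold when the nucleoids compact at onset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .containers import CellTruth, GroundTruth, MovieStack, TruthEvent
from .presets import StrainPreset

# rendering constants (arbitrary intensity units; membrane band peak = 1)
_EROSION_RADIUS = 2      # membrane band thickness, px
_yx = np.mgrid[-_EROSION_RADIUS:_EROSION_RADIUS + 1,
               -_EROSION_RADIUS:_EROSION_RADIUS + 1]
_EROSION_DISK = (_yx[0] ** 2 + _yx[1] ** 2) <= _EROSION_RADIUS**2
_WAIST_SIGMA_PX = 2.5    # axial width of the constriction waist, px
_SEP_WIDTH_PX = 1.5      # neck width at which daughters separate, px
_PHOTONS_PER_UNIT = 200  # Poisson shot-noise scale
_READ_NOISE_SD = 0.02    # Gaussian read noise, fraction of membrane peak
_DNA_FLUX = 60.0         # integrated intensity per nucleoid blob
_SIGMA_SINGLE = 3.0      # diffuse single nucleoid spread, px
_SIGMA_DIFFUSE = 2.6     # each of two diffuse nucleoids, px
_SIGMA_COMPACT = 1.2     # compacted nucleoid spread (>= 2x shrink), px
_SIGMA_NEWBORN = 1.6     # daughter-cell nucleoid spread, px

_ONSET_DEF_FRAC = 0.8    # truth onset: observable width below 0.8 x baseline
_FAIL_MIN_FRAC = 0.35    # failure events reverse once w reaches this fraction
# the rendered mask carries the two apposed membrane walls at the neck and
# a slight erosion of the outline at baseline; the truth onset is defined
# on this observable width so that truth and measurement describe the same
# quantity (calibrated on noiseless renders)
_NECK_WALL_PX = 2.3
_EDGE_EROSION_PX = 1.0


def _observable_width(w: float, w_start: float) -> float:
    """Mask-level furrow width corresponding to true neck width ``w``."""
    return min(w + _NECK_WALL_PX, w_start - _EDGE_EROSION_PX)


@dataclass
class _Division:
    t0: float
    tau: float
    outcome: str
    offset_frac: float       # signed, fraction of cell length
    ghost: bool
    lead_s: float
    onset_t: float = 0.0
    sep_t: float = math.inf
    daughter_ids: Tuple[int, int] = (-1, -1)
    # daughter geometry along the parent axis, filled at setup
    d_geom: Tuple[Tuple[float, float, float], ...] = ()


@dataclass
class _Cell:
    cell_id: int
    center: np.ndarray        # (row, col)
    a: float
    b: float
    theta: float
    division: Optional[_Division] = None


def _axis_unit(theta: float) -> np.ndarray:
    return np.array([math.cos(theta), math.sin(theta)])


def _logistic_width(t: float, w_start: float, t0: float, tau: float) -> float:
    return w_start / (1.0 + math.exp(min((t - t0) / tau, 500.0)))


def _fail_mirror_time(t0: float, tau: float) -> float:
    """Time at which a failing constriction reverses (w = _FAIL_MIN_FRAC)."""
    return t0 + tau * math.log((1.0 - _FAIL_MIN_FRAC) / _FAIL_MIN_FRAC)


def _width_at(t: float, cell: _Cell) -> float:
    """Truth neck width at time t, handling the failure reversal."""
    div = cell.division
    w_start = 2.0 * cell.b
    if div is None:
        return w_start
    if div.outcome == "failure":
        t_m = _fail_mirror_time(div.t0, div.tau)
        if t > t_m:
            t = 2.0 * t_m - t  # time-mirrored recovery
    return _logistic_width(t, w_start, div.t0, div.tau)


def _waist_sigmas(a: float, xp: float) -> Tuple[float, float]:
    """Axial waist widths on the two sides of the division plane.

    The constriction is local: on a short lobe the waist must not swallow
    the whole compartment, so its width is capped at a third of the lobe
    length (asymmetric divisions show a bulging small compartment, not a
    vanishing sliver).
    """
    sl = min(_WAIST_SIGMA_PX, max((xp + a) / 3.0, 0.4))
    sr = min(_WAIST_SIGMA_PX, max((a - xp) / 3.0, 0.4))
    return sl, sr


def _add_membrane(
    img: np.ndarray,
    cy: float,
    cx: float,
    a: float,
    b: float,
    theta: float,
    xp: Optional[float] = None,
    w: Optional[float] = None,
    amp: float = 1.0,
    cap_side: int = 0,
    axis_shift: float = 0.0,
    cleft_at: Optional[float] = None,
) -> None:
    """Draw a perimeter band for an ellipse, optionally waist-constricted
    to neck width ``w`` at axial coordinate ``xp``.

    With ``cap_side`` -1/+1 only the lobe on that side of the plane is
    drawn (smoothly capped at ``xp``), translated ``axis_shift`` px along
    the major axis away from the plane — the post-separation daughters.
    """
    h, wid = img.shape
    rad = a + 4.0 + abs(axis_shift)
    r0 = max(int(math.floor(cy - rad)), 0)
    r1 = min(int(math.ceil(cy + rad)) + 1, h)
    c0 = max(int(math.floor(cx - rad)), 0)
    c1 = min(int(math.ceil(cx + rad)) + 1, wid)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - cy
    dc = cc - cx
    ct, st = math.cos(theta), math.sin(theta)
    x = dr * ct + dc * st
    y = -dr * st + dc * ct
    x_lab = x
    if cap_side != 0:
        # lobe translated away from the plane: evaluate the parent shape
        # in the lobe's own (shifted) frame
        x = x - cap_side * axis_shift
    if xp is None or w is None:
        m = 1.0
    else:
        hp = b * math.sqrt(max(1.0 - (xp / a) ** 2, 1e-6))
        depth = max(0.0, 1.0 - w / (2.0 * hp))
        sl, sr = _waist_sigmas(a, xp)
        sig = np.where(x < xp, sl, sr)
        m = 1.0 - depth * np.exp(-((x - xp) ** 2) / (2.0 * sig**2))
        m = np.maximum(m, 0.02)
    beff = b * m
    rho = np.sqrt((x / a) ** 2 + (y / beff) ** 2)
    # soft filled indicator (anti-aliased edge ~1.4 px), then keep only a
    # perimeter shell ~2 px thick: the membrane dye marks the cell outline
    soft = np.clip((1.0 - rho) * beff / 0.7 + 0.5, 0.0, 1.0)
    if cap_side != 0 and xp is not None:
        # smooth cut at the division plane closes the lobe's new pole; the
        # inset compensates the mask border the new pole would add, but
        # must not consume a tiny fragment lobe
        lobe_len = (xp + a) if cap_side < 0 else (a - xp)
        inset = float(np.clip(0.2 + 1.4 * (lobe_len / a - 0.5), 0.2, 1.6))
        soft = soft / (1.0 + np.exp(-cap_side * (x - xp - cap_side * inset) / 0.35))
    inner = ndi.grey_erosion(soft, footprint=_EROSION_DISK)
    band = np.clip(soft - inner, 0.0, 1.0)
    if cleft_at is not None:
        # dark cleft at the abscission plane: the receding daughter's
        # membrane pulls back from the inter-daughter space
        band = band * (1.0 - np.exp(-((x_lab - cleft_at) ** 2) / (2.0 * 0.8**2)))
    img[r0:r1, c0:c1] += amp * band


def _add_blob(img: np.ndarray, cy: float, cx: float, sigma: float, flux: float) -> None:
    h, w = img.shape
    rad = 4.0 * sigma
    r0 = max(int(math.floor(cy - rad)), 0)
    r1 = min(int(math.ceil(cy + rad)) + 1, h)
    c0 = max(int(math.floor(cx - rad)), 0)
    c1 = min(int(math.ceil(cx + rad)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    amp = flux / (2.0 * math.pi * sigma**2)
    img[r0:r1, c0:c1] += amp * np.exp(
        -((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sigma**2)
    )


def _half_width_profile(
    x: np.ndarray, a: float, b: float, xp: float, w: float
) -> np.ndarray:
    """Local half-width H(x) of the waist-constricted ellipse."""
    hp = b * math.sqrt(max(1.0 - (xp / a) ** 2, 1e-6))
    depth = max(0.0, 1.0 - w / (2.0 * hp))
    sl, sr = _waist_sigmas(a, xp)
    sig = np.where(x < xp, sl, sr)
    m = 1.0 - depth * np.exp(-((x - xp) ** 2) / (2.0 * sig**2))
    inside = np.clip(1.0 - (x / a) ** 2, 0.0, None)
    return b * m * np.sqrt(inside)


def _setup_daughters(cell: _Cell, next_id: int) -> int:
    """Compute daughter (lobe) geometry for a success event.

    Each daughter is one lobe of the constricted parent, cut at the
    division plane, so daughters occupy the parent's footprint at
    separation and their areas sum to the dumbbell area (conservation
    across the separation frame).  Per side the lobe area, axial centroid,
    length and maximum width are obtained by integrating the half-width
    profile.  Returns the next free cell id.
    """
    div = cell.division
    assert div is not None
    a, b = cell.a, cell.b
    xp = div.offset_frac * 2.0 * a
    xs = np.linspace(-a, a, 400)
    hh = _half_width_profile(xs, a, b, xp, _SEP_WIDTH_PX)
    dx = xs[1] - xs[0]
    geom = []
    for side in (-1, +1):
        sel = xs < xp if side < 0 else xs >= xp
        area = float(np.sum(2.0 * hh[sel]) * dx)
        if area > 0:
            cx = float(np.sum(xs[sel] * 2.0 * hh[sel]) * dx / area)
        else:
            cx = xp + side * 0.5
        length = float((xp + a) if side < 0 else (a - xp))
        width = float(2.0 * hh[sel].max()) if sel.any() else 0.0
        geom.append((area, cx, length, width))
    div.d_geom = tuple(geom)
    div.daughter_ids = (next_id, next_id + 1)
    return next_id + 2


def _lobe_shift(t: float, sep_t: float) -> float:
    """Total axial parting of the daughters, post-separation.

    The parting is divided between the lobes in inverse proportion to
    their areas, so a tiny fragment stays at the parent pole while the
    large daughter recoils from the plane."""
    return min(3.0 + 0.04 * max(t - sep_t, 0.0), 6.0)


def _lobe_relax_width(t: float, sep_t: float, w_max: float) -> float:
    """Waist width used when rendering separated lobes.

    Newborn daughters round up after abscission: the inherited waist
    profile relaxes at 0.08 px/s until the lobe is a plain ellipse piece.
    """
    return min(2.2 + 0.08 * max(t - sep_t, 0.0), w_max)


#: Extreme-offset ("ghost") divisions draw a plane offset in this range of
#: cell length; the fragment beyond the plane then holds ~4-6% of the cell
#: area — segmentable, but under the 10% ghost-flag bound.
_GHOST_OFFSET_RANGE = (0.385, 0.40)
#: Renderability cap on |offset|: beyond this the far lobe is too small to
#: resolve at the ~1.7 um cell scale.
_MAX_OFFSET = 0.40


def _draw_offset(preset: StrainPreset, rng: np.random.Generator, ghost: bool) -> float:
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if ghost:
        return sign * rng.uniform(*_GHOST_OFFSET_RANGE)
    if preset.offset_dist == "uniform":
        lo, hi = preset.offset_range  # type: ignore[misc]
        f = rng.uniform(lo, hi)
    else:
        f = abs(rng.normal(0.0, preset.offset_sd_frac)) if preset.offset_sd_frac > 0 else 0.0
    return sign * min(f, _MAX_OFFSET)


def simulate_movie(
    preset: StrainPreset,
    n_cells: int,
    n_frames: int,
    frame_interval_s: float = 30.0,
    seed: int = 0,
    *,
    field_shape: Tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.1235,
    channels: Sequence[str] = ("membrane", "dna"),
    noise: bool = True,
    drift_step_sd_px: float = 0.5,
    cell_long_axis_px: Tuple[float, float] = (14.0, 18.0),
) -> Tuple[MovieStack, GroundTruth]:
    """Render a ground-truthed two-channel movie of dividing cells.

    Parameters follow the acquisition conditions of high-temperature
    live imaging: default pixel size 0.1235 µm, membrane-plus-DNA staining,
    frame intervals of 30 s to 2 min.  Deterministic given ``seed``.

    Returns
    -------
    (MovieStack, GroundTruth)
        The rendered stack and the exact per-cell, per-frame truth,
        including every division attempt and the applied XY drift.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    h, w_field = field_shape
    if h < 32 or w_field < 32:
        raise ValueError("field_shape must be at least 32 x 32")
    for ch in channels:
        if ch not in ("membrane", "dna"):
            raise ValueError(f"unknown channel {ch!r}")

    rng = np.random.default_rng(seed)
    dt = float(frame_interval_s)
    t_end = (n_frames - 1) * dt

    # --- placement: jittered grid with spacing that keeps cells disjoint
    margin, spacing = 20, 34
    nx = max((w_field - 2 * margin) // spacing, 1)
    ny = max((h - 2 * margin) // spacing, 1)
    capacity = nx * ny
    n_placed = n_cells
    if n_cells > capacity:
        warnings.warn(
            f"field holds only {capacity} non-overlapping cells; "
            f"reducing from {n_cells}",
            stacklevel=2,
        )
        n_placed = capacity
    slots = [(margin + spacing // 2 + i * spacing, margin + spacing // 2 + j * spacing)
             for i in range(ny) for j in range(nx)]
    order = rng.permutation(len(slots))[:n_placed]

    cells: List[_Cell] = []
    next_id = n_placed
    for k in range(n_placed):
        gy, gx = slots[order[k]]
        center = np.array([gy + rng.uniform(-3, 3), gx + rng.uniform(-3, 3)])
        a = rng.uniform(cell_long_axis_px[0] / 2.0, cell_long_axis_px[1] / 2.0)
        b = 0.72 * a
        theta = rng.uniform(0.0, math.pi)
        cell = _Cell(cell_id=k, center=center, a=a, b=b, theta=theta)

        span_h = t_end / 3600.0
        p_div = min(1.0, preset.division_rate_per_h * span_h)
        tau = preset.tau_s * rng.uniform(0.9, 1.1)
        t_lo = 3 * dt + 2.5 * tau
        t_hi = t_end - 3.5 * tau - 3 * dt
        if rng.random() < p_div and t_hi > t_lo:
            t0 = rng.uniform(t_lo, t_hi)
            outcome = "failure" if rng.random() < preset.p_fail else "success"
            ghost = outcome == "success" and rng.random() < preset.p_ghost
            f_off = _draw_offset(preset, rng, ghost)
            lead = preset.dna_state_lead_s * rng.uniform(0.8, 1.2)
            div = _Division(t0=t0, tau=tau, outcome=outcome,
                            offset_frac=f_off, ghost=ghost, lead_s=lead)
            w_start = 2.0 * b
            w_onset = _ONSET_DEF_FRAC * (w_start - _EDGE_EROSION_PX) - _NECK_WALL_PX
            w_onset = min(max(w_onset, 0.05 * w_start), 0.95 * w_start)
            div.onset_t = t0 + tau * math.log(w_start / w_onset - 1.0)
            if outcome == "success":
                div.sep_t = t0 + tau * math.log(w_start / _SEP_WIDTH_PX - 1.0)
                cell.division = div
                next_id = _setup_daughters(cell, next_id)
            else:
                cell.division = div
        cells.append(cell)

    # --- drift: global random walk, recorded exactly
    steps = rng.normal(0.0, drift_step_sd_px, size=(n_frames, 2)) if drift_step_sd_px > 0 \
        else np.zeros((n_frames, 2))
    steps[0] = 0.0
    drift = np.cumsum(steps, axis=0)

    # --- truth bookkeeping
    truth_cells: Dict[int, CellTruth] = {}
    events: List[TruthEvent] = []

    def frame_of(t: float) -> int:
        return int(math.ceil(t / dt - 1e-9))

    for cell in cells:
        div = cell.division
        sep_frame = None
        if div is not None:
            ws = 2 * cell.b
            base_obs = ws - _EDGE_EROSION_PX
            onset_frame = next(
                (f for f in range(n_frames)
                 if _observable_width(_width_at(f * dt, cell), ws)
                 < _ONSET_DEF_FRAC * base_obs - 1e-12),
                None,
            )
            if div.outcome == "success":
                sep_frame = frame_of(div.sep_t)
                if onset_frame is None or sep_frame >= n_frames:
                    cell.division = None  # does not complete; drop the attempt
                else:
                    events.append(TruthEvent(
                        parent_id=cell.cell_id,
                        onset_frame=onset_frame,
                        separation_frame=sep_frame,
                        outcome="success",
                        offset_frac=div.offset_frac,
                        daughter_ids=div.daughter_ids,
                        ghost=div.ghost,
                    ))
            else:
                recov_t = 2 * _fail_mirror_time(div.t0, div.tau) - (div.t0 - 2.2 * div.tau)
                if onset_frame is None or recov_t > t_end:
                    cell.division = None
                else:
                    events.append(TruthEvent(
                        parent_id=cell.cell_id,
                        onset_frame=onset_frame,
                        separation_frame=None,
                        outcome="failure",
                        offset_frac=div.offset_frac,
                        ghost=False,
                    ))
        div = cell.division
        last = (frame_of(div.sep_t) - 1) if (div is not None and div.outcome == "success") \
            else (n_frames - 1)
        nfr = last + 1
        centers = np.tile(cell.center, (nfr, 1))
        lengths = np.full(nfr, 2 * cell.a)
        widths = np.array([min(_width_at(f * dt, cell), 2 * cell.b) for f in range(nfr)])
        states = []
        for f in range(nfr):
            t = f * dt
            if div is None:
                states.append("single_diffuse")
            elif t < div.onset_t - div.lead_s:
                states.append("single_diffuse")
            elif t < div.onset_t:
                states.append("two_diffuse")
            else:
                states.append("compact_separated")
        truth_cells[cell.cell_id] = CellTruth(
            cell_id=cell.cell_id, first_frame=0, centers=centers,
            length_px=lengths, furrow_width_px=widths, dna_state=states,
        )
        if div is not None and div.outcome == "success":
            sep_frame = frame_of(div.sep_t)
            u = _axis_unit(cell.theta)
            area1, area2 = div.d_geom[0][0], div.d_geom[1][0]
            tot = max(area1 + area2, 1e-6)
            for di, (dg, did) in enumerate(zip(div.d_geom, div.daughter_ids)):
                side = -1 if di == 0 else +1
                own_frac = (area1 if di == 0 else area2) / tot
                area_i, cx_i, len_i, wid_i = dg
                nfr_d = n_frames - sep_frame
                cs = np.zeros((nfr_d, 2))
                for i, f in enumerate(range(sep_frame, n_frames)):
                    ax = cx_i + side * own_frac * _lobe_shift(f * dt, div.sep_t)
                    cs[i] = cell.center + ax * u
                truth_cells[did] = CellTruth(
                    cell_id=did, first_frame=sep_frame, centers=cs,
                    length_px=np.full(nfr_d, len_i),
                    furrow_width_px=np.full(nfr_d, wid_i),
                    dna_state=["single_diffuse"] * nfr_d,
                )

    # --- render
    want_mem = "membrane" in channels
    want_dna = "dna" in channels
    frames = np.zeros((n_frames, len(channels), h, w_field), dtype=np.float64)
    ch_index = {ch: i for i, ch in enumerate(channels)}

    for f in range(n_frames):
        t = f * dt
        dy, dx = drift[f]
        mem = frames[f, ch_index["membrane"]] if want_mem else None
        dna = frames[f, ch_index["dna"]] if want_dna else None
        for cell in cells:
            div = cell.division
            cy, cx = cell.center[0] + dy, cell.center[1] + dx
            u = _axis_unit(cell.theta)
            w_start = 2 * cell.b
            separated = div is not None and div.outcome == "success" and t >= div.sep_t
            if separated:
                xp = div.offset_frac * 2 * cell.a
                sh_tot = _lobe_shift(t, div.sep_t)
                w_relax = _lobe_relax_width(t, div.sep_t, 2 * cell.b)
                area1, area2 = div.d_geom[0][0], div.d_geom[1][0]
                tot = max(area1 + area2, 1e-6)
                shifts = (sh_tot * area1 / tot, sh_tot * area2 / tot)
                big_idx = 0 if area1 >= area2 else 1
                small_idx = 1 if div.offset_frac >= 0 else 0
                for di, dg in enumerate(div.d_geom):
                    side = -1 if di == 0 else +1
                    area_i, cx_i, _, _ = dg
                    if mem is not None:
                        _add_membrane(mem, cy, cx, cell.a, cell.b, cell.theta,
                                      xp=xp, w=w_relax,
                                      cap_side=side, axis_shift=shifts[di])
                    if dna is not None:
                        ax = cx_i + side * shifts[di]
                        dcy, dcx = cy + ax * u[0], cx + ax * u[1]
                        if div.ghost and di == small_idx:
                            continue  # anucleate fragment
                        _add_blob(dna, dcy, dcx, _SIGMA_NEWBORN, _DNA_FLUX)
                        if div.ghost:
                            _add_blob(dna, dcy + 1.5 * u[0], dcx + 1.5 * u[1],
                                      _SIGMA_NEWBORN, _DNA_FLUX)
                continue
            wt = _width_at(t, cell)
            constricting = div is not None and wt < 0.98 * w_start
            xp = div.offset_frac * 2 * cell.a if div is not None else 0.0
            if mem is not None:
                if constricting:
                    _add_membrane(mem, cy, cx, cell.a, cell.b, cell.theta,
                                  xp=xp, w=wt)
                else:
                    _add_membrane(mem, cy, cx, cell.a, cell.b, cell.theta)
            if dna is not None:
                state = (truth_cells[cell.cell_id].dna_state[f]
                         if f < len(truth_cells[cell.cell_id].dna_state)
                         else "single_diffuse")
                if state == "single_diffuse":
                    _add_blob(dna, cy, cx, _SIGMA_SINGLE, _DNA_FLUX)
                elif state == "two_diffuse":
                    for s in (-0.6, 0.6):
                        _add_blob(dna, cy + s * cell.a * u[0],
                                  cx + s * cell.a * u[1], _SIGMA_DIFFUSE, _DNA_FLUX)
                else:  # compact_separated: one compact mass per nascent side
                    if div is not None and div.ghost:
                        # ghost division: both chromosomes stay on the large side
                        big_mid = ((xp + cell.a) / 2.0 if div.offset_frac >= 0
                                   else (-cell.a + xp) / 2.0)
                        mids = (big_mid - 1.5, big_mid + 1.5)
                    else:
                        mids = ((-cell.a + xp) / 2.0, (xp + cell.a) / 2.0)
                    for x_mid in mids:
                        _add_blob(dna, cy + x_mid * u[0], cx + x_mid * u[1],
                                  _SIGMA_COMPACT, _DNA_FLUX)

        if noise:
            for c in range(len(channels)):
                img = frames[f, c]
                img[:] = rng.poisson(np.clip(img, 0, None) * _PHOTONS_PER_UNIT) \
                    / _PHOTONS_PER_UNIT
                img += rng.normal(0.0, _READ_NOISE_SD, size=img.shape)
                np.clip(img, 0.0, None, out=img)

    movie = MovieStack(
        frames=frames.astype(np.float32),
        pixel_size_um=pixel_size_um,
        frame_interval_s=dt,
        channel_names=tuple(channels),
    )
    truth = GroundTruth(cells=truth_cells, events=events, drift=drift)
    return movie, truth


def simulate_cytometry(
    preset: StrainPreset,
    n_events: int,
    seed: int = 0,
    *,
    n1_fraction: float = 0.5,
    dna_median_1n: float = 100.0,
    dna_cv: float = 0.15,
    size_median: float = 100.0,
    size_noise_cv: float = 0.05,
    offset_size_gain: float = 1.5,
) -> pd.DataFrame:
    """Simulate a flow-cytometry event table (size and DNA-content signals).

    The DNA signal is a two-component log-normal mixture whose 2N median is
    twice the 1N median (newly divided cells have 1N content).  The size
    signal is log-normal with dispersion that widens with the strain's
    division-plane offset spread: strains that misplace the division plane
    produce newborn cells of more variable size.

    Returns a DataFrame with columns ``size_signal, dna_signal, true_ploidy``.
    """
    if n_events < 100:
        raise ValueError("n_events must be >= 100")
    rng = np.random.default_rng(seed)
    ploidy = np.where(rng.random(n_events) < n1_fraction, 1, 2)
    sigma_dna = math.sqrt(math.log(1.0 + dna_cv**2))
    dna = dna_median_1n * ploidy * np.exp(rng.normal(0.0, sigma_dna, n_events))
    sigma_size = math.sqrt(
        size_noise_cv**2 + (offset_size_gain * preset.effective_offset_sd) ** 2
    )
    noise = rng.normal(0.0, sigma_size, n_events) if sigma_size > 0 else np.zeros(n_events)
    size = size_median * ploidy ** (2.0 / 3.0) * np.exp(noise)
    return pd.DataFrame(
        {"size_signal": size, "dna_signal": dna, "true_ploidy": ploidy}
    )


def simulate_ring_images(
    n_cells: int,
    position_dist: dict,
    seed: int = 0,
    *,
    shape: Tuple[int, int] = (64, 64),
    noise: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render fixed-cell style images of a division ring inside a cell.

    Each image has two channels: the cell outline (perimeter band) and a
    bright band perpendicular to the major axis at a drawn fractional
    position along the axis (0 and 1 are the poles, 0.5 the centre).

    ``position_dist`` is one of::

        {"kind": "fixed",    "value": p}
        {"kind": "uniform",  "lo": lo, "hi": hi}
        {"kind": "gaussian", "mean": m, "sd": s}   # clipped to [0, 1]

    Returns ``(images, positions)`` with images shaped (n, 2, H, W) and the
    true fractional positions in [0, 1].
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    kind = position_dist.get("kind")
    if kind == "fixed":
        v = position_dist["value"]
        if not 0.0 <= v <= 1.0:
            raise ValueError("fixed ring position must lie in [0, 1]")
    elif kind == "uniform":
        lo, hi = position_dist["lo"], position_dist["hi"]
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("uniform ring-position bounds must lie in [0, 1]")
    elif kind == "gaussian":
        if not 0.0 <= position_dist["mean"] <= 1.0:
            raise ValueError("gaussian ring-position mean must lie in [0, 1]")
    else:
        raise ValueError(f"unknown position_dist kind {kind!r}")

    rng = np.random.default_rng(seed)
    h, w = shape
    images = np.zeros((n_cells, 2, h, w), dtype=np.float32)
    positions = np.zeros(n_cells)
    for i in range(n_cells):
        if kind == "fixed":
            p = float(position_dist["value"])
        elif kind == "uniform":
            p = rng.uniform(position_dist["lo"], position_dist["hi"])
        else:
            p = float(np.clip(rng.normal(position_dist["mean"], position_dist["sd"]),
                              0.0, 1.0))
        positions[i] = p
        a = rng.uniform(10.0, 13.0)
        b = 0.7 * a
        theta = rng.uniform(0.0, math.pi)
        cy = h / 2.0 + rng.uniform(-2, 2)
        cx = w / 2.0 + rng.uniform(-2, 2)
        outline = np.zeros((h, w))
        _add_membrane(outline, cy, cx, a, b, theta)
        ring = np.zeros((h, w))
        rr, cc = np.mgrid[0:h, 0:w]
        ct, st = math.cos(theta), math.sin(theta)
        x = (rr - cy) * ct + (cc - cx) * st
        y = -(rr - cy) * st + (cc - cx) * ct
        rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
        x_ring = (p - 0.5) * 2.0 * a
        interior = 1.0 / (1.0 + np.exp((rho - 1.03) / 0.04))
        ring[:] = np.exp(-((x - x_ring) ** 2) / (2.0 * 1.2**2)) * interior
        if noise:
            outline = rng.poisson(outline * _PHOTONS_PER_UNIT) / _PHOTONS_PER_UNIT \
                + rng.normal(0.0, _READ_NOISE_SD, outline.shape)
            ring = rng.poisson(ring * _PHOTONS_PER_UNIT) / _PHOTONS_PER_UNIT \
                + rng.normal(0.0, _READ_NOISE_SD, ring.shape)
        images[i, 0] = np.clip(outline, 0, None)
        images[i, 1] = np.clip(ring, 0, None)
    return images, positions
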
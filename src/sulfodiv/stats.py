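"""Summary statistics for division symmetry, ring position and size spread.

All statistics are implemented here rather than delegated:

* ``daughter_ratio`` — min/max of the two daughter areas; 1 is a perfectly
  symmetric division, smaller values increasing asymmetry.
* ``ring_position`` — min/max of the axial distances from a division ring
  to the two cell poles; 1 is a perfectly central ring, 0 a polar one.
* ``rcv`` — the robust coefficient of variance, sample standard deviation
  divided by sample median, used to compare cell-size spread between
  strains on gated newborn (1N) populations.
* ``gate_1n`` — splits a DNA-content signal at the Otsu threshold of its
  log-transform and keeps the 1N (newly divided) events.
* ``mann_whitney_u`` — the two-sided Mann-Whitney rank test, exact by full
  enumeration for small tie-free samples and normal-approximated (with tie
  and continuity corrections) otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.measure import label as sklabel
from scipy import ndimage as ndi
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

EXACT_MAX_N = 10  # per-group size up to which the exact null is enumerated


@dataclass
class RingMeasurement:
    """Measured division-ring position in one fixed cell."""

    cell_id: int
    stage: str
    position_stat: float  # rho in [0, 1]; 1 = exactly central


def daughter_ratio(area_a: float, area_b: float) -> float:
    """min/max of two daughter areas; symmetric in its arguments."""
    if area_a <= 0 or area_b <= 0:
        raise ValueError("areas must be positive")
    return min(area_a, area_b) / max(area_a, area_b)


def ring_position(ring_axial_coord: float, pole_a: float, pole_b: float) -> float:
    """Ring-position statistic rho = min(d1, d2) / max(d1, d2).

    ``d1, d2`` are the axial distances from the ring to the two poles; a
    central ring scores 1, a polar ring 0.
    """
    lo, hi = min(pole_a, pole_b), max(pole_a, pole_b)
    if not lo <= ring_axial_coord <= hi:
        raise ValueError("ring coordinate must lie between the poles")
    d1 = ring_axial_coord - lo
    d2 = hi - ring_axial_coord
    if max(d1, d2) == 0:
        raise ValueError("degenerate cell: poles coincide")
    return min(d1, d2) / max(d1, d2)


def rcv(sample: Sequence[float]) -> float:
    """Robust coefficient of variance: sample sd (n-1) over sample median."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    med = float(np.median(x))
    if med == 0:
        raise ValueError("median is zero; rCV undefined")
    return float(np.std(x, ddof=1)) / med


class GateFailure(RuntimeError):
    """Raised when the DNA-content histogram does not separate 1N from 2N."""


def gate_1n(table: pd.DataFrame) -> pd.DataFrame:
    """Select the 1N (newly divided) events of a cytometry event table.

    Splits ``dna_signal`` at the Otsu threshold of its log-transform and
    returns the below-threshold rows.  Raises :class:`GateFailure` with a
    diagnostic when the log-signal is not bimodal.
    """
    if len(table) < 100:
        raise ValueError("need at least 100 events to gate")
    logx = np.log(np.asarray(table["dna_signal"], dtype=float))
    # bimodality check on a smoothed histogram
    hist, edges = np.histogram(logx, bins=64)
    smooth = ndi.gaussian_filter1d(hist.astype(float), sigma=2.0)
    # zero-pad so that a mode at the histogram boundary still counts
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=0.05 * smooth.max())
    if len(peaks) < 2:
        raise GateFailure(
            f"dna_signal looks unimodal ({len(peaks)} mode(s) found); "
            "cannot place a 1N/2N gate"
        )
    thr = threshold_otsu(logx, nbins=256)
    return table.loc[logx < thr]


def _u_statistic(ranks_x: np.ndarray, nx: int) -> float:
    return float(ranks_x.sum() - nx * (nx + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U_x, p)`` where ``U_x`` is computed from midranks.  For
    tie-free samples with both sizes at most 10 the p-value comes from
    full enumeration of the permutation null; otherwise from the normal
    approximation with tie and continuity corrections.  The identity
    ``U_x + U_y = n_x * n_y`` always holds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = _u_statistic(ranks[:nx], nx)
    m = nx * ny
    has_ties = np.unique(pooled).size < pooled.size

    if nx <= EXACT_MAX_N and ny <= EXACT_MAX_N and not has_ties:
        # enumerate all assignments of ranks 1..n to the x-group
        n = nx + ny
        u_lo = min(u_x, m - u_x)
        u_hi = m - u_lo
        count = 0
        total = 0
        base = nx * (nx + 1) / 2.0
        for comb in combinations(range(1, n + 1), nx):
            u = sum(comb) - base
            if u <= u_lo + 1e-9 or u >= u_hi - 1e-9:
                count += 1
            total += 1
        return u_x, count / total

    mu = m / 2.0
    n = nx + ny
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts) / (n * (n - 1)) if n > 1 else 0.0
    var = m / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_x, 1.0
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - ndtr(z))
    return u_x, min(p, 1.0)


def measure_ring_images(
    images: np.ndarray, stage: str = "unspecified"
) -> List[RingMeasurement]:
    """Measure the ring-position statistic from simulated ring images.

    Each image is (2, H, W): channel 0 the cell outline, channel 1 the
    ring band.  The cell ellipse is fitted from the filled outline; the
    ring's intensity-weighted coordinate along the major axis gives its
    fractional position, converted to rho = min/max pole distance.  Cells
    whose ring channel holds no signal are skipped with a warning.
    """
    out: List[RingMeasurement] = []
    for i, img in enumerate(images):
        outline, ring = np.asarray(img[0], float), np.asarray(img[1], float)
        thr = threshold_otsu(outline)
        bw = ndi.binary_fill_holes(outline > thr)
        lab = sklabel(bw)
        props = regionprops(lab)
        if not props:
            logger.warning("image %d: no cell outline found; skipped", i)
            continue
        p = max(props, key=lambda q: q.area)
        if ring.max() <= 3.0 * max(np.median(ring), 1e-6):
            logger.warning("image %d: no ring band detected; skipped", i)
            continue
        cy, cx = p.centroid
        o = p.orientation
        a = p.axis_major_length / 2.0
        rr, cc = np.nonzero(lab == p.label)
        weights = ring[rr, cc]
        wsum = weights.sum()
        if wsum <= 0:
            logger.warning("image %d: empty ring signal in cell; skipped", i)
            continue
        axial = (rr - cy) * math.cos(o) + (cc - cx) * math.sin(o)
        x_ring = float(np.sum(axial * weights) / wsum)
        x_ring = float(np.clip(x_ring, -a, a))
        rho = ring_position(x_ring, -a, a)
        out.append(RingMeasurement(cell_id=i, stage=stage, position_stat=rho))
    return out
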
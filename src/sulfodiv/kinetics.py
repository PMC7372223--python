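"""Furrow-closure kinetics: sigmoid fitting and the division window.

The short-axis (furrow) width of a constricting cell is fitted with a
four-parameter falling logistic

    w(t) = w_end + (w_start - w_end) / (1 + exp((t - t0) / tau))

The period of division-associated morphological change is bounded by the
two knee points of the fitted curve — the extrema of its second
derivative, at ``t0 ± ln(2 + sqrt(3)) * tau``.  (A logistic has a single
true inflection at ``t0``; the two curvature extrema are what visibly
bracket the transition on a plot and define the shaded division window.)

This module also scores the three-class nucleoid-organisation state of a
cell from its segmented nucleoids and aggregates per-cell state timelines
relative to furrow onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .containers import DNA_STATES, CellObservation

#: Half-length of the division window in units of tau: the second
#: derivative of the logistic is extremal at t0 +/- KNEE_FACTOR * tau.
KNEE_FACTOR = math.log(2.0 + math.sqrt(3.0))

DEFAULT_SOLIDITY_MIN = 0.9
DEFAULT_AREA_FRAC_MAX = 0.25


@dataclass
class SigmoidFit:
    """Fitted logistic parameters for a furrow-width time series."""

    w_start: float
    w_end: float
    t0: float
    tau: float
    rss: float
    window: Tuple[float, float]
    converged: bool


def _logistic(t: np.ndarray, w_start: float, w_end: float, t0: float, tau: float):
    return w_end + (w_start - w_end) / (1.0 + np.exp((t - t0) / tau))


def fit_sigmoid(times: Sequence[float], widths: Sequence[float]) -> SigmoidFit:
    """Least-squares logistic fit of a furrow-width series.

    Initialisation: plateaus from the sample extremes, ``t0`` from the
    first crossing of the midrange, ``tau`` one tenth of the time span.
    ``converged`` is False when the optimiser fails or the fitted
    amplitude is under three residual standard deviations (no real
    transition in the data).

    Raises ``ValueError`` for fewer than 6 samples or non-increasing times.
    """
    t = np.asarray(times, dtype=float)
    w = np.asarray(widths, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 samples")
    if t.shape != w.shape:
        raise ValueError("times and widths must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    w_hi, w_lo = float(w.max()), float(w.min())
    mid = 0.5 * (w_hi + w_lo)
    below = np.nonzero(w < mid)[0]
    t0_init = float(t[below[0]]) if below.size else float(t[t.size // 2])
    tau_init = (t[-1] - t[0]) / 10.0
    p0 = (w_hi, w_lo, t0_init, tau_init)
    try:
        popt, _ = curve_fit(
            _logistic, t, w, p0=p0,
            bounds=([-np.inf, -np.inf, -np.inf, 1e-9],
                    [np.inf, np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        opt_ok = True
    except (RuntimeError, ValueError):
        popt = p0
        opt_ok = False
    w_start, w_end, t0, tau = (float(x) for x in popt)
    resid = w - _logistic(t, *popt)
    rss = float(np.sum(resid**2))
    resid_sd = math.sqrt(rss / max(t.size - 4, 1))
    converged = opt_ok and (w_start - w_end) > 3.0 * resid_sd
    window = (t0 - KNEE_FACTOR * tau, t0 + KNEE_FACTOR * tau)
    return SigmoidFit(
        w_start=w_start, w_end=w_end, t0=t0, tau=tau,
        rss=rss, window=window, converged=converged,
    )


def division_window(fit: SigmoidFit) -> Tuple[float, float]:
    """The (t_lo, t_hi) window bounded by the fitted curve's knee points.

    These are the extrema of the second derivative of the logistic, at
    ``t0 ± ln(2 + sqrt(3)) * tau``; the window length is therefore
    ``2 * ln(2 + sqrt(3)) * tau ≈ 2.634 * tau``.  Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError("division window undefined for a non-converged fit")
    return (fit.t0 - KNEE_FACTOR * fit.tau, fit.t0 + KNEE_FACTOR * fit.tau)


def classify_dna_state(
    observation: CellObservation,
    solidity_min: float = DEFAULT_SOLIDITY_MIN,
    area_frac_max: float = DEFAULT_AREA_FRAC_MAX,
) -> str:
    """Score a cell's nucleoid organisation into one of three classes.

    ``compact_separated``: at least two nucleoids, all compact (solidity
    >= ``solidity_min``) and jointly small (total nucleoid area at most
    ``area_frac_max`` of the cell area).  Otherwise ``two_diffuse`` when
    two or more nucleoids are present, else ``single_diffuse``.

    Raises ``ValueError`` when the observation carries no nucleoid at all
    (unclassifiable, e.g. no DNA channel).
    """
    nuc = observation.nucleoids
    if not observation.dna_measured or len(nuc) == 0:
        raise ValueError("cell has no segmented nucleoids; unclassifiable")
    if len(nuc) >= 2:
        total = sum(n.area_px for n in nuc)
        if (
            all(n.solidity >= solidity_min for n in nuc)
            and total <= area_frac_max * observation.area_px
        ):
            return "compact_separated"
        return "two_diffuse"
    return "single_diffuse"


def dna_state_timeline(
    records: Dict[int, Dict[int, str]],
    onset_frames: Dict[int, int],
) -> pd.DataFrame:
    """Class fractions over time relative to furrow onset.

    ``records`` maps cell id -> {frame: state}; ``onset_frames`` maps cell
    id -> onset frame.  Cells without a known onset are ignored; in each
    relative-frame bin the three class fractions sum to 1 over the cells
    classified in that bin.

    Returns a DataFrame with columns ``rel_frame, n`` and one fraction
    column per class.
    """
    usable = [cid for cid in records if cid in onset_frames]
    if not usable:
        raise ValueError("no cells with a known onset")
    rows: Dict[int, Dict[str, int]] = {}
    for cid in usable:
        onset = onset_frames[cid]
        for frame, state in records[cid].items():
            rel = frame - onset
            counts = rows.setdefault(rel, {s: 0 for s in DNA_STATES})
            if state in counts:
                counts[state] += 1
    out = []
    for rel in sorted(rows):
        counts = rows[rel]
        n = sum(counts.values())
        if n == 0:
            continue
        row = {"rel_frame": rel, "n": n}
        for s in DNA_STATES:
            row[f"frac_{s}"] = counts[s] / n
        out.append(row)
    return pd.DataFrame(out)
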
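"""Frame-to-frame linking of cell observations and division-event detection.

Tracks are built by greedy bipartite matching on mask overlap (IoU)
between consecutive frames.  Before matching, division transitions are
proposed by containment: when two new labels each lie at least half inside
the footprint of one previous cell, that cell is closed and two daughter
tracks open.  (Containment rather than IoU is used for daughter assignment
because a ghost fragment — under 10% of the parent's area — necessarily
has a tiny IoU with the parent while still lying wholly inside it.)
Two tracks collapsing onto one label record a merge, the signature of a
failed division fusing back.

Division attempts are then classified from the furrow-width series of
each track: onset is the first frame the furrow narrows below a fraction
of the pre-constriction baseline, a success ends with two persisting
daughters, and a failure re-widens to near baseline without ever
producing persistent daughters.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from statsmodels.stats.proportion import proportion_confint

from .containers import CellObservation, DivisionEvent, Track

logger = logging.getLogger(__name__)

DEFAULT_IOU_LINK = 0.3
DEFAULT_ONSET_FRAC = 0.8
DEFAULT_RECOVER_FRAC = 0.9
DEFAULT_PERSIST_FRAMES = 3
_CHILD_CONTAINMENT = 0.15  # fraction of a daughter inside the parent footprint
_GHOST_AREA_FRAC = 0.10
#: A width-based failure call needs a resolvable furrow: on tracks whose
#: baseline short axis is only a few pixels, a 20% relative dip is within
#: measurement noise, so such tracks are never scored as failures.
_MIN_FAILURE_BASELINE_PX = 8.0


def _overlap_area(a: CellObservation, b: CellObservation) -> int:
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r0 >= r1 or c0 >= c1:
        return 0
    ma = a.mask[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
    mb = b.mask[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
    return int(np.count_nonzero(ma & mb))


def mask_iou(a: CellObservation, b: CellObservation) -> float:
    inter = _overlap_area(a, b)
    if inter == 0:
        return 0.0
    return inter / float(a.area_px + b.area_px - inter)


def link_tracks(
    observations: Sequence[Sequence[CellObservation]],
    iou_threshold: float = DEFAULT_IOU_LINK,
) -> List[Track]:
    """Link per-frame observation lists into tracks.

    Greedy one-to-one matching on decreasing IoU (acceptance at
    ``iou_threshold``) between consecutive frames, with a one-frame gap
    tolerance.  Division and merge transitions are recorded on the tracks
    (``child_ids``, ``merged_into``).
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 frames of observations")
    tracks: List[Track] = []
    active: Dict[int, int] = {}  # track index -> frames since last seen
    for obs in observations[0]:
        tracks.append(Track(track_id=len(tracks), observations=[obs]))
        active[len(tracks) - 1] = 0

    for f in range(1, len(observations)):
        cur = list(observations[f])
        act_ids = list(active.keys())
        used_labels: set = set()

        # --- division proposals by containment
        best_parent: Dict[int, Tuple[float, int]] = {}
        for ti in act_ids:
            last = tracks[ti].observations[-1]
            for j, ob in enumerate(cur):
                inter = _overlap_area(last, ob)
                frac = inter / float(ob.area_px)
                if frac >= _CHILD_CONTAINMENT and (
                    j not in best_parent or frac > best_parent[j][0]
                ):
                    best_parent[j] = (frac, ti)
        kids_of: Dict[int, List[int]] = {}
        for j, (_, ti) in best_parent.items():
            kids_of.setdefault(ti, []).append(j)
        for ti, kids in kids_of.items():
            if len(kids) < 2:
                continue
            kids = sorted(kids, key=lambda j: -cur[j].area_px)[:2]
            for j in kids:
                child = Track(
                    track_id=len(tracks), observations=[cur[j]], parent_id=ti
                )
                tracks.append(child)
                tracks[ti].child_ids.append(child.track_id)
                active[child.track_id] = 0
                used_labels.add(j)
            del active[ti]

        # --- greedy IoU matching on the remainder
        act_ids = [ti for ti in active if active[ti] >= 0 and ti in active]
        pairs = []
        for ti in act_ids:
            if tracks[ti].observations[-1].frame >= f:
                continue  # freshly opened child
            last = tracks[ti].observations[-1]
            for j, ob in enumerate(cur):
                if j in used_labels:
                    continue
                iou = mask_iou(last, ob)
                if iou >= iou_threshold:
                    pairs.append((iou, ti, j))
        pairs.sort(key=lambda p: -p[0])
        taken_t: set = set()
        claimed_by: Dict[int, int] = {}
        matched_label: Dict[int, int] = {}
        for iou, ti, j in pairs:
            if ti in taken_t or j in used_labels:
                continue
            tracks[ti].observations.append(cur[j])
            active[ti] = 0
            taken_t.add(ti)
            used_labels.add(j)
            claimed_by[j] = ti
            matched_label[ti] = j

        # --- late-appearing second daughter: an unmatched label mostly
        # inside a *recent* footprint of a just-matched track marks a
        # division whose second product was unresolvable at the actual
        # separation frame (looks up to two frames back)
        for j in range(len(cur)):
            if j in used_labels:
                continue
            ob = cur[j]
            best_ti, best_frac, best_k = None, 0.0, 0
            for ti in list(taken_t):
                trobs = tracks[ti].observations
                if tracks[ti].child_ids:
                    continue
                for k in (2, 3):
                    if len(trobs) < k or trobs[-k].frame != f - (k - 1):
                        continue
                    frac = _overlap_area(trobs[-k], ob) / float(ob.area_px)
                    if frac > best_frac:
                        best_frac, best_ti, best_k = frac, ti, k
            if best_ti is not None and best_frac >= _CHILD_CONTAINMENT:
                parent = tracks[best_ti]
                tail = parent.observations[-(best_k - 1):]
                del parent.observations[-(best_k - 1):]
                c1 = Track(track_id=len(tracks), observations=tail,
                           parent_id=best_ti)
                tracks.append(c1)
                parent.child_ids.append(c1.track_id)
                active[c1.track_id] = 0
                c2 = Track(track_id=len(tracks), observations=[ob],
                           parent_id=best_ti)
                tracks.append(c2)
                parent.child_ids.append(c2.track_id)
                active[c2.track_id] = 0
                used_labels.add(j)
                claimed_by[matched_label[best_ti]] = c1.track_id
                del active[best_ti]
                taken_t.discard(best_ti)

        # --- merges and gap handling for still-unmatched tracks
        for ti in act_ids:
            if ti in taken_t or ti not in active:
                continue
            if tracks[ti].observations[-1].frame >= f:
                continue
            last = tracks[ti].observations[-1]
            best_j, best_iou = -1, 0.0
            for j, ob in enumerate(cur):
                iou = mask_iou(last, ob)
                if iou > best_iou:
                    best_iou, best_j = iou, j
            if best_j in claimed_by and best_iou >= iou_threshold / 2.0:
                tracks[ti].merged_into = claimed_by[best_j]
                tracks[ti].merge_frame = f
                del active[ti]
                continue
            active[ti] += 1
            if active[ti] > 1:
                del active[ti]

        # --- leftover labels start fresh tracks
        for j in range(len(cur)):
            if j not in used_labels:
                tracks.append(Track(track_id=len(tracks), observations=[cur[j]]))
                active[len(tracks) - 1] = 0
    return _stitch_fused(tracks)


def _stitch_fused(tracks: List[Track]) -> List[Track]:
    """Reabsorb transient split-then-merge episodes into the parent track.

    A segmentation that briefly splits a deeply constricted (but still
    connected) cell produces a daughter pair of which one immediately
    merges back into the other.  Such an episode is not a division: the
    persisting child's observations are appended to the parent and the
    episode's tracks are dropped, so the parent's width series runs on and
    a genuine failure is still recognisable by its width recovery.
    """
    changed = True
    while changed:
        changed = False
        for tr in tracks:
            if len(tr.child_ids) != 2:
                continue
            c1, c2 = tracks[tr.child_ids[0]], tracks[tr.child_ids[1]]
            if c2.merged_into == c1.track_id:
                cont, gone = c1, c2
            elif c1.merged_into == c2.track_id:
                cont, gone = c2, c1
            else:
                continue
            tr.observations.extend(cont.observations)
            tr.child_ids = list(cont.child_ids)
            for cid in tr.child_ids:
                tracks[cid].parent_id = tr.track_id
            cont.observations = []
            cont.child_ids = []
            gone.observations = []
            changed = True
    return [t for t in tracks if t.observations]


def _baseline_width(widths: np.ndarray) -> float:
    """Pre-constriction width: median of the track's first 3 frames."""
    if len(widths) < 2:
        return float("nan")
    return float(np.median(widths[: min(3, len(widths))]))


def detect_division_events(
    tracks: List[Track],
    frame_interval_s: float,
    onset_frac: float = DEFAULT_ONSET_FRAC,
    recover_frac: float = DEFAULT_RECOVER_FRAC,
    persist_frames: int = DEFAULT_PERSIST_FRAMES,
) -> List[DivisionEvent]:
    """Classify division attempts from linked tracks.

    Onset is the first frame where the furrow width drops below
    ``onset_frac`` times the pre-constriction baseline (median of the
    track's first 3 frames).  Success: two daughters persist for at least
    ``persist_frames`` frames.  Failure: after onset the nascent daughters
    fuse back (split-then-merge) or the track never splits and the furrow
    recovers to at least ``recover_frac`` of baseline.  Division time
    (success only) runs from onset to physical separation.  A daughter
    under 10% of the parent's area with zero nucleoids marks a ghost cell.
    """
    if not 0 < onset_frac < recover_frac <= 1.0:
        raise ValueError("need 0 < onset_frac < recover_frac <= 1")
    by_id = {t.track_id: t for t in tracks}
    events: List[DivisionEvent] = []
    for tr in tracks:
        widths = np.array([o.furrow_width_px for o in tr.observations])
        if len(widths) >= 3:
            # single-frame dips in the min-width statistic are noise, not
            # constriction; a 3-frame running median suppresses them
            widths = ndi.median_filter(widths, size=3, mode="nearest")
        onset_idx: Optional[int] = None
        baseline = _baseline_width(widths)
        if np.isfinite(baseline) and baseline > 0:
            for i in range(1, len(widths)):
                if widths[i] < onset_frac * baseline:
                    onset_idx = i
                    break
        if len(tr.child_ids) == 2:
            c1, c2 = (by_id[c] for c in tr.child_ids)
            fused = (
                c1.merged_into == c2.track_id or c2.merged_into == c1.track_id
            )
            if fused:
                if onset_idx is not None:
                    events.append(
                        DivisionEvent(
                            parent_track=tr.track_id,
                            onset_frame=tr.observations[onset_idx].frame,
                            separation_frame=None,
                            outcome="failure",
                        )
                    )
                continue
            persist = min(len(c1.observations), len(c2.observations))
            if persist < persist_frames:
                logger.warning(
                    "track %d: daughters persist only %d frames; skipping",
                    tr.track_id, persist,
                )
                continue
            if onset_idx is None:
                # wide-offset constrictions can escape the central width
                # window; fall back to the last intact-parent frame
                if len(tr.observations) < 2:
                    logger.warning(
                        "track %d: too short for a baseline; skipping",
                        tr.track_id,
                    )
                    continue
                onset_idx = len(tr.observations) - 1
            onset_frame = tr.observations[onset_idx].frame
            sep_frame = c1.first_frame
            a1 = float(c1.observations[0].area_px)
            a2 = float(c2.observations[0].area_px)
            small = c1 if a1 <= a2 else c2
            ghost = (
                min(a1, a2) < _GHOST_AREA_FRAC * tr.observations[-1].area_px
                and small.observations[0].dna_measured
                and len(small.observations[0].nucleoids) == 0
            )
            events.append(
                DivisionEvent(
                    parent_track=tr.track_id,
                    onset_frame=onset_frame,
                    separation_frame=sep_frame,
                    outcome="success",
                    daughter_areas_px=(a1, a2),
                    daughter_ratio=min(a1, a2) / max(a1, a2),
                    ghost=bool(ghost),
                    division_time_s=(sep_frame - onset_frame) * frame_interval_s,
                )
            )
        elif (
            onset_idx is not None
            and not tr.child_ids
            and baseline >= _MIN_FAILURE_BASELINE_PX
        ):
            # no surviving split: look for recovery back to baseline
            post = widths[onset_idx:]
            if np.any(post >= recover_frac * baseline):
                events.append(
                    DivisionEvent(
                        parent_track=tr.track_id,
                        onset_frame=tr.observations[onset_idx].frame,
                        separation_frame=None,
                        outcome="failure",
                    )
                )
            # else: constriction still in progress at movie end; no event
    return events


def failure_frequency(
    events: Sequence[DivisionEvent],
) -> Tuple[float, Tuple[float, float]]:
    """Fraction of division attempts that failed, with a 95% Wilson CI."""
    if len(events) == 0:
        raise ValueError("no events: failure frequency undefined")
    n_fail = sum(1 for e in events if e.outcome == "failure")
    n = len(events)
    lo, hi = proportion_confint(n_fail, n, alpha=0.05, method="wilson")
    return n_fail / n, (float(lo), float(hi))
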
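# Methods

`sulfodiv` quantifies cell division in time-lapse fluorescence movies of
near-spherical archaeal cells (a membrane stain plus an optional DNA
stain). Because raw high-temperature live-imaging data are rarely shared,
every stage of the pipeline is driven and validated by a forward model — a
synthetic movie generator with an exact ground-truth sidecar. This note
describes the model, the measurement definitions, the parameters that
matter, and the limits of what the synthetic validation demonstrates.

## The forward model

**Cell geometry.** A cell is a 2-D ellipse with semi-axes `a > b`
(aspect `b/a = 0.72`, long axis drawn uniformly from 14–18 px, i.e.
1.7–2.2 µm at the default 0.1235 µm/px). Cells are placed on a jittered
grid (34 px spacing, 20 px margin) so they never touch; a field too small
for the requested count is filled to capacity with a warning. Cells do
not grow between divisions: movies span at most a couple of hours, about
one division per lineage, and growth would only dilate the ground truth
without exercising any measurement.

**Constriction.** A dividing cell follows the falling logistic

    w(t) = w_start / (1 + exp((t − t0)/τ)),

where `w(t)` is the furrow (neck) width, `w_start = 2b` the resting short
axis and `τ` the closure time constant (preset default 90 s, ±10%
per-cell jitter). Geometrically the constriction multiplies the local
half-width profile of the ellipse by a Gaussian waist centred on the
division plane, so the rendered neck width equals `w(t)` exactly. The
waist is local: its axial width (2.5 px) is capped at a third of each
lobe's length, so a strongly off-centre plane produces a bulging small
compartment rather than an unresolvable sliver — which is what
asymmetric divisions look like in real micrographs.

**Division plane.** The plane offset is drawn per event as a fraction of
cell length: Gaussian (sd 3%) for the control-like strains, uniform over
the preset range for the wide-offset strain. Offsets are clipped at 0.40
of the length because beyond that the far compartment holds under ~4% of
the cell area (< 6 rendered px at this scale) and is physically
unresolvable. "Ghost" events draw offsets in 0.385–0.40 of the length and
place both chromosomes in the large compartment, producing an anucleate
fragment of ~4–6% of the cell area.

**Separation.** A successful event separates when `w(t)` falls below
1.5 px. The daughters are the two lobes of the constricted parent, cut at
the plane: their areas therefore sum to the parent's constricted area in
the frame straddling separation (conservation), and their area ratio
follows the plane offset. After abscission the larger daughter recedes
~3 px from the plane (parting split in proportion to lobe area, so a tiny
fragment stays at the parent pole), the cut is inset by up to 1.2 px on
the larger side to offset the mask border its new pole adds, and the
inherited waist relaxes at 0.08 px/s as the newborns round up.

**Failure.** With preset probability `p_fail` the constriction reverses:
`w(t)` follows the logistic down to 0.35·`w_start` and then retraces it in
mirrored time until the cell is whole again. The depth is chosen so the
*observable* width (see below) clearly crosses the detection threshold;
the value is a model constant, not a fitted one.

**DNA.** Nucleoids are isotropic Gaussian blobs: one diffuse blob
(σ = 3 px) at rest; two diffuse blobs (σ = 2.6 px, at ±0.6·a) from
`dna_state_lead_s` (default 600 s) before constriction onset; two compact
blobs (σ = 1.2 px — a > 2× shrink — at the lobe midpoints) from onset.
Newborn daughters carry one compact-ish blob each (σ = 1.6 px). The
three-state sequence per dividing cell is monotone by construction, with
compaction within one frame of furrow onset.

**Noise and drift.** Poisson shot noise (200 photons per intensity unit
at the membrane-band peak) plus Gaussian read noise (sd = 2% of the
peak), both switchable off for oracle tests. A global XY random walk
(per-frame step sd 0.5 px, configurable) translates every rendered object
and is recorded exactly in the truth sidecar.

**Rendering.** The membrane channel draws each cell's outline as a ~2 px
perimeter shell: an anti-aliased soft indicator of the filled shape minus
its grey-scale erosion by a radius-2 disk. This construction follows the
exact constricted geometry (a parametric bright ridge bridges or breaks
the narrow constriction notch) and keeps sub-pixel positions meaningful
for drift estimation.

## Measurement definitions

**Observable furrow width.** The segmentation mask of a constricting cell
carries the two apposed membranes at the neck (≈ +2.3 px) and loses
≈ 1 px of outline at baseline. The ground-truth onset frame is therefore
defined on this observable width — the first frame where
`min(w + 2.3, w_start − 1) < 0.8 · (w_start − 1)` — so the truth sidecar
and the pipeline describe the same quantity. The geometric parameters
(`t0`, `τ`, `w(t)`) in the truth remain exact. The wall and erosion
constants were calibrated once on noiseless renders.

**Segmentation.** Gaussian smoothing (σ = 1 px), Otsu threshold with a
background guard (the threshold must clear the median by 4 robust sigmas,
so blank or noise-only frames yield no labels), hole filling (the
membrane marks perimeters), and a watershed seeded from
distance-transform maxima. Watershed splits whose separating valley is
shallow — saddle depth above 0.35 of the shallower peak — are merged
back: a constricting cell's neck is wide relative to its lobes, a true
contact between two cells is not. The minimum object size is 6 px so that
ghost fragments survive filtering. A classical pipeline replaces the
learned segmenter used on real data; on synthetic imagery with known
truth this is exact enough to validate every downstream stage, and it
requires no trained weights.

**Furrow width.** Pixel coordinates of the mask are projected on the
moment-ellipse major axis; per-axial-bin occupancy counts (3-bin running
mean, so one ragged column cannot set the minimum) give the local width,
and the furrow width is the minimum over the central 50% of the length.
The global minor axis is recorded alongside. Necks beyond the central
window (far-offset planes) escape this statistic by construction; event
detection therefore falls back to the split itself for such divisions.

**Tracking.** Greedy one-to-one matching on mask IoU (≥ 0.3) between
consecutive frames, with one-frame gap tolerance. Division transitions
are proposed by containment — two new labels each ≥ 15% inside one
previous footprint — because a ghost fragment is under 10% of its
parent's area and necessarily has near-zero IoU with it. A second
daughter that becomes resolvable one or two frames after abscission is
recovered by re-testing unmatched labels against recent footprints of
just-matched tracks. Transient split-then-merge episodes (a deeply
constricted but still connected cell briefly oversplit) are stitched back
into the parent track, so a genuine failure is recognised by its width
recovery, not by segmentation jitter.

**Event classification.** Onset: first frame the (3-frame
median-filtered) furrow width drops below 0.8 of the pre-constriction
baseline (median of the track's first three frames). Success: two
daughters persist ≥ 3 frames; the daughter-area ratio is measured at the
first post-separation frame. Failure: the track never produces persistent
daughters and the width recovers to ≥ 0.9 of baseline; width-based
failure calls additionally require a baseline of ≥ 8 px, because a 20%
dip on a ~6 px newborn is below measurement noise. Ghost flag: the
smaller daughter holds < 10% of the parent's area and zero segmented
nucleoids. Division time runs from onset to physical separation.

**Kinetics.** `fit_sigmoid` performs a least-squares fit of the
4-parameter falling logistic (plateaus initialised from the sample
extremes, `t0` from the midrange crossing, `τ` from a tenth of the span);
a fit is flagged non-converged when the optimiser fails or the amplitude
is under three residual standard deviations. The division window is
`t0 ± ln(2+√3)·τ`: a logistic has a single true inflection at `t0`, and
the two curvature extrema (knees) of the curve are what visibly bracket
the transition on a plot — the alternative reading of a double-sigmoid
fit is rejected for parsimony. The logistic is the minimal symmetric
sigmoid family; a Gompertz curve would break the window's symmetry.

**Statistics.** Daughter ratio `min/max` of the two areas (1 =
symmetric); ring position `ρ = min/max` of the axial pole distances (1 =
central); rCV = sample sd (n−1) over sample median, exactly as printed —
not a MAD-based robust CV. The 1N gate splits the log DNA signal at its
Otsu threshold after a bimodality check (two peaks of a smoothed,
zero-padded histogram); unimodal input raises a gate failure with a
diagnostic. The Mann-Whitney test computes U from midranks and the
two-sided p by full enumeration of the permutation null for tie-free
groups of ≤ 10, otherwise by the normal approximation with tie and
continuity corrections — documented so p-values are bit-reproducible.

**Registration.** Translation-only, estimated on the membrane channel by
phase cross-correlation with upsampled sub-pixel refinement between
consecutive frames and accumulated relative to frame 0; all channels are
resampled bilinearly with the per-frame background median filling the
vacated margins. Rotation and focus drift are out of scope (the latter is
handled in hardware on the instruments this models).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `pixel_size_um` | 0.1235 | µm per pixel |
| `frame_interval_s` | 30 | s between frames (30–120 typical) |
| `tau_s` | 90 | furrow-closure time constant, s |
| `p_fail` | 0.015 / 0.16 / 0.02 | failure probability (MW001 / ΔcdvB1 / ΔcdvB2) |
| offset distribution | N(0, 0.03·L) or U(0.05–0.5·L) | division-plane offset |
| `p_ghost` | 0.05 (ΔcdvB2) | extreme-offset anucleate-fragment probability |
| `dna_state_lead_s` | 600 | two-diffuse stage begins this long before onset |
| `onset_frac` / `recover_frac` | 0.8 / 0.9 | width thresholds for onset / failure recovery |
| `persist_frames` | 3 | frames daughters must persist for a success |
| `solidity_min` / `area_frac_max` | 0.9 / 0.25 | compact-nucleoid classification |
| `min_area_px` | 6 | smallest segmented object |
| `iou_link` | 0.3 | track-linking acceptance |

Only the 16% and "1–2%" failure magnitudes are published values; the
offset breadths, ghost frequency and kinetic constants are declared,
configurable defaults chosen to reproduce the qualitative phenotypes and
are not facts about any strain.

## What the synthetic validation does and does not show

The generator emulates: perimeter-stained near-spherical cells, logistic
furrow closure, strain-dependent plane offset and failure probability, a
three-state nucleoid sequence tied to onset, shot and read noise, and
global XY drift. It does not emulate: cell growth, motility, touching or
overlapping cells, photobleaching, uneven illumination, focus drift,
debris, or segmentation-relevant texture inside cells. Passing tests
therefore demonstrate that the measurement definitions and the event
logic are correct and self-consistent at realistic noise levels — not
that the classical segmenter would match a trained one on real
micrographs, where the learned stage this pipeline replaces earns its
keep.

Problem sizes used by the test suite and the acceptance script (fields of
40–60 cells, 50–60 frames at 30 s, a few hundred to ~700 pooled division
events) were chosen so each statistical check has adequate power — e.g.
the pooled failure-rate estimate concentrates to about ±1.5 percentage
points — while a full run stays comfortable on a single CPU.

## Known limitations

* A *failure* at a far-offset plane escapes the central-width statistic
  and is not scored; at the wide-offset strain's 2% failure rate this is
  rare and no summary in this package depends on it.
* Ghost-flag recall is complete on noiseless renders but ~50% under full
  noise, and a non-ghost fragment whose nucleoid falls below the
  resolution limit can be flagged — at this cell scale "anucleate" and
  "nucleoid unresolvable" genuinely coincide.
* Measured division times are quantised by the frame interval and the
  1-px width resolution: individual events can be off by up to two
  frames against truth (median within one).
* The daughter-area ratio of very asymmetric divisions is measured at
  separation, when the fragment is still partly waist-compressed; ratios
  below ~0.1 are compressed toward smaller values.
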
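# Methods

This note documents the models, numerical choices and limitations behind
`nichetrack`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Conventions and units

Pixel coordinates are (x, y) with x = column, y = row, origin at the
top-left, 0-based; centroids are real-valued in pixel units. All distances
are handled internally in micrometres (positions × `pixel_size_um`, assumed
isotropic) and all times in seconds; minutes appear only in reported
velocities and the short/long duration split. Calibration is always
explicit configuration: TIFF tag dialects vary between acquisition
software, so reading them would make runs irreproducible across
conversions.

## Drift correction

Whole-field lateral drift (breathing and slow stage motion) is estimated
per frame as the shift maximising the full, zero-padded cross-correlation
with frame 0 after mean subtraction. The estimate is integer-pixel; ties in
the correlation peak are broken by smallest |dx|+|dy|, then
lexicographically, so the output is deterministic. Frames with zero
variance yield offset (0, 0) with a warning rather than an error.

The correction translates each frame by the negated offset with zero fill.
Because true drift is generally fractional, an integer translation leaves a
remainder of up to half a pixel that is *common to every object in the
frame*. The pipeline therefore refines each peak by a separable three-point
parabolic fit (bounded to ±0.5 px, so integer shifts of clean images remain
exact) and subtracts the fractional remainder from the detected centroids
of that frame. Without this refinement the shared remainder consumes most
of a 1 px position-error budget; with it the typical total position error
on synthetic movies is ≈ 0.3 px. Frame pixels themselves are never
resampled — only positions are corrected — so detection runs on
unsmoothed data.

## Detection

Each frame is median filtered (window 5 px by default; odd windows only),
thresholded at a user-supplied intensity cutoff (strictly above), and
segmented into 8-connected components. Components smaller than
`min_object_area_px` are dropped. The centroid is the unweighted mean of
the component's pixel coordinates: a binary centroid is less sensitive to
the threshold choice than an intensity-weighted one; the weighted variant
is available as `intensity_weighted_centroid` for comparison. The mean
intensity is measured on the filtered image over the component. The
threshold is deliberately manual (an analysis parameter); detection counts
are monotonically non-increasing in both the threshold and the minimum
area for unimodal spots.

## Tracking

Linking uses the classic nearest-neighbour particle-tracking objective:
between consecutive frames, the assignment of live tracks to detections
minimises the summed squared displacement, with links farther than
`max_link_displacement_px` forbidden and every unmatched track or detection
charged `max_link_displacement_px`². The assignment is solved exactly with
the Hungarian algorithm on an augmented cost matrix; a brute-force
enumeration oracle in the test suite confirms optimality on small
instances. Tracks sorted by id before assignment and deterministic tie
handling make linking reproducible.

A track missing a detection survives `gap_memory_frames` frames (default
1, matching the one-frame z-excursions the interpolation rule is meant
for) before being closed. Tracks with **strictly more than**
`min_track_frames` = 10 *detected* frames are retained — the bound is
exclusive, and interpolated samples do not count towards it, both stated
here because they change downstream event counts. Missing interior frames
are then filled by linear interpolation between the flanking detections
and flagged `interpolated`; endpoints are never extrapolated.

## Distance fields and zones

Region annotations are binary masks ("nonzero = inside"); the distance to
a region is the exact Euclidean distance transform of the mask complement,
scaled to μm, i.e. 0 anywhere inside the (filled) region. Distances are
measured from the detection centroid — cell radius is not modelled — and
sampled from the field bilinearly at the real-valued centroid, which bounds
the sampling error by one pixel. Querying an empty mask is refused
(`RegionUndefinedError`): absence of an annotation is not infinite
distance.

Zones partition distance: contact d ≤ 5 μm, proximal 5 < d ≤ 25 μm,
distal d > 25 μm. Both boundaries are closed above ("within 5 μm"
includes 5.0); the convention is fixed so that counts are reproducible.

## Interaction classification

Per frame the candidate label is the region with the smaller distance;
exact ties keep the previous frame's label and default to vascular at the
first frame. The zone state passes a Schmitt trigger: entering a state uses
the nominal cutoff, but leaving a state toward a larger distance requires
the distance to exceed the cutoff by more than `hysteresis_um` = 1 μm.
This one-sided trigger suppresses classification flicker for cells sitting
on a boundary (a series oscillating 4.5 ↔ 5.5 μm around the 5 μm cutoff
stays in contact, since leaving requires d > 6 μm). When the nearest
region changes while both are within the proximal cutoff, the new label is
classified nominally; a transition to *none* (no interaction) requires the
held region's distance to clear the proximal cutoff plus the margin. The
margin is configurable because a per-cell, data-driven variant of the
±1 μm adjustment is equally defensible; the fixed symmetric trigger was
chosen for determinism.

Maximal runs of constant (label, zone) become interaction events with
`duration_s = end_s − start_s + frame_interval_s`, so a track's events tile
its observed span exactly. Transient merging then iteratively absorbs any
event shorter than `merge_window_s` = 200 s whose two neighbours share one
(label, zone) — the three fuse — or which sits at a track edge — it is
absorbed into its single neighbour. Transients flanked by two different
states are kept: they are genuine brief interactions, not flicker. Merging
conserves total duration exactly, never increases the event count, and is
idempotent (property-tested over random event sequences). Finally,
interactions shorter than `long_duration_min` = 60 min are classed *short*
and the rest *long*; the 60 min boundary is assigned to *long* because the
short class is defined strictly. No-interaction periods carry no class.

## Metrics

Velocity is |Δposition| per frame interval in μm/min, from raw consecutive
displacements with interpolated samples included (no smoothing).
Normalised displacement is the mean over t > 0 of the distance to the first
recorded position, divided by the observed span in minutes. "Time near" a
region is defined directly from per-frame distances (d ≤ 25 μm), whereas
contact/proximal time fractions use the hysteresis labelling, because the
former quantifies proximity and the latter classified interactions; the
distance-based contact/proximal/distal fractions partition to 1 per
region. Relative vascular/endosteal frequencies are time-weighted by
default with a count-based mode available; an empty denominator returns a
NaN sentinel with a warning, never an exception. All s.e.m. values are
sd(ddof=1)/√n over cells. The occupancy map is a 2D histogram of all
cell-frames, optionally Gaussian-smoothed, normalised to total mass 1.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the pipeline assumes:
bright isotropic Gaussian spots (σ = 2 px, amplitude 200) over a constant
background (10) plus a dim rendering of the niche structures (40), i.i.d.
Gaussian pixel noise (sd 8, i.e. 4% of the spot amplitude), a slow global
fractional drift ((0.1, −0.06) px/frame, applied by shifting spot centres
and bilinearly shifting the backdrop — frames are never resampled, so the
ground truth stays exact), and per-frame single-frame disappearances
(probability 0.01) emulating z-excursions. The backdrop drifts with the
field; it is what makes drift estimable, playing the role of the
counter-labelled microenvironment in real movies. The reference geometry
is a central vertical vessel ribbon (half-width 8 px) and a peripheral
endosteal band (10 px) along the image border.

Cell motion is a three-state Markov model (vascular dwell, endosteal
dwell, free) and is a *testing device*, not a biological claim — no
quantitative motion model for these cells is established. Each state
anchors the cell: dwell anchors sit on region pixels, free anchors in the
proximal band (12–18 μm) or the distal interior (≥ 31 μm); around its
anchor the cell performs mean-reverting jitter (pull 0.5, step sd
0.35–0.5 px). State switches (default ~0.3% per frame per cell) trigger a
rapid straight-line relocation at ~10 px/frame to a freshly sampled
anchor. Three constraints make the ground truth unambiguous at the
pipeline's sub-pixel accuracy, and they are deliberate test design rather
than biology:

- travel steps are nudged in length (±3 px) and laterally (±4 px) so that
  no frame lies within 2 μm of a zone-trigger distance (5, 6, 25 or
  26 μm);
- anchors keep 14 px separation, travel corridors keep 18 px clearance
  from other cells, and anchors stay inside the drift envelope, so spots
  never merge and never drift out of the field;
- only one cell relocates at a time, switches are deferred otherwise, and
  disappearances are suppressed during relocation (linear interpolation is
  exact on a straight, evenly stepped path but not across a turning
  point).

Consequently, a passing end-to-end test certifies that the pipeline makes
no errors when the data respects its resolution limits; it does not
certify behaviour for cells that hover at a zone boundary, touch each
other, or vanish for several frames. Those regimes are reachable by
loosening the corresponding parameters (`boundary_margin_um`,
`min_cell_separation_px`, `max_gap_frames`) and are intentionally outside
the default scenario.

Ground-truth labelling and events are computed by the *same* classifier
code applied to the true positions, which is what makes exact event-list
equality a meaningful oracle: any divergence is attributable to the
imaging stages (rendering, drift, detection, linking), not to a parallel
reimplementation of the rules.

The `contact_dwell_scenario` preset reduces the model to two states
(vascular dwell ↔ distal free) with switch rates in the ratio that gives
the dwell state a stationary occupancy equal to the target contact-time
fraction (default 0.7, rates 0.015/0.035 per frame). Relocation frames
dilute the realised fraction slightly and niche geometry adds occasional
incidental contact; at the default mixing speed the realised true fraction
centres on ≈ 0.71 with seed-to-seed spread ≈ 0.12. Recovery is asserted
against the binomial 95% interval around the target at n = number of
cells, which is the natural scale for a population mean over cells (per
frame the series is strongly autocorrelated, so a per-frame binomial
interval would be meaninglessly tight).

## Problem sizes

The reference scenario is 256×256 px × 200 frames × 10 cells; the
acceptance script runs it, and the recovery scenario, on three seeds each
(≈ 45 s total on one CPU). These sizes give every event class multiple
occurrences per run while keeping the full suite fast; all thresholds in
the tests (95% frame recovery within 1 px, exact event equality) are
asserted per seed, not averaged.

## Known limitations

- Tracking is 2D; axial motion appears only as disappearance plus
  interpolation. Movies with systematic z-drift need external handling.
- Touching cells are not split (no watershed); the linker will merge or
  drop them.
- Drift is modelled as a single global translation per frame; rotation and
  non-rigid tissue motion are out of scope.
- The distance fields treat annotated regions as filled: distance is 0
  anywhere inside a region, not distance to its outline.
- Statistical comparison between populations (e.g. t-tests) is left to the
  user; the summary CSV exposes per-cell quantities for any such test.
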
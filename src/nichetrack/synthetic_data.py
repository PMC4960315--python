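"""Synthetic intravital movies with exact ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: bright
Gaussian-spot cells over a dimly backlit microenvironment (a vessel ribbon
and a peripheral endosteal band), slow global lateral drift, biased motion
with dwell states at niche regions, and intermittent single-frame
disappearance (z-excursions).

The motion model is deliberately a *testing device*, not a biological claim:
cells alternate between anchored dwell phases (jitter around a fixed anchor
in the vascular contact zone, the endosteal contact zone, or a free anchor in
the proximal band or distal interior) and rapid straight-line excursions
between anchors.  Dwell anchors and travel steps are chosen so that no frame
sits within a small margin of a zone boundary, which makes the ground-truth
(label, zone) series unambiguous at the sub-pixel accuracy the pipeline
achieves; real data carries no such guarantee (see the methods note).
Ground-truth events are produced by the very same classifier code the
pipeline uses, applied to the true positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .interactions import (
    InteractionEvent,
    classify_durations,
    label_timepoints,
    merge_transients,
    segment_events,
)
from .io_formats import AnalysisParameters, MovieStack, RegionMap
from .niche_geometry import region_distance_fields, sample_distances
from .tracking import Track, TrackSample

DWELL_VASCULAR = 0
DWELL_ENDOSTEAL = 1
FREE = 2
STATE_NAMES = ("dwell_vascular", "dwell_endosteal", "free")

_DEFAULT_SWITCH = (
    (0.997, 0.001, 0.002),
    (0.001, 0.997, 0.002),
    (0.002, 0.002, 0.996),
)


@dataclass
class SimulationParameters:
    """Scene, optics and motion-model parameters of the synthetic movie.

    The defaults describe the reference scenario: a 256 x 256 px field at
    1 μm/px and 10 s/frame, 200 frames, 10 non-overlapping cells, spot noise
    at 4% of the spot amplitude and a slow fractional drift.
    """

    height: int = 256
    width: int = 256
    pixel_size_um: float = 1.0
    frame_interval_s: float = 10.0
    n_frames: int = 200
    n_cells: int = 10
    spot_sigma_px: float = 2.0
    spot_amplitude: float = 200.0
    background_level: float = 10.0
    structure_level: float = 40.0  # backlit niche-structure intensity
    noise_sd: float = 8.0
    drift_per_frame: tuple[float, float] = (0.1, -0.06)  # (dx, dy) px/frame
    switch_matrix: tuple = _DEFAULT_SWITCH
    initial_state_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    anchor_pull: float = 0.5  # OU mean reversion toward the anchor
    step_sd_dwell_px: float = 0.35
    step_sd_free_px: float = 0.5
    travel_step_px: float = 10.0  # nominal saltatory step between anchors
    free_distal_prob: float = 0.4  # free anchors: distal interior vs proximal band
    disappearance_prob: float = 0.01  # per-frame single-frame z-excursion
    max_gap_frames: int = 1  # >1 is a stress-test option, off by default
    min_cell_separation_px: float = 14.0
    boundary_margin_um: float = 2.0  # keep-out margin around zone triggers
    rng_seed: int = 0

    def __post_init__(self) -> None:
        matrix = np.asarray(self.switch_matrix, dtype=float)
        if matrix.shape != (3, 3) or np.any(matrix < 0) or np.any(matrix > 1):
            raise ValidationError("switch_matrix must be 3x3 with probabilities in [0, 1]")
        if not np.allclose(matrix.sum(axis=1), 1.0):
            raise ValidationError("switch_matrix rows must sum to 1")
        probs = np.asarray(self.initial_state_probs, dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("initial_state_probs must be a distribution over 3 states")
        if not 0 <= self.disappearance_prob <= 1:
            raise ValidationError("disappearance_prob must lie in [0, 1]")
        if not self.spot_sigma_px > 0:
            raise ValidationError("spot_sigma_px must be > 0")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


@dataclass
class GroundTruth:
    """Exact per-frame truth of one simulated movie."""

    drift: np.ndarray  # (n_frames, 2) cumulative (dx, dy) px
    positions: np.ndarray  # (n_cells, n_frames, 2) pre-drift (x, y) px
    visible: np.ndarray  # (n_cells, n_frames) bool
    states: np.ndarray  # (n_cells, n_frames) int state codes
    labelled: list[pd.DataFrame]  # per cell: frame, t_s, d_v_um, d_e_um, label, zone
    events: list[list[InteractionEvent]]  # per cell, merged + duration-classed
    region_map: RegionMap = None
    sim_params: SimulationParameters = None
    analysis_params: AnalysisParameters = None

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def all_events(self) -> list[InteractionEvent]:
        return [e for per_cell in self.events for e in per_cell]

    def track_table(self) -> pd.DataFrame:
        """True positions as a track table (one track per cell, all frames)."""
        rows = [
            (cid, t, self.positions[cid, t, 0], self.positions[cid, t, 1], False)
            for cid in range(self.n_cells)
            for t in range(self.n_frames)
        ]
        return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "interpolated"])


def make_default_region_map(
    grid_shape: tuple[int, int],
    pixel_size_um: float = 1.0,
    vessel_half_width_px: int = 8,
    endosteal_band_px: int = 10,
    gap_px: int = 6,
) -> RegionMap:
    """Reference niche geometry: a central vertical vessel ribbon and a
    peripheral endosteal band along the image border, non-overlapping."""
    h, w = grid_shape
    min_w = 2 * (endosteal_band_px + gap_px) + 2 * vessel_half_width_px + 2
    min_h = 2 * (endosteal_band_px + gap_px) + 2
    if w < min_w or h < min_h:
        raise ValidationError(
            f"grid {grid_shape} too small for the default region geometry "
            f"(needs at least {min_h} x {min_w})"
        )
    endosteal = np.zeros((h, w), dtype=bool)
    endosteal[:endosteal_band_px, :] = True
    endosteal[-endosteal_band_px:, :] = True
    endosteal[:, :endosteal_band_px] = True
    endosteal[:, -endosteal_band_px:] = True
    vascular = np.zeros((h, w), dtype=bool)
    cx = w // 2
    row_lo = endosteal_band_px + gap_px
    row_hi = h - endosteal_band_px - gap_px
    vascular[row_lo:row_hi, cx - vessel_half_width_px : cx + vessel_half_width_px + 1] = True
    return RegionMap(vascular, endosteal, pixel_size_um)


# ---------------------------------------------------------------------------
# anchor geometry
# ---------------------------------------------------------------------------


class _AnchorGeometry:
    """Precomputed candidate anchor pixels for each behavioural state."""

    def __init__(self, region_map: RegionMap, sim: SimulationParameters,
                 analysis: AnalysisParameters):
        v_field, e_field = region_distance_fields(region_map)
        self.d_v = v_field.values_um
        self.d_e = e_field.values_um
        h, w = region_map.shape
        # anchors must stay imageable for the whole movie: keep clear of the
        # border plus the cumulative drift envelope on each side
        edge = 6
        cum = np.arange(sim.n_frames)[:, None] * np.asarray(sim.drift_per_frame, float)
        lo_x = edge + max(0.0, -cum[:, 0].min())
        hi_x = w - edge - max(0.0, cum[:, 0].max())
        lo_y = edge + max(0.0, -cum[:, 1].min())
        hi_y = h - edge - max(0.0, cum[:, 1].max())
        if lo_x >= hi_x or lo_y >= hi_y:
            raise ValidationError("cumulative drift leaves no imageable interior")
        yy, xx = np.mgrid[0:h, 0:w]
        interior = (xx >= lo_x) & (xx < hi_x) & (yy >= lo_y) & (yy < hi_y)
        ambiguous = np.abs(self.d_v - self.d_e) < 3.0  # nearest region must be clear-cut
        d_min = np.minimum(self.d_v, self.d_e)
        self.candidates = {
            DWELL_VASCULAR: np.argwhere(
                interior & (self.d_v == 0) & ~ambiguous
            ),
            DWELL_ENDOSTEAL: np.argwhere(
                interior & (self.d_e == 0) & ~ambiguous
            ),
            "free_proximal": np.argwhere(
                interior & (d_min >= 12.0) & (d_min <= 18.0) & ~ambiguous
            ),
            "free_distal": np.argwhere(
                interior & (d_min >= 31.0)
            ),
        }
        # small grids may lack a distal interior; the free state then falls
        # back to proximal anchors at sampling time, but a dwell state with no
        # sites is a hard geometry error
        for key in (DWELL_VASCULAR, DWELL_ENDOSTEAL):
            if len(self.candidates[key]) == 0:
                raise ValidationError(
                    f"region geometry leaves no anchor sites for {STATE_NAMES[key]!r}"
                )
        if len(self.candidates["free_proximal"]) == 0 and len(self.candidates["free_distal"]) == 0:
            raise ValidationError("region geometry leaves no anchor sites for the free state")
        shells = []
        for cutoff in (analysis.contact_cutoff_um,
                       analysis.contact_cutoff_um + analysis.hysteresis_um,
                       analysis.proximal_cutoff_um,
                       analysis.proximal_cutoff_um + analysis.hysteresis_um):
            shells.append((cutoff - sim.boundary_margin_um, cutoff + sim.boundary_margin_um))
        self.shells = shells

    def _bilinear(self, field: np.ndarray, x: float, y: float) -> float:
        h, w = field.shape
        x = min(max(x, 0.0), w - 1.0)
        y = min(max(y, 0.0), h - 1.0)
        x0, y0 = int(x), int(y)
        x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
        fx, fy = x - x0, y - y0
        top = field[y0, x0] * (1 - fx) + field[y0, x1] * fx
        bot = field[y1, x0] * (1 - fx) + field[y1, x1] * fx
        return float(top * (1 - fy) + bot * fy)

    def in_shell(self, x: float, y: float) -> bool:
        """True when either region distance at (x, y) is near a zone trigger."""
        for field in (self.d_v, self.d_e):
            d = self._bilinear(field, x, y)
            for lo, hi in self.shells:
                if lo < d < hi:
                    return True
        return False

    def sample_anchor(self, state: int, free_distal: bool, rng: np.random.Generator,
                      other_anchors: list[np.ndarray], min_sep: float,
                      origin: np.ndarray | None) -> np.ndarray | None:
        """Draw an anchor for a state, keeping clear of the other cells and of
        the straight corridor from ``origin`` (when travelling)."""
        if state == FREE:
            key = "free_distal" if free_distal else "free_proximal"
            if len(self.candidates[key]) == 0:
                key = "free_proximal" if key == "free_distal" else "free_distal"
        else:
            key = state
        pts = self.candidates[key]
        for _ in range(200):
            row, col = pts[rng.integers(len(pts))]
            anchor = np.array([col, row], dtype=float)
            if any(np.linalg.norm(anchor - a) < min_sep for a in other_anchors):
                continue
            # travel corridor must clear the other cells by the separation
            # radius plus the largest lateral shell-avoidance nudge (4 px)
            if origin is not None and any(
                _point_segment_distance(a, origin, anchor) < min_sep + 4.0
                for a in other_anchors
            ):
                continue
            return anchor
        return None


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.linalg.norm(p - a))
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_ground_truth(
    sim_params: SimulationParameters,
    analysis_params: AnalysisParameters | None = None,
    region_map: RegionMap | None = None,
) -> GroundTruth:
    """Simulate cell motion, visibility and drift, and derive the exact truth.

    The returned ground-truth (label, zone) series and events are computed by
    the pipeline's own classifier applied to the true (pre-drift) positions,
    so they are exact oracles for the downstream stages.
    """
    if analysis_params is None:
        analysis_params = AnalysisParameters(
            pixel_size_um=sim_params.pixel_size_um,
            frame_interval_s=sim_params.frame_interval_s,
        )
    if region_map is None:
        region_map = make_default_region_map(
            (sim_params.height, sim_params.width), sim_params.pixel_size_um
        )
    region_map.check_grid((sim_params.height, sim_params.width))
    rng = np.random.default_rng(np.random.SeedSequence([sim_params.rng_seed, 0]))
    n_cells, n_frames = sim_params.n_cells, sim_params.n_frames

    drift = np.arange(n_frames)[:, None] * np.asarray(sim_params.drift_per_frame, float)
    positions = np.zeros((n_cells, n_frames, 2))
    visible = np.ones((n_cells, n_frames), dtype=bool)
    states = np.zeros((n_cells, n_frames), dtype=int)
    switch = np.asarray(sim_params.switch_matrix, dtype=float)

    geometry = _AnchorGeometry(region_map, sim_params, analysis_params)
    min_sep = sim_params.min_cell_separation_px

    anchors: list[np.ndarray] = []
    cell_states = []
    for cid in range(n_cells):
        state = int(rng.choice(3, p=np.asarray(sim_params.initial_state_probs, float)))
        anchor = geometry.sample_anchor(
            state, rng.random() < sim_params.free_distal_prob, rng, anchors, min_sep, None
        )
        if anchor is None:
            raise ValidationError(
                "could not place non-overlapping cells; grid too crowded"
            )
        anchors.append(anchor)
        cell_states.append(state)
        positions[cid, 0] = anchor
        states[cid, 0] = state

    # per-cell transit bookkeeping: target anchor and pending state, or None
    transit_target: list[np.ndarray | None] = [None] * n_cells
    pending_state: list[int | None] = [None] * n_cells
    someone_in_transit = False
    # candidate travel steps: along-track length tweaks and lateral nudges so
    # that a frame never has to sit inside a zone-boundary shell, even when
    # the path runs parallel to an isodistance curve
    length_options = (0.0, 1.5, -1.5, 3.0, -3.0)
    lateral_options = (0.0, 2.0, -2.0, 4.0, -4.0)
    landing_reach = sim_params.travel_step_px + 4.0

    for t in range(1, n_frames):
        for cid in range(n_cells):
            pos = positions[cid, t - 1].copy()
            if transit_target[cid] is not None:
                target = transit_target[cid]
                to_go = target - pos
                dist = float(np.linalg.norm(to_go))
                if dist <= landing_reach:
                    pos = target.copy()
                    anchors[cid] = target
                    cell_states[cid] = pending_state[cid]
                    transit_target[cid] = None
                    pending_state[cid] = None
                    someone_in_transit = False
                else:
                    direction = to_go / dist
                    normal = np.array([-direction[1], direction[0]])
                    found = False
                    for lateral in lateral_options:
                        for extra in length_options:
                            step = sim_params.travel_step_px + extra
                            cand = pos + direction * step + normal * lateral
                            if not geometry.in_shell(cand[0], cand[1]):
                                pos = cand
                                found = True
                                break
                        if found:
                            break
                    if not found:  # pragma: no cover - shells are narrower than the sweep
                        pos = pos + direction * sim_params.travel_step_px
            else:
                state = cell_states[cid]
                nxt = int(rng.choice(3, p=switch[state]))
                if nxt != state and not someone_in_transit:
                    others = [a for j, a in enumerate(anchors) if j != cid]
                    target = geometry.sample_anchor(
                        nxt,
                        rng.random() < sim_params.free_distal_prob,
                        rng,
                        others,
                        min_sep,
                        pos,
                    )
                    if target is not None:
                        transit_target[cid] = target
                        pending_state[cid] = nxt
                        someone_in_transit = True
                # OU jitter around the current anchor (also on the switch frame:
                # travel begins next frame)
                sd = (
                    sim_params.step_sd_free_px
                    if cell_states[cid] == FREE
                    else sim_params.step_sd_dwell_px
                )
                pull = sim_params.anchor_pull
                pos = anchors[cid] + (1 - pull) * (pos - anchors[cid]) + rng.normal(0, sd, 2)
            pos[0] = np.clip(pos[0], 0.0, sim_params.width - 1.0)
            pos[1] = np.clip(pos[1], 0.0, sim_params.height - 1.0)
            positions[cid, t] = pos
            states[cid, t] = pending_state[cid] if transit_target[cid] is not None else cell_states[cid]

        # single-frame z-excursions: never at the endpoints, never two in a row,
        # and never while travelling (linear interpolation must stay accurate
        # and the linking gate must remain satisfiable across the gap)
        if 1 <= t < n_frames - 1:
            for cid in range(n_cells):
                if (
                    transit_target[cid] is None
                    and visible[cid, t - 1]
                    and rng.random() < sim_params.disappearance_prob
                ):
                    visible[cid, t] = False

    labelled, events = _true_labelling(positions, region_map, analysis_params)
    return GroundTruth(
        drift=drift,
        positions=positions,
        visible=visible,
        states=states,
        labelled=labelled,
        events=events,
        region_map=region_map,
        sim_params=sim_params,
        analysis_params=analysis_params,
    )


def _true_labelling(
    positions: np.ndarray, region_map: RegionMap, params: AnalysisParameters
) -> tuple[list[pd.DataFrame], list[list[InteractionEvent]]]:
    """Run the pipeline's own distance sampling + classifier on true positions."""
    n_cells = positions.shape[0]
    if n_cells == 0:
        return [], []
    v_field, e_field = region_distance_fields(region_map)
    labelled_all, events_all = [], []
    for cid in range(n_cells):
        track = Track(
            track_id=cid,
            samples=[
                TrackSample(t, float(positions[cid, t, 0]), float(positions[cid, t, 1]))
                for t in range(positions.shape[1])
            ],
        )
        series = sample_distances(track, v_field, e_field, params)
        labelled = label_timepoints(series, params)
        events = classify_durations(
            merge_transients(
                segment_events(labelled, params.frame_interval_s, track_id=cid), params
            ),
            params,
        )
        labelled_all.append(labelled)
        events_all.append(events)
    return labelled_all, events_all


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_movie(
    ground_truth: GroundTruth,
    sim_params: SimulationParameters,
    region_map: RegionMap | None = None,
) -> MovieStack:
    """Render the simulation as a noisy fluorescence movie.

    Each visible cell becomes an isotropic Gaussian spot at its drifted
    position; the niche structures are rendered as a dim static backdrop that
    drifts with the field (which is what makes drift estimable, as the
    counterlabelled microenvironment does in real movies).  Fractional drift
    is applied by shifting spot centres and bilinearly shifting the backdrop,
    never by resampling rendered frames, so the ground truth stays exact.
    """
    if region_map is None:
        region_map = ground_truth.region_map
    h, w = sim_params.height, sim_params.width
    region_map.check_grid((h, w))
    rng = np.random.default_rng(np.random.SeedSequence([sim_params.rng_seed, 1]))
    structure = (
        region_map.vascular_mask.astype(float) + region_map.endosteal_mask.astype(float)
    ) * sim_params.structure_level
    frames = np.zeros((sim_params.n_frames, h, w), dtype=np.float32)
    reach = max(1, int(np.ceil(4 * sim_params.spot_sigma_px)))
    for t in range(sim_params.n_frames):
        dx, dy = ground_truth.drift[t]
        canvas = np.full((h, w), sim_params.background_level, dtype=float)
        if sim_params.structure_level > 0:
            canvas += ndimage.shift(structure, (dy, dx), order=1, mode="constant", cval=0.0)
        for cid in range(ground_truth.n_cells):
            if not ground_truth.visible[cid, t]:
                continue
            cx = ground_truth.positions[cid, t, 0] + dx
            cy = ground_truth.positions[cid, t, 1] + dy
            x_lo, x_hi = int(np.floor(cx)) - reach, int(np.floor(cx)) + reach + 1
            y_lo, y_hi = int(np.floor(cy)) - reach, int(np.floor(cy)) + reach + 1
            x_lo, x_hi = max(0, x_lo), min(w, x_hi)
            y_lo, y_hi = max(0, y_lo), min(h, y_hi)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue  # spot centre off-grid: clipped, not an error
            yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
            canvas[y_lo:y_hi, x_lo:x_hi] += sim_params.spot_amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sim_params.spot_sigma_px**2)
            )
        if sim_params.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, sim_params.noise_sd, size=(h, w))
        frames[t] = np.clip(canvas, 0.0, None)
    return MovieStack(
        frames=frames,
        pixel_size_um=sim_params.pixel_size_um,
        frame_interval_s=sim_params.frame_interval_s,
        channel_name="synthetic",
    )


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------


def match_tracks_to_truth(
    tracks: list[Track], ground_truth: GroundTruth, tol_px: float = 1.0
) -> dict:
    """Match pipeline tracks to ground-truth cells and score frame recovery.

    Each track is assigned to the cell minimising its mean per-frame distance;
    a ground-truth (cell, frame) counts as recovered when an assigned track
    has a sample at that frame within ``tol_px`` of the true position.
    Returns the recovered fraction, the mean position error over recovered
    frames, and the track-to-cell assignment.
    """
    n_cells, n_frames = ground_truth.n_cells, ground_truth.n_frames
    assignment: dict[int, int] = {}
    recovered = np.zeros((n_cells, n_frames), dtype=bool)
    errors: list[float] = []
    for track in tracks:
        frames = track.frames
        pos = track.positions
        in_range = frames < n_frames
        if not in_range.any():
            continue
        mean_d = [
            float(
                np.linalg.norm(
                    pos[in_range] - ground_truth.positions[cid, frames[in_range]], axis=1
                ).mean()
            )
            for cid in range(n_cells)
        ]
        cid = int(np.argmin(mean_d))
        assignment[track.track_id] = cid
        err = np.linalg.norm(
            pos[in_range] - ground_truth.positions[cid, frames[in_range]], axis=1
        )
        ok = err <= tol_px
        recovered[cid, frames[in_range][ok]] = True
        errors.extend(err[ok].tolist())
    total = n_cells * n_frames
    return {
        "recovered_fraction": recovered.sum() / total if total else 1.0,
        "mean_error_px": float(np.mean(errors)) if errors else float("nan"),
        "assignment": assignment,
    }


def contact_dwell_scenario(
    rng_seed: int, target_fraction: float = 0.7, rate_scale: float = 0.05
) -> SimulationParameters:
    """Two-state scenario whose true vascular contact-time fraction targets a value.

    Cells alternate between a vascular-contact dwell and a distal free state
    with switch rates in the ratio that makes the dwell state's stationary
    occupancy equal ``target_fraction``; ``rate_scale`` sets how fast the
    chain mixes.  Used for parameter-recovery checks: the population mean of
    the estimated contact-time fraction should recover the target.
    """
    if not 0 < target_fraction < 1:
        raise ValidationError("target_fraction must lie in (0, 1)")
    p_leave = rate_scale * (1.0 - target_fraction)
    p_enter = rate_scale * target_fraction
    return SimulationParameters(
        rng_seed=rng_seed,
        switch_matrix=(
            (1.0 - p_leave, 0.0, p_leave),
            (0.0, 1.0, 0.0),
            (p_enter, 0.0, 1.0 - p_enter),
        ),
        initial_state_probs=(target_fraction, 0.0, 1.0 - target_fraction),
        free_distal_prob=1.0,
    )


def resolved_parameters(sim_params: SimulationParameters) -> dict:
    """The generator parameters as a plain dict (for the resolved run record)."""
    out = dataclasses.asdict(sim_params)
    out["switch_matrix"] = [list(row) for row in np.asarray(sim_params.switch_matrix)]
    return out
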
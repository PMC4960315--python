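"""Frame-to-frame linking of detections into tracks, track filtering, gap filling.

Linking follows the classic nearest-neighbour particle-tracking formulation:
for each consecutive frame the assignment between live tracks and new
detections minimises the total squared displacement, where any pairing
farther than ``max_link_displacement_px`` is forbidden and leaving a track or
detection unmatched costs ``max_link_displacement_px ** 2``.  A track that
misses a detection may coast for up to ``gap_memory_frames`` frames before it
is closed; the resulting single-frame holes are later filled by linear
interpolation, mirroring how brief z-excursions of a cell are handled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .io_formats import AnalysisParameters, validate_track_table
from .preprocess import Detection


@dataclass
class TrackSample:
    frame: int
    x_px: float
    y_px: float
    interpolated: bool = False


@dataclass
class Track:
    """A single cell's time-ordered positions."""

    track_id: int
    samples: list[TrackSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.samples]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError(f"track {self.track_id}: frames must be strictly increasing")

    @property
    def n_detected(self) -> int:
        """Number of genuinely detected (non-interpolated) samples."""
        return sum(not s.interpolated for s in self.samples)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.samples], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) pixel positions."""
        return np.array([[s.x_px, s.y_px] for s in self.samples], dtype=float)


def solve_frame_assignment(
    sources: np.ndarray, targets: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two point sets under a gating radius.

    Minimises the summed squared displacement plus ``max_disp ** 2`` for every
    unmatched source or target (so a link is only made when it beats leaving
    both endpoints unmatched).  Returns (source_index, target_index) pairs.
    """
    n_s, n_t = len(sources), len(targets)
    if n_s == 0 or n_t == 0:
        return []
    big = max_disp**2
    cost = np.full((n_s + n_t, n_t + n_s), np.inf)
    d2 = ((sources[:, None, :] - targets[None, :, :]) ** 2).sum(axis=2)
    link = np.where(d2 <= max_disp**2, d2, np.inf)
    cost[:n_s, :n_t] = link
    cost[np.arange(n_s), n_t + np.arange(n_s)] = big  # source left unmatched
    cost[n_s + np.arange(n_t), np.arange(n_t)] = big  # target starts fresh
    cost[n_s:, n_t:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < n_s and c < n_t]


def link_detections(
    detections_per_frame: list[list[Detection]], params: AnalysisParameters
) -> list[Track]:
    """Link per-frame detections into tracks.

    Track ids are assigned in order of first appearance (frame, then detection
    index), and assignment ties are resolved deterministically by the
    assignment solver operating on tracks sorted by id.
    """
    if not params.max_link_displacement_px > 0:
        raise ValidationError("max_link_displacement_px must be > 0")
    tracks: list[Track] = []
    # live track state: [track id, last x, last y, consecutive missed frames]
    live: list[list] = []
    for frame_idx, detections in enumerate(detections_per_frame):
        live = [state for state in live if state[3] <= params.gap_memory_frames]
        live.sort(key=lambda state: state[0])  # deterministic tie-breaking by track id
        sources = np.array([[s[1], s[2]] for s in live], dtype=float).reshape(-1, 2)
        targets = np.array([[d.x_px, d.y_px] for d in detections], dtype=float).reshape(-1, 2)
        pairs = solve_frame_assignment(sources, targets, params.max_link_displacement_px)
        matched_tracks = set()
        matched_dets = set()
        for src, tgt in pairs:
            track_idx = live[src][0]
            det = detections[tgt]
            tracks[track_idx].samples.append(TrackSample(frame_idx, det.x_px, det.y_px))
            live[src][1:] = [det.x_px, det.y_px, 0]
            matched_tracks.add(src)
            matched_dets.add(tgt)
        for state_idx, state in enumerate(live):
            if state_idx not in matched_tracks:
                state[3] += 1
        for det_idx, det in enumerate(detections):
            if det_idx not in matched_dets:
                track = Track(track_id=len(tracks))
                track.samples.append(TrackSample(frame_idx, det.x_px, det.y_px))
                tracks.append(track)
                live.append([track.track_id, det.x_px, det.y_px, 0])
    return tracks


def filter_short_tracks(tracks: list[Track], params: AnalysisParameters) -> list[Track]:
    """Keep only tracks with strictly more than ``min_track_frames`` detected frames."""
    return [t for t in tracks if t.n_detected > params.min_track_frames]


def fill_gaps(track: Track) -> Track:
    """Fill missing interior frames by linear interpolation between flanking detections.

    Inserted samples carry ``interpolated=True`` and lie exactly on the
    segment between their nearest detected neighbours; endpoints are never
    extrapolated and existing samples are preserved bit-exactly.
    """
    if len(track.samples) < 2:
        warnings.warn(f"track {track.track_id} has fewer than 2 samples; nothing to fill")
        return track
    filled: list[TrackSample] = []
    for prev, nxt in zip(track.samples, track.samples[1:]):
        filled.append(prev)
        span = nxt.frame - prev.frame
        for frame in range(prev.frame + 1, nxt.frame):
            w = (frame - prev.frame) / span
            filled.append(
                TrackSample(
                    frame=frame,
                    x_px=prev.x_px + w * (nxt.x_px - prev.x_px),
                    y_px=prev.y_px + w * (nxt.y_px - prev.y_px),
                    interpolated=True,
                )
            )
    filled.append(track.samples[-1])
    return Track(track_id=track.track_id, samples=filled)


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Convert tracks to the canonical track table (sorted, validated)."""
    rows = [
        (t.track_id, s.frame, s.x_px, s.y_px, s.interpolated)
        for t in tracks
        for s in t.samples
    ]
    table = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "interpolated"])
    return validate_track_table(table)


def table_to_tracks(table: pd.DataFrame) -> list[Track]:
    table = validate_track_table(table)
    tracks = []
    for track_id, group in table.groupby("track_id", sort=True):
        samples = [
            TrackSample(int(r.frame), float(r.x_px), float(r.y_px), bool(r.interpolated))
            for r in group.itertuples(index=False)
        ]
        tracks.append(Track(track_id=int(track_id), samples=samples))
    return tracks
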
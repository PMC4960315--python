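"""Per-cell and population statistics: velocity, displacement, dwell-time fractions,
interaction incidence, relative frequencies, distance histograms and occupancy maps.

Conventions: velocities are reported in μm/min from raw consecutive
displacements (interpolated samples included); "time near" a region is
defined directly from per-frame distances (within the proximal cutoff),
whereas contact/proximal time fractions use the hysteresis labelling, since
those quantify classified interactions.  All s.e.m. values are sd/sqrt(n)
with the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .interactions import ENDOSTEAL, InteractionEvent, NONE, VASCULAR
from .io_formats import AnalysisParameters
from .tracking import Track

UNDEFINED = float("nan")  # sentinel for ratios/means over an empty denominator


@dataclass
class CellMetrics:
    """Summary statistics for one tracked cell."""

    track_id: int
    mean_velocity_um_min: float
    normalized_avg_displacement_um_min: float
    fraction_time_near_vascular: float
    fraction_time_near_endosteal: float
    fraction_time_contact_vascular: float
    fraction_time_contact_endosteal: float
    fraction_time_proximal_vascular: float
    fraction_time_proximal_endosteal: float
    n_short_vascular: int = 0
    n_long_vascular: int = 0
    n_short_endosteal: int = 0
    n_long_endosteal: int = 0


def sem(values) -> float:
    """Standard error of the mean, sd(ddof=1)/sqrt(n); NaN for n < 2."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        return UNDEFINED
    return float(np.std(values, ddof=1) / np.sqrt(n))


def velocity_series(track: Track, params: AnalysisParameters) -> np.ndarray:
    """Instantaneous velocity in μm/min, defined from the second sample on."""
    if len(track.samples) < 2:
        raise ValidationError(f"track {track.track_id}: velocity undefined for < 2 samples")
    pos = track.positions
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1) * params.pixel_size_um
    dt_min = np.diff(track.frames) * params.frame_interval_s / 60.0
    return steps / dt_min


def mean_velocity_by_group(
    tracks: list[Track], group_labels: list[str], params: AnalysisParameters
) -> pd.DataFrame:
    """Group mean ± s.e.m. of per-track mean velocities (e.g. marrow vs vessel)."""
    if len(tracks) != len(group_labels):
        raise ValidationError("one group label per track is required")
    per_track = pd.DataFrame(
        {
            "group": group_labels,
            "mean_velocity_um_min": [
                float(np.mean(velocity_series(t, params))) for t in tracks
            ],
        }
    )
    rows = []
    for group, sub in per_track.groupby("group", sort=True):
        vals = sub["mean_velocity_um_min"].to_numpy()
        if vals.size == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"group {group!r} is empty; omitted")
            continue
        rows.append(
            {
                "group": group,
                "mean_velocity_um_min": float(vals.mean()),
                "sem_um_min": sem(vals),
                "n_cells": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def normalized_displacement(track: Track, params: AnalysisParameters) -> float:
    """Mean displacement from the first position, per minute of observation.

    Displacement at time t is the distance (μm) between the position at t and
    the first recorded position; the average over all t > 0 is divided by the
    total time the cell was observed, in minutes.
    """
    if len(track.samples) < 2:
        raise ValidationError(
            f"track {track.track_id}: displacement undefined for < 2 samples"
        )
    pos = track.positions
    disp = np.linalg.norm(pos[1:] - pos[0], axis=1) * params.pixel_size_um
    frames = track.frames
    total_min = (frames[-1] - frames[0]) * params.frame_interval_s / 60.0
    return float(disp.mean() / total_min)


def time_fractions(labelled: pd.DataFrame, params: AnalysisParameters) -> dict[str, float]:
    """Per-cell time fractions from a labelled zone series.

    ``near_*`` fractions count frames with the per-frame distance within the
    proximal cutoff; ``contact_*`` / ``proximal_*`` fractions count frames by
    their hysteresis (label, zone) classification.  For each region, the
    distance-based contact/proximal/distal fractions partition to 1.
    """
    n = len(labelled)
    if n == 0:
        raise ValidationError("empty zone series")
    d_v = labelled["d_v_um"].to_numpy(dtype=float)
    d_e = labelled["d_e_um"].to_numpy(dtype=float)
    out: dict[str, float] = {
        "near_vascular": float(np.mean(d_v <= params.proximal_cutoff_um)),
        "near_endosteal": float(np.mean(d_e <= params.proximal_cutoff_um)),
    }
    for region, d in ((VASCULAR, d_v), (ENDOSTEAL, d_e)):
        out[f"dist_contact_{region}"] = float(np.mean(d <= params.contact_cutoff_um))
        out[f"dist_proximal_{region}"] = float(
            np.mean((d > params.contact_cutoff_um) & (d <= params.proximal_cutoff_um))
        )
        out[f"dist_distal_{region}"] = float(np.mean(d > params.proximal_cutoff_um))
    labels = labelled["label"].to_numpy()
    zones = labelled["zone"].to_numpy()
    for region in (VASCULAR, ENDOSTEAL):
        out[f"contact_{region}"] = float(np.mean((labels == region) & (zones == "contact")))
        out[f"proximal_{region}"] = float(np.mean((labels == region) & (zones == "proximal")))
    return out


def cell_metrics(
    track: Track,
    labelled: pd.DataFrame,
    events: list[InteractionEvent],
    params: AnalysisParameters,
) -> CellMetrics:
    """Assemble the per-cell summary from track, labelled series and merged events."""
    fractions = time_fractions(labelled, params)
    counts = {(VASCULAR, "short"): 0, (VASCULAR, "long"): 0,
              (ENDOSTEAL, "short"): 0, (ENDOSTEAL, "long"): 0}
    for event in events:
        if event.label != NONE and event.duration_class is not None:
            counts[(event.label, event.duration_class)] += 1
    return CellMetrics(
        track_id=track.track_id,
        mean_velocity_um_min=float(np.mean(velocity_series(track, params))),
        normalized_avg_displacement_um_min=normalized_displacement(track, params),
        fraction_time_near_vascular=fractions["near_vascular"],
        fraction_time_near_endosteal=fractions["near_endosteal"],
        fraction_time_contact_vascular=fractions["contact_vascular"],
        fraction_time_contact_endosteal=fractions["contact_endosteal"],
        fraction_time_proximal_vascular=fractions["proximal_vascular"],
        fraction_time_proximal_endosteal=fractions["proximal_endosteal"],
        n_short_vascular=counts[(VASCULAR, "short")],
        n_long_vascular=counts[(VASCULAR, "long")],
        n_short_endosteal=counts[(ENDOSTEAL, "short")],
        n_long_endosteal=counts[(ENDOSTEAL, "long")],
    )


def incidence_per_cell(
    events: list[InteractionEvent], cell_ids: list[int] | None = None
) -> pd.DataFrame:
    """Mean ± s.e.m. over cells of per-cell event counts, by (region, duration class).

    ``cell_ids`` fixes the population (cells with zero events still count);
    by default the cells present in the event list are used.
    """
    if cell_ids is None:
        cell_ids = sorted({e.track_id for e in events})
    rows = []
    for region in (VASCULAR, ENDOSTEAL):
        for duration_class in ("short", "long"):
            counts = [
                sum(
                    1
                    for e in events
                    if e.track_id == cid
                    and e.label == region
                    and e.duration_class == duration_class
                )
                for cid in cell_ids
            ]
            rows.append(
                {
                    "region": region,
                    "duration_class": duration_class,
                    "mean_incidence_per_cell": float(np.mean(counts)) if counts else 0.0,
                    "sem": sem(counts),
                    "n_cells": len(cell_ids),
                }
            )
    return pd.DataFrame(rows)


def relative_frequency(
    events: list[InteractionEvent],
    zone: str,
    params: AnalysisParameters,
    mode: str = "time",
) -> float:
    """Vascular/endosteal frequency ratio for one zone.

    ``mode='time'`` (default) weights events by duration; ``mode='count'``
    uses event counts.  A zero endosteal denominator yields the NaN sentinel
    with a warning, never an exception.
    """
    if mode not in ("time", "count"):
        raise ValidationError(f"mode must be 'time' or 'count', got {mode!r}")

    def total(region: str) -> float:
        selected = [e for e in events if e.label == region and e.zone == zone]
        return sum(e.duration_s for e in selected) if mode == "time" else float(len(selected))

    numer, denom = total(VASCULAR), total(ENDOSTEAL)
    if denom == 0:
        warnings.warn(f"no endosteal {zone} events: relative frequency undefined")
        return UNDEFINED
    return numer / denom


def distance_histogram(
    distances_um, bin_width_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of cell-frame distances with right-open bins of fixed width.

    Returns (counts, bin_edges); the counts always sum to the number of
    cell-frames (the final bin is closed above so the maximum is included).
    """
    if not bin_width_um > 0:
        raise ValidationError("bin_width_um must be > 0")
    distances = np.asarray(distances_um, dtype=float)
    upper = max(float(distances.max()) if distances.size else 0.0, bin_width_um)
    n_bins = int(np.ceil(upper / bin_width_um))
    edges = np.arange(n_bins + 1) * bin_width_um
    if edges[-1] < upper:  # guard against float round-off at the top edge
        edges = np.append(edges, edges[-1] + bin_width_um)
    counts, edges = np.histogram(distances, bins=edges)
    return counts, edges


def zone_incidence_and_mean_distance(
    distances_um, params: AnalysisParameters
) -> pd.DataFrame:
    """Counts of cells per zone and the mean ± s.e.m. distance within each zone.

    Accepts one representative distance per cell (static snapshots are series
    of length 1).  Empty zones report count 0 and a NaN mean.
    """
    from .niche_geometry import classify_zone

    distances = np.asarray(distances_um, dtype=float)
    zones = classify_zone(distances, params) if distances.size else np.array([])
    rows = []
    for zone in ("contact", "proximal", "distal"):
        in_zone = distances[zones == zone] if distances.size else np.array([])
        rows.append(
            {
                "zone": zone,
                "n_cells": int(in_zone.size),
                "mean_distance_um": float(in_zone.mean()) if in_zone.size else UNDEFINED,
                "sem_um": sem(in_zone),
            }
        )
    return pd.DataFrame(rows)


def occupancy_map(
    tracks: list[Track], grid_shape: tuple[int, int], smoothing_sigma_px: float = 0.0
) -> np.ndarray:
    """Probability map of cell presence: 2D histogram of all cell-frames,
    Gaussian-smoothed, normalised to sum to 1."""
    h, w = grid_shape
    grid = np.zeros((h, w), dtype=float)
    for track in tracks:
        pos = track.positions
        cols = np.clip(np.round(pos[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.round(pos[:, 1]).astype(int), 0, h - 1)
        np.add.at(grid, (rows, cols), 1.0)
    if smoothing_sigma_px > 0:
        grid = ndimage.gaussian_filter(grid, sigma=smoothing_sigma_px)
    total = grid.sum()
    if total > 0:
        grid /= total
    return grid
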
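"""End-to-end orchestration: simulate / preprocess / track / classify / metrics.

One configuration drives a run; every stage writes its outputs as CSV/TIFF
under the output directory and the resolved configuration plus input digests,
stage timings and audit counts end up in ``manifest.json``.  Re-running with
the same configuration and seed reproduces the CSV outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .interactions import (
    classify_durations,
    count_periods,
    events_to_table,
    label_timepoints,
    merge_transients,
    segment_events,
)
from .io_formats import (
    AnalysisParameters,
    MovieStack,
    RegionMap,
    dump_params,
    params_from_dict,
    read_movie,
    read_region_maps,
    write_events,
    write_movie,
    write_region_maps,
    write_tracks,
)
from .metrics import cell_metrics, incidence_per_cell, relative_frequency
from .niche_geometry import region_distance_fields, sample_distances
from .preprocess import correct_drift, detect_movie, estimate_drift
from .synthetic_data import (
    SimulationParameters,
    render_movie,
    resolved_parameters,
    simulate_ground_truth,
)
from .tracking import (
    Track,
    fill_gaps,
    filter_short_tracks,
    link_detections,
    tracks_to_table,
)

logger = logging.getLogger("nichetrack")


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it."""

    parameters: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def track_movie(
    movie: MovieStack, params: AnalysisParameters, drift_correction: bool = True
) -> tuple[pd.DataFrame, list[Track], dict]:
    """Drift-correct, detect and link a movie into gap-filled tracks.

    Returns the track table, the track objects, and stage audit counts.
    """
    counts: dict[str, int] = {"frames": movie.n_frames}
    residual = None
    if drift_correction:
        drift = estimate_drift(movie, subpixel=True)
        movie = correct_drift(movie, drift)
        residual = drift.residual()
        counts["max_drift_px"] = int(np.abs(drift.rounded()).max())
    detections = detect_movie(movie, params)
    if residual is not None:
        # integer translation leaves a sub-pixel remainder common to every
        # object in a frame; remove it from the detected centroids
        for per_frame in detections:
            for det in per_frame:
                det.x_px -= residual[det.frame_index, 0]
                det.y_px -= residual[det.frame_index, 1]
    counts["detections"] = sum(len(d) for d in detections)
    tracks = link_detections(detections, params)
    counts["tracks_linked"] = len(tracks)
    kept = filter_short_tracks(tracks, params)
    counts["tracks_kept"] = len(kept)
    counts["tracks_dropped"] = len(tracks) - len(kept)
    filled = [fill_gaps(t) for t in kept]
    return tracks_to_table(filled), filled, counts


def classify_tracks(
    tracks: list[Track], region_map: RegionMap, params: AnalysisParameters
) -> tuple[pd.DataFrame, dict[int, list], dict]:
    """Distance sampling, hysteresis labelling, segmentation and merging.

    Returns the labelled per-frame zone table, merged duration-classed events
    per track, and audit counts.
    """
    if region_map.vascular_empty or region_map.endosteal_empty:
        raise ValidationError(
            "both a vascular and an endosteal annotation are required for classification"
        )
    v_field, e_field = region_distance_fields(region_map)
    labelled_frames = []
    events_by_track: dict[int, list] = {}
    n_before = n_after = 0
    for track in tracks:
        series = sample_distances(track, v_field, e_field, params)
        labelled = label_timepoints(series, params)
        labelled_frames.append(labelled)
        raw = segment_events(labelled, params.frame_interval_s, track_id=track.track_id)
        merged = merge_transients(raw, params)
        n_before += len(raw)
        n_after += len(merged)
        events_by_track[track.track_id] = classify_durations(merged, params)
    zones = (
        pd.concat(labelled_frames, ignore_index=True)
        if labelled_frames
        else pd.DataFrame(columns=["track_id", "frame", "t_s", "d_v_um", "d_e_um", "label", "zone"])
    )
    counts = {"events_before_merge": n_before, "events_after_merge": n_after}
    return zones, events_by_track, counts


def summarize(
    tracks: list[Track],
    zones: pd.DataFrame,
    events_by_track: dict[int, list],
    params: AnalysisParameters,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell metrics table and population summary table."""
    all_events = [e for evs in events_by_track.values() for e in evs]
    per_cell = pd.DataFrame(
        [
            dataclasses.asdict(
                cell_metrics(
                    track,
                    zones[zones["track_id"] == track.track_id],
                    events_by_track.get(track.track_id, []),
                    params,
                )
            )
            for track in tracks
        ]
    )
    incidence = incidence_per_cell(all_events, cell_ids=[t.track_id for t in tracks])
    n_interaction, n_none = count_periods(all_events)
    summary_rows = [
        {"quantity": "n_interaction_periods", "value": float(n_interaction)},
        {"quantity": "n_no_interaction_periods", "value": float(n_none)},
        {
            "quantity": "relative_contact_frequency_v_over_e",
            "value": relative_frequency(all_events, "contact", params),
        },
        {
            "quantity": "relative_proximal_frequency_v_over_e",
            "value": relative_frequency(all_events, "proximal", params),
        },
    ]
    for row in incidence.itertuples(index=False):
        summary_rows.append(
            {
                "quantity": f"incidence_{row.region}_{row.duration_class}",
                "value": row.mean_incidence_per_cell,
            }
        )
    return per_cell, pd.DataFrame(summary_rows)


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline described by a configuration mapping.

    The configuration either carries a ``simulation`` section (synthetic run)
    or ``inputs`` with ``movie``, ``vascular_mask`` and ``endosteal_mask``
    paths; ``analysis`` holds :class:`AnalysisParameters` overrides.  All
    inputs are validated before any compute starts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis_cfg = dict(config.get("analysis", {}))
    sim_cfg = config.get("simulation")
    inputs_cfg = config.get("inputs")
    if (sim_cfg is None) == (inputs_cfg is None):
        raise ValidationError("config must define exactly one of 'simulation' or 'inputs'")

    manifest = RunManifest(parameters={}, seed=int(analysis_cfg.get("rng_seed", 0)))
    timings = manifest.stage_seconds

    if sim_cfg is not None:
        sim_params = SimulationParameters(**sim_cfg)
        params = params_from_dict(
            {
                "pixel_size_um": sim_params.pixel_size_um,
                "frame_interval_s": sim_params.frame_interval_s,
                "intensity_threshold": sim_params.spot_amplitude / 2.0,
                **analysis_cfg,
            }
        )
        t0 = time.perf_counter()
        ground_truth = simulate_ground_truth(sim_params, params)
        movie = render_movie(ground_truth, sim_params)
        region_map = ground_truth.region_map
        write_movie(movie, out_dir / "movie.tif")
        write_region_maps(
            region_map, out_dir / "vascular_mask.tif", out_dir / "endosteal_mask.tif"
        )
        write_tracks(ground_truth.track_table(), out_dir / "true_tracks.csv")
        write_events(
            events_to_table(ground_truth.all_events()), out_dir / "true_events.csv"
        )
        with open(out_dir / "simulation.json", "w", encoding="utf-8") as handle:
            json.dump(resolved_parameters(sim_params), handle, indent=2)
        timings["simulate"] = time.perf_counter() - t0
        logger.info("simulate: %d frames, %d cells", sim_params.n_frames, sim_params.n_cells)
    else:
        for key in ("movie", "vascular_mask", "endosteal_mask"):
            if key not in inputs_cfg or not Path(inputs_cfg[key]).exists():
                raise ValidationError(f"input '{key}' missing or does not exist")
        if "pixel_size_um" not in analysis_cfg or "frame_interval_s" not in analysis_cfg:
            raise ValidationError(
                "analysis.pixel_size_um and analysis.frame_interval_s are required "
                "for real movies (calibration is never read from TIFF tags)"
            )
        params = params_from_dict(analysis_cfg)
        movie = read_movie(
            inputs_cfg["movie"], params.pixel_size_um, params.frame_interval_s
        )
        region_map = read_region_maps(
            inputs_cfg["vascular_mask"],
            inputs_cfg["endosteal_mask"],
            params.pixel_size_um,
            expected_shape=movie.shape,
        )
        manifest.input_digests = {
            key: _sha256(Path(inputs_cfg[key]))
            for key in ("movie", "vascular_mask", "endosteal_mask")
        }

    if params.intensity_threshold is None:
        raise ValidationError("analysis.intensity_threshold is required")
    if region_map.vascular_empty or region_map.endosteal_empty:
        raise ValidationError("classification requires nonempty vascular and endosteal masks")
    manifest.parameters = dataclasses.asdict(params)
    dump_params(params, out_dir / "resolved_params.yaml")

    t0 = time.perf_counter()
    track_table, tracks, track_counts = track_movie(movie, params)
    write_tracks(track_table, out_dir / "tracks.csv")
    timings["track"] = time.perf_counter() - t0
    logger.info(
        "track: %(detections)d detections -> %(tracks_kept)d tracks kept "
        "(%(tracks_dropped)d dropped)",
        track_counts,
    )

    t0 = time.perf_counter()
    zones, events_by_track, event_counts = classify_tracks(tracks, region_map, params)
    zones.to_csv(out_dir / "zones.csv", index=False)
    all_events = [e for evs in events_by_track.values() for e in evs]
    write_events(events_to_table(all_events), out_dir / "events.csv")
    timings["classify"] = time.perf_counter() - t0
    logger.info(
        "classify: %(events_before_merge)d events -> %(events_after_merge)d after merging",
        event_counts,
    )

    t0 = time.perf_counter()
    per_cell, summary = summarize(tracks, zones, events_by_track, params)
    per_cell.to_csv(out_dir / "metrics.csv", index=False)
    summary.to_csv(out_dir / "summary.csv", index=False)
    timings["metrics"] = time.perf_counter() - t0

    manifest.counts = {**track_counts, **event_counts}
    manifest.outputs = {
        name: str(out_dir / name)
        for name in ("tracks.csv", "zones.csv", "events.csv", "metrics.csv", "summary.csv")
    }
    manifest.write(out_dir / "manifest.json")
    return manifest
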
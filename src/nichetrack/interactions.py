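"""Per-frame niche labelling with hysteresis and segmentation into interaction events.

Each tracked frame is labelled with the nearest niche region (vascular or
endosteal) and a zone (contact or proximal); frames farther than the
proximal cutoff from both regions carry the label *none* (no interaction).
Zone changes pass through a Schmitt trigger: a state is entered at the
nominal cutoff but only left once the distance exceeds the cutoff by more
than the hysteresis margin, which suppresses classification flicker when a
cell sits near a boundary.  Maximal runs of constant (label, zone) become
interaction events; adjacent transient events shorter than the merge window
are absorbed into their matching neighbours; finally events are classed
*short* or *long* by duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AnalysisParameters

VASCULAR = "vascular"
ENDOSTEAL = "endosteal"
NONE = "none"
CONTACT = "contact"
PROXIMAL = "proximal"


@dataclass(frozen=True)
class InteractionEvent:
    """A maximal period during which one track holds a constant (label, zone).

    ``duration_s = end_s - start_s + frame_interval_s``: an event of a single
    frame still occupies one frame interval, so the durations of a track's
    events tile its observed span exactly.
    """

    track_id: int
    label: str  # vascular | endosteal | none
    zone: str | None  # contact | proximal | None (when label == none)
    start_s: float
    end_s: float
    duration_s: float
    duration_class: str | None = None  # short | long | None


def _nominal_state(d: float, label: str, params: AnalysisParameters) -> tuple[str, str | None]:
    if d <= params.contact_cutoff_um:
        return label, CONTACT
    if d <= params.proximal_cutoff_um:
        return label, PROXIMAL
    return NONE, None


def label_timepoints(zone_series: pd.DataFrame, params: AnalysisParameters) -> pd.DataFrame:
    """Assign (label, zone) to every frame of one track's distance series.

    The candidate label of a frame is the region with the smaller distance
    (ties keep the previous frame's label, or default to vascular at frame 0).
    Entering a zone uses the nominal cutoffs; leaving the current zone toward
    a larger distance requires the distance to exceed the cutoff by more than
    ``hysteresis_um``.  Frame 0 is classified with the nominal cutoffs.
    """
    required = {"d_v_um", "d_e_um"}
    if not required.issubset(zone_series.columns):
        raise ValidationError(f"zone series must carry columns {sorted(required)}")
    d_v = zone_series["d_v_um"].to_numpy(dtype=float)
    d_e = zone_series["d_e_um"].to_numpy(dtype=float)
    if np.any(~np.isfinite(d_v)) or np.any(~np.isfinite(d_e)):
        raise ValidationError("distances must be present and finite at every frame")
    eps = params.hysteresis_um
    d_c, d_p = params.contact_cutoff_um, params.proximal_cutoff_um

    labels: list[str] = []
    zones: list[str | None] = []
    prev_label: str | None = None
    prev_zone: str | None = None
    for i in range(len(d_v)):
        dv, de = d_v[i], d_e[i]
        if dv < de:
            cand = VASCULAR
        elif de < dv:
            cand = ENDOSTEAL
        else:  # exact tie: keep the previous region label, else vascular
            cand = prev_label if prev_label in (VASCULAR, ENDOSTEAL) else VASCULAR
        d = dv if cand == VASCULAR else de

        if prev_label is None:
            label, zone = _nominal_state(d, cand, params)
        elif prev_label == NONE:
            # entering an interaction uses the nominal cutoffs
            if d <= d_p:
                label, zone = _nominal_state(d, cand, params)
            else:
                label, zone = NONE, None
        elif cand == prev_label:
            if prev_zone == CONTACT:
                if d > d_p + eps:
                    label, zone = NONE, None
                elif d > d_c + eps:
                    label, zone = cand, PROXIMAL
                else:
                    label, zone = cand, CONTACT
            else:  # proximal
                if d <= d_c:
                    label, zone = cand, CONTACT
                elif d > d_p + eps:
                    label, zone = NONE, None
                else:
                    label, zone = cand, PROXIMAL
        else:
            # the nearest region changed while interacting
            if d <= d_p:
                label, zone = _nominal_state(d, cand, params)
            else:
                # both regions beyond the proximal cutoff: leave to "none" only
                # once the held region's distance clears the hysteresis margin
                d_prev = dv if prev_label == VASCULAR else de
                if d_prev > d_p + eps:
                    label, zone = NONE, None
                else:
                    label, zone = prev_label, prev_zone
        labels.append(label)
        zones.append(zone)
        prev_label, prev_zone = label, zone

    out = zone_series.copy()
    out["label"] = labels
    out["zone"] = zones
    return out


def segment_events(
    labelled: pd.DataFrame, frame_interval_s: float, track_id: int | None = None
) -> list[InteractionEvent]:
    """Cut a labelled series into maximal runs of constant (label, zone)."""
    if len(labelled) == 0:
        return []
    if track_id is None:
        track_id = int(labelled["track_id"].iloc[0]) if "track_id" in labelled else 0
    t = labelled["t_s"].to_numpy(dtype=float)
    labels = labelled["label"].tolist()
    zones = labelled["zone"].tolist()
    events: list[InteractionEvent] = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or (labels[i], zones[i]) != (labels[run_start], zones[run_start]):
            start_s, end_s = float(t[run_start]), float(t[i - 1])
            events.append(
                InteractionEvent(
                    track_id=track_id,
                    label=labels[run_start],
                    zone=zones[run_start],
                    start_s=start_s,
                    end_s=end_s,
                    duration_s=end_s - start_s + frame_interval_s,
                )
            )
            run_start = i
    return events


def _fuse(events: list[InteractionEvent], lo: int, hi: int,
          label: str, zone: str | None) -> list[InteractionEvent]:
    """Replace events[lo:hi+1] by a single event with the given state."""
    span = events[lo : hi + 1]
    fused = InteractionEvent(
        track_id=span[0].track_id,
        label=label,
        zone=zone,
        start_s=span[0].start_s,
        end_s=span[-1].end_s,
        duration_s=sum(e.duration_s for e in span),
    )
    return events[:lo] + [fused] + events[hi + 1 :]


def _coalesce(events: list[InteractionEvent]) -> list[InteractionEvent]:
    """Fuse adjacent events that ended up with identical (label, zone)."""
    i = 0
    while i < len(events) - 1:
        if (events[i].label, events[i].zone) == (events[i + 1].label, events[i + 1].zone):
            events = _fuse(events, i, i + 1, events[i].label, events[i].zone)
        else:
            i += 1
    return events


def merge_transients(
    events: list[InteractionEvent], params: AnalysisParameters
) -> list[InteractionEvent]:
    """Absorb transient events (duration < ``merge_window_s``) into their neighbours.

    A transient flanked by two events that share one (label, zone) fuses with
    both; a transient at a track edge is absorbed into its single neighbour.
    Transients flanked by two different states are kept.  The pass repeats
    until no eligible transient remains; total duration is conserved and the
    operation is idempotent.
    """
    events = _coalesce(list(events))
    changed = True
    while changed:
        changed = False
        for i, event in enumerate(events):
            if event.duration_s >= params.merge_window_s:
                continue
            left = events[i - 1] if i > 0 else None
            right = events[i + 1] if i < len(events) - 1 else None
            if left is not None and right is not None:
                if (left.label, left.zone) == (right.label, right.zone):
                    events = _fuse(events, i - 1, i + 1, left.label, left.zone)
                    changed = True
                    break
            elif left is not None:
                events = _fuse(events, i - 1, i, left.label, left.zone)
                changed = True
                break
            elif right is not None:
                events = _fuse(events, i, i + 1, right.label, right.zone)
                changed = True
                break
        if changed:
            events = _coalesce(events)
    return events


def classify_durations(
    events: list[InteractionEvent], params: AnalysisParameters
) -> list[InteractionEvent]:
    """Class interactions as short (< ``long_duration_min`` min) or long (>= it).

    Periods with label *none* carry no duration class.
    """
    threshold_s = params.long_duration_min * 60.0
    out = []
    for event in events:
        if event.label == NONE:
            out.append(replace(event, duration_class=None))
        elif event.duration_s < threshold_s:
            out.append(replace(event, duration_class="short"))
        else:
            out.append(replace(event, duration_class="long"))
    return out


def count_periods(events: list[InteractionEvent]) -> tuple[int, int]:
    """(number of interaction periods, number of no-interaction periods)."""
    n_interaction = sum(1 for e in events if e.label in (VASCULAR, ENDOSTEAL))
    n_none = sum(1 for e in events if e.label == NONE)
    return n_interaction, n_none


def events_to_table(events: list[InteractionEvent]) -> pd.DataFrame:
    """Convert events to the on-disk event table schema."""
    return pd.DataFrame(
        [
            {
                "track_id": e.track_id,
                "label": e.label,
                "zone": e.zone,
                "start_s": e.start_s,
                "end_s": e.end_s,
                "duration_s": e.duration_s,
                "duration_class": e.duration_class,
            }
            for e in events
        ],
        columns=[
            "track_id",
            "label",
            "zone",
            "start_s",
            "end_s",
            "duration_s",
            "duration_class",
        ],
    )


def table_to_events(table: pd.DataFrame) -> list[InteractionEvent]:
    events = []
    for row in table.itertuples(index=False):
        zone = row.zone if isinstance(row.zone, str) and row.zone else None
        cls = (
            row.duration_class
            if isinstance(row.duration_class, str) and row.duration_class
            else None
        )
        events.append(
            InteractionEvent(
                track_id=int(row.track_id),
                label=str(row.label),
                zone=zone,
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                duration_s=float(row.duration_s),
                duration_class=cls,
            )
        )
    return events
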
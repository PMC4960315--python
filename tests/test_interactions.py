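"""Hysteresis labelling, event segmentation, transient merging and counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nichetrack.interactions import (
    InteractionEvent,
    classify_durations,
    count_periods,
    events_to_table,
    label_timepoints,
    merge_transients,
    segment_events,
    table_to_events,
)
from nichetrack.io_formats import AnalysisParameters


def _series(d_v, d_e, dt=10.0):
    n = len(d_v)
    return pd.DataFrame(
        {
            "track_id": 0,
            "frame": np.arange(n),
            "t_s": np.arange(n) * dt,
            "d_v_um": np.asarray(d_v, dtype=float),
            "d_e_um": np.asarray(d_e, dtype=float),
        }
    )


def _events(run_list, dt=10.0, track_id=0):
    """Build a tiling event list from (label, zone, duration_s) triples."""
    events, t = [], 0.0
    for label, zone, duration in run_list:
        events.append(
            InteractionEvent(track_id, label, zone, t, t + duration - dt, duration)
        )
        t += duration
    return events


class TestLabelling:
    def test_nearest_region_and_zone(self, params):
        out = label_timepoints(_series([3.0], [40.0]), params)
        assert (out["label"][0], out["zone"][0]) == ("vascular", "contact")

    def test_exact_tie_at_frame_zero_defaults_to_vascular(self, params):
        out = label_timepoints(_series([10.0], [10.0]), params)
        assert (out["label"][0], out["zone"][0]) == ("vascular", "proximal")

    def test_tie_keeps_previous_label(self, params):
        out = label_timepoints(_series([12.0, 10.0], [8.0, 10.0]), params)
        assert list(out["label"]) == ["endosteal", "endosteal"]

    def test_flicker_around_contact_cutoff_suppressed(self, params):
        # oscillation between 4.5 and 5.5 um around the 5 um cutoff with a
        # 1 um margin: leaving contact would require d > 6, so the cell
        # remains in contact throughout
        d_v = [4.5, 5.5] * 5
        out = label_timepoints(_series(d_v, [40.0] * 10), params)
        assert (out["zone"] == "contact").all()

    def test_leaving_contact_requires_cutoff_plus_margin(self, params):
        out = label_timepoints(_series([4.0, 5.9, 6.1], [40.0] * 3), params)
        assert list(out["zone"]) == ["contact", "contact", "proximal"]

    def test_entering_contact_uses_nominal_cutoff(self, params):
        out = label_timepoints(_series([10.0, 5.0], [40.0] * 2), params)
        assert list(out["zone"]) == ["proximal", "contact"]

    def test_leaving_interaction_to_none_requires_margin(self, params):
        out = label_timepoints(_series([24.0, 25.9, 26.1], [40.0] * 3), params)
        assert list(out["label"]) == ["vascular", "vascular", "none"]

    def test_none_iff_both_distances_beyond_proximal_cutoff(self, params):
        rng = np.random.default_rng(0)
        d_v = rng.uniform(0, 60, 200)
        d_e = rng.uniform(0, 60, 200)
        out = label_timepoints(_series(d_v, d_e), params)
        none_rows = out["label"] == "none"
        assert (out.loc[none_rows, ["d_v_um", "d_e_um"]].min(axis=1)
                > params.proximal_cutoff_um).all()

    def test_zero_hysteresis_differs_only_near_boundaries(self):
        rng = np.random.default_rng(1)
        d_v = rng.uniform(0, 35, 300)
        d_e = np.full(300, 60.0)
        series = _series(d_v, d_e)
        with_eps = label_timepoints(series, AnalysisParameters(hysteresis_um=1.0))
        without = label_timepoints(series, AnalysisParameters(hysteresis_um=0.0))
        differs = (with_eps["zone"].to_numpy() != without["zone"].to_numpy()) | (
            with_eps["label"].to_numpy() != without["label"].to_numpy()
        )
        near_boundary = (np.abs(d_v - 5.0) <= 1.0) | (np.abs(d_v - 25.0) <= 1.0)
        assert not (differs & ~near_boundary).any()

    def test_missing_distance_rejected(self, params):
        series = _series([1.0, np.nan], [2.0, 2.0])
        with pytest.raises(Exception):
            label_timepoints(series, params)


class TestSegmentation:
    def test_constant_run_single_event(self, params):
        series = label_timepoints(_series([2.0] * 100, [50.0] * 100), params)
        (event,) = segment_events(series, 10.0)
        assert (event.label, event.zone) == ("vascular", "contact")
        assert event.duration_s == 1000.0

    def test_three_phase_trace_yields_three_events(self, params):
        # contact with the vasculature, then proximal to it, then proximal to
        # the endosteal region
        d_v = [2.0] * 5 + [15.0] * 5 + [40.0] * 5
        d_e = [60.0] * 10 + [15.0] * 5
        series = label_timepoints(_series(d_v, d_e), params)
        events = segment_events(series, 10.0)
        assert [(e.label, e.zone) for e in events] == [
            ("vascular", "contact"),
            ("vascular", "proximal"),
            ("endosteal", "proximal"),
        ]

    def test_empty_series(self, params):
        assert segment_events(_series([], []), 10.0) == []

    def test_events_tile_the_observed_span(self, params):
        rng = np.random.default_rng(2)
        series = label_timepoints(
            _series(rng.uniform(0, 40, 50), rng.uniform(0, 40, 50)), params
        )
        events = segment_events(series, 10.0)
        assert sum(e.duration_s for e in events) == pytest.approx(500.0)
        for prev, nxt in zip(events, events[1:]):
            assert nxt.start_s == prev.end_s + 10.0


class TestMerging:
    def test_short_none_between_matching_contacts_fuses(self, params):
        events = _events(
            [("vascular", "contact", 300.0), ("none", None, 100.0),
             ("vascular", "contact", 300.0)]
        )
        (merged,) = merge_transients(events, params)
        assert (merged.label, merged.zone, merged.duration_s) == (
            "vascular", "contact", 700.0
        )

    def test_transient_with_mismatched_flanks_kept(self, params):
        events = _events(
            [("endosteal", "proximal", 400.0), ("vascular", "contact", 150.0),
             ("none", None, 400.0)]
        )
        merged = merge_transients(events, params)
        assert [(e.label, e.zone) for e in merged] == [
            ("endosteal", "proximal"), ("vascular", "contact"), ("none", None)
        ]

    def test_edge_transient_absorbed_into_neighbour(self, params):
        events = _events([("none", None, 50.0), ("vascular", "contact", 900.0)])
        (merged,) = merge_transients(events, params)
        assert (merged.label, merged.zone, merged.start_s, merged.duration_s) == (
            "vascular", "contact", 0.0, 950.0
        )

    def test_all_long_events_unchanged(self, params):
        events = _events(
            [("vascular", "contact", 300.0), ("endosteal", "proximal", 250.0),
             ("none", None, 200.0)]
        )
        assert merge_transients(events, params) == events

    @given(
        st.lists(
            st.tuples(st.sampled_from([
                ("vascular", "contact"), ("vascular", "proximal"),
                ("endosteal", "contact"), ("endosteal", "proximal"),
                ("none", None),
            ]), st.integers(min_value=1, max_value=40)),
            min_size=1,
            max_size=12,
        )
    )
    def test_merging_conserves_time_and_is_idempotent(self, runs):
        params = AnalysisParameters()
        run_list = [(label, zone, frames * 10.0) for (label, zone), frames in runs]
        events = _events(run_list)
        merged = merge_transients(events, params)
        total = sum(d for _, _, d in run_list)
        assert sum(e.duration_s for e in merged) == pytest.approx(total)
        assert merge_transients(merged, params) == merged
        assert len(merged) <= len(events)
        for prev, nxt in zip(merged, merged[1:]):
            assert (prev.label, prev.zone) != (nxt.label, nxt.zone)


class TestDurationsAndCounts:
    def test_thirty_minute_contact_is_short(self, params):
        (event,) = classify_durations(_events([("vascular", "contact", 1800.0)]), params)
        assert event.duration_class == "short"

    def test_sixty_one_minutes_is_long_and_boundary_is_long(self, params):
        events = _events(
            [("vascular", "contact", 61 * 60.0), ("endosteal", "proximal", 3600.0)]
        )
        classed = classify_durations(events, params)
        assert [e.duration_class for e in classed] == ["long", "long"]

    def test_none_periods_carry_no_class(self, params):
        (event,) = classify_durations(_events([("none", None, 7200.0)]), params)
        assert event.duration_class is None

    def test_count_periods(self, params):
        events = _events(
            [("vascular", "contact", 300.0)] * 3
            + [("endosteal", "proximal", 300.0)] * 2
            + [("none", None, 300.0)]
        )
        assert count_periods(events) == (5, 1)

    def test_count_empty_and_always_distal(self, params):
        assert count_periods([]) == (0, 0)
        assert count_periods(_events([("none", None, 2000.0)])) == (0, 1)


def test_event_table_round_trip(tmp_path, params):
    from nichetrack.io_formats import read_events, write_events

    events = classify_durations(
        _events(
            [("vascular", "contact", 4000.0), ("none", None, 300.0),
             ("endosteal", "proximal", 600.0)]
        ),
        params,
    )
    path = tmp_path / "events.csv"
    write_events(events_to_table(events), path)
    assert table_to_events(read_events(path)) == events
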
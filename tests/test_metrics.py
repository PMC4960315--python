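"""Per-cell and population statistics."""

import numpy as np
import pandas as pd
import pytest

from nichetrack.errors import ValidationError
from nichetrack.interactions import InteractionEvent
from nichetrack.io_formats import AnalysisParameters
from nichetrack.metrics import (
    distance_histogram,
    incidence_per_cell,
    mean_velocity_by_group,
    normalized_displacement,
    occupancy_map,
    relative_frequency,
    sem,
    time_fractions,
    velocity_series,
    zone_incidence_and_mean_distance,
)
from nichetrack.tracking import Track, TrackSample


def _track(xs, ys=None, track_id=0):
    ys = ys if ys is not None else [0.0] * len(xs)
    return Track(track_id, [TrackSample(t, float(x), float(y))
                            for t, (x, y) in enumerate(zip(xs, ys))])


def _event(track_id, label, zone, duration_s, duration_class=None, start_s=0.0):
    return InteractionEvent(
        track_id, label, zone, start_s, start_s + duration_s - 10.0, duration_s,
        duration_class,
    )


class TestVelocity:
    def test_stationary_track_all_zero(self, params):
        assert (velocity_series(_track([5.0] * 6), params) == 0).all()

    def test_two_pixels_per_frame_is_twelve_um_per_min(self):
        params = AnalysisParameters(pixel_size_um=1.0, frame_interval_s=10.0)
        track = _track([0, 2, 4, 6])
        np.testing.assert_allclose(velocity_series(track, params), 12.0)

    def test_single_sample_errors(self, params):
        with pytest.raises(ValidationError, match="velocity undefined"):
            velocity_series(_track([1.0]), params)

    def test_group_means_and_sem(self, params):
        # per-track means 6 and 12 -> group mean 9, s.e.m. 3
        t1 = _track([0, 1, 2, 3])  # 1 px / 10 s = 6 um/min
        t2 = _track([0, 2, 4, 6])  # 12 um/min
        t3 = _track([0, 0.5, 1.0])  # separate group
        out = mean_velocity_by_group([t1, t2, t3], ["marrow", "marrow", "vessel"], params)
        marrow = out[out["group"] == "marrow"].iloc[0]
        assert marrow["mean_velocity_um_min"] == pytest.approx(9.0)
        assert marrow["sem_um_min"] == pytest.approx(3.0)
        assert set(out["group"]) == {"marrow", "vessel"}  # no pooling


class TestDisplacement:
    def test_stationary_is_zero(self, params):
        assert normalized_displacement(_track([3.0] * 5), params) == 0.0

    def test_straight_motion_reference_value(self):
        # 1 um/frame over 10 intervals at 10 s/frame: mean displacement over
        # t>0 is mean(1..10) = 5.5 um, observed span 100 s -> 3.3 um/min
        params = AnalysisParameters(pixel_size_um=1.0, frame_interval_s=10.0)
        track = _track(list(range(11)))
        assert normalized_displacement(track, params) == pytest.approx(3.3)

    def test_invariant_under_rotation(self, params, rng):
        xy = rng.random((8, 2)) * 20
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        track_a = _track(xy[:, 0], xy[:, 1])
        rotated = xy @ rot.T
        track_b = _track(rotated[:, 0], rotated[:, 1])
        assert normalized_displacement(track_a, params) == pytest.approx(
            normalized_displacement(track_b, params)
        )


class TestTimeFractions:
    def _labelled(self, d_v, d_e, labels, zones):
        return pd.DataFrame(
            {"d_v_um": d_v, "d_e_um": d_e, "label": labels, "zone": zones}
        )

    def test_always_near_vascular_never_near_endosteal(self, params):
        lab = self._labelled([2.0] * 4, [50.0] * 4, ["vascular"] * 4, ["contact"] * 4)
        out = time_fractions(lab, params)
        assert out["near_vascular"] == 1.0
        assert out["near_endosteal"] == 0.0
        assert out["contact_vascular"] == 1.0

    def test_half_near(self, params):
        lab = self._labelled(
            [10.0, 10.0, 40.0, 40.0], [50.0] * 4,
            ["vascular", "vascular", "none", "none"],
            ["proximal", "proximal", None, None],
        )
        assert time_fractions(lab, params)["near_vascular"] == 0.5

    def test_distance_zone_fractions_partition(self, params, rng):
        n = 50
        lab = self._labelled(
            rng.uniform(0, 60, n), rng.uniform(0, 60, n), ["none"] * n, [None] * n
        )
        out = time_fractions(lab, params)
        for region in ("vascular", "endosteal"):
            total = (
                out[f"dist_contact_{region}"]
                + out[f"dist_proximal_{region}"]
                + out[f"dist_distal_{region}"]
            )
            assert total == pytest.approx(1.0, abs=1e-9)


class TestIncidence:
    def test_single_cell_two_short_vascular_events(self):
        events = [_event(0, "vascular", "contact", 300.0, "short")] * 2
        out = incidence_per_cell(events)
        row = out[(out.region == "vascular") & (out.duration_class == "short")].iloc[0]
        assert row["mean_incidence_per_cell"] == 2.0

    def test_mean_and_sem_over_two_cells(self):
        events = [_event(0, "vascular", "contact", 300.0, "short")] + [
            _event(1, "vascular", "contact", 300.0, "short")
        ] * 3
        out = incidence_per_cell(events, cell_ids=[0, 1])
        row = out[(out.region == "vascular") & (out.duration_class == "short")].iloc[0]
        assert row["mean_incidence_per_cell"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0)  # sd([1, 3])/sqrt(2)

    def test_absent_region_reports_zero(self):
        events = [_event(0, "vascular", "contact", 300.0, "short")]
        out = incidence_per_cell(events)
        endo = out[out.region == "endosteal"]
        assert (endo["mean_incidence_per_cell"] == 0).all()


class TestRelativeFrequency:
    def test_time_weighted_ratio(self, params):
        events = [
            _event(0, "vascular", "contact", 100.0),
            _event(1, "endosteal", "contact", 50.0),
        ]
        assert relative_frequency(events, "contact", params) == pytest.approx(2.0)

    def test_zero_denominator_yields_nan_sentinel(self, params):
        events = [_event(0, "vascular", "contact", 100.0)]
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(relative_frequency(events, "contact", params))

    def test_equal_times_give_one_and_count_mode(self, params):
        events = [
            _event(0, "vascular", "contact", 300.0),
            _event(1, "endosteal", "contact", 300.0),
        ]
        assert relative_frequency(events, "contact", params) == 1.0
        assert relative_frequency(events, "contact", params, mode="count") == 1.0


class TestHistogramAndZones:
    def test_all_mass_in_first_bin(self):
        counts, edges = distance_histogram(np.zeros(17), 5.0)
        assert counts[0] == 17 and counts.sum() == 17

    def test_counts_sum_to_frames(self, rng):
        d = rng.uniform(0, 80, 500)
        counts, _ = distance_histogram(d, 2.5)
        assert counts.sum() == 500

    def test_uniform_distances_approximately_flat(self, rng):
        d = rng.uniform(0, 100, 20000)
        counts, edges = distance_histogram(d, 10.0)
        counts = counts[:10]
        expected = 20000 / 10
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < 30  # chi2_{0.999, 9} = 27.9

    def test_zone_incidence_counts_and_means(self, params):
        out = zone_incidence_and_mean_distance([2.0, 10.0, 40.0], params)
        assert list(out["n_cells"]) == [1, 1, 1]
        assert list(out["mean_distance_um"]) == [2.0, 10.0, 40.0]

    def test_all_contact_and_empty_zone_sentinel(self, params):
        out = zone_incidence_and_mean_distance([1.0, 2.0, 3.0], params)
        assert list(out["n_cells"]) == [3, 0, 0]
        assert np.isnan(out["mean_distance_um"].iloc[1])

    def test_zone_means_ordered(self, params, rng):
        out = zone_incidence_and_mean_distance(rng.uniform(0, 60, 200), params)
        means = out["mean_distance_um"].to_numpy()
        assert means[0] <= means[1] <= means[2]


class TestOccupancy:
    def test_single_stationary_cell_single_pixel(self):
        grid = occupancy_map([_track([7.0] * 5, [9.0] * 5)], (16, 16))
        assert grid[9, 7] == 1.0 and grid.sum() == 1.0

    def test_smoothed_map_sums_to_one_and_keeps_maximum(self, rng):
        cluster = rng.normal(30, 1.5, size=(40, 2))
        track = _track(cluster[:, 0], cluster[:, 1])
        grid = occupancy_map([track], (64, 64), smoothing_sigma_px=2.0)
        assert grid.sum() == pytest.approx(1.0)
        peak = np.unravel_index(grid.argmax(), grid.shape)
        assert abs(peak[0] - 30) <= 2 and abs(peak[1] - 30) <= 2


def test_sem_matches_two_pass_computation(rng):
    values = rng.random(37) * 10
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    assert sem(values) == pytest.approx(np.sqrt(var / n))
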
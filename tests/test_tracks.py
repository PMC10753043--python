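"""Track IO, cleaning, visit segmentation and behavioral metrics."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mozsight import (
    CleaningConfig,
    Track,
    TrackParseError,
    build_cuboid,
    filter_outliers,
    heatmap_density,
    interpolate_gaps,
    no_target_cuboid,
    read_tracks,
    segment_visits,
    smooth_track,
    summarize_target,
    visit_metrics,
    write_tracks,
)


def make_track(frames, xyz, track_id="t1", rate=50.0):
    frames = np.asarray(frames)
    return Track(track_id, frames, np.asarray(xyz, dtype=float),
                 np.zeros(len(frames), dtype=bool), frame_rate_hz=rate)


def straight_track(n=100, start=(30.0, 30.0, 30.0), step=(0.2, 0.3, 0.1)):
    frames = np.arange(n)
    xyz = np.asarray(start) + frames[:, None] * np.asarray(step)
    return make_track(frames, xyz)


class TestReadTracks:
    def test_two_tracks_with_unsorted_frames(self):
        rows = ["track_id,frame,x,y,z"]
        for tid in ("a", "b"):
            for f in reversed(range(100)):
                rows.append(f"{tid},{f},{10 + f * 0.1},{20},{30}")
        tracks = read_tracks(io.StringIO("\n".join(rows)))
        assert [t.track_id for t in tracks] == ["a", "b"]
        for t in tracks:
            assert t.n_points == 100
            assert np.all(np.diff(t.frames) > 0)
            assert not t.interpolated.any()

    def test_tab_separated_input(self):
        text = "track_id\tframe\tx\ty\tz\nt\t0\t1\t2\t3\nt\t1\t1.1\t2\t3\n"
        (track,) = read_tracks(io.StringIO(text))
        assert track.n_points == 2

    def test_non_numeric_coordinate_names_the_line(self):
        text = "track_id,frame,x,y,z\nt,0,1,2,3\nt,1,1,NA,3\n"
        with pytest.raises(TrackParseError, match=r"line\(s\) 3"):
            read_tracks(io.StringIO(text))

    def test_missing_column_is_reported(self):
        with pytest.raises(TrackParseError, match="z"):
            read_tracks(io.StringIO("track_id,frame,x,y\nt,0,1,2\n"))

    def test_write_read_round_trip(self, tmp_path):
        track = straight_track(20)
        path = tmp_path / "tracks.csv"
        write_tracks([track], path)
        (back,) = read_tracks(path)
        assert np.allclose(back.xyz, track.xyz)
        assert np.array_equal(back.frames, track.frames)


class TestFilterOutliers:
    def test_constant_velocity_track_is_untouched(self):
        track = straight_track()  # |v| = sqrt(0.2^2+0.3^2+0.1^2)*50 ~ 19 cm/s
        out = filter_outliers(track)
        assert out.n_points == track.n_points

    def test_isolated_spike_is_removed_and_neighbors_kept(self):
        track = straight_track()
        track.xyz[50] += np.array([50.0, 0.0, 0.0])  # 2500 cm/s to both sides
        out = filter_outliers(track)
        assert out.n_points == 99
        assert 50 not in out.frames

    def test_point_outside_arena_is_removed(self):
        track = straight_track()
        track.xyz[10, 2] = -5.0
        out = filter_outliers(track)
        assert 10 not in out.frames
        assert out.n_points == 99

    def test_idempotent(self, rng):
        xyz = 30 + np.cumsum(rng.normal(0, 0.5, size=(200, 3)), axis=0)
        track = make_track(np.arange(200), xyz)
        spikes = [20, 77, 150]
        for s in spikes:
            track.xyz[s] += rng.normal(0, 60, size=3)
        once = filter_outliers(track)
        twice = filter_outliers(once)
        assert np.array_equal(once.frames, twice.frames)
        assert np.allclose(once.xyz, twice.xyz)


class TestInterpolateGaps:
    def test_short_gap_filled_exactly_on_the_line(self):
        track = straight_track(20)
        keep = ~np.isin(track.frames, [7, 8, 9])
        gappy = make_track(track.frames[keep], track.xyz[keep])
        (out,) = interpolate_gaps(gappy)
        assert out.n_points == 20
        full = straight_track(20)
        assert np.allclose(out.xyz, full.xyz, atol=1e-12)
        assert np.array_equal(np.flatnonzero(out.interpolated), [7, 8, 9])

    def test_long_gap_splits_the_track(self):
        track = straight_track(30)
        keep = ~np.isin(track.frames, [10, 11, 12, 13, 14, 15])  # 6 missing
        gappy = make_track(track.frames[keep], track.xyz[keep])
        parts = interpolate_gaps(gappy)
        assert len(parts) == 2
        assert [p.track_id for p in parts] == ["t1.1", "t1.2"]
        assert parts[0].n_points == 10 and parts[1].n_points == 14
        assert not any(p.interpolated.any() for p in parts)

    def test_gapless_track_is_identity(self):
        track = straight_track(15)
        (out,) = interpolate_gaps(track)
        assert out.track_id == "t1"
        assert np.allclose(out.xyz, track.xyz)

    def test_idempotent(self):
        track = straight_track(40)
        keep = ~np.isin(track.frames, [5, 6, 20])
        gappy = make_track(track.frames[keep], track.xyz[keep])
        once = interpolate_gaps(gappy)
        twice = [p for t in once for p in interpolate_gaps(t)]
        assert len(once) == len(twice) == 1
        assert np.allclose(once[0].xyz, twice[0].xyz)
        assert np.array_equal(once[0].interpolated, twice[0].interpolated)


class TestSmoothTrack:
    def test_zero_parameter_reproduces_input(self, rng):
        xyz = 40 + np.cumsum(rng.normal(0, 0.5, size=(50, 3)), axis=0)
        track = make_track(np.arange(50), xyz)
        out = smooth_track(track, CleaningConfig(smoothing_parameter=0.0))
        assert np.allclose(out.xyz, track.xyz, atol=1e-8)
        assert out.smoothed

    def test_straight_line_is_invariant(self):
        track = straight_track(60)
        out = smooth_track(track, CleaningConfig(smoothing_parameter=1.0))
        assert np.allclose(out.xyz, track.xyz, atol=1e-6)

    def test_noise_on_a_sine_is_reduced(self, rng):
        frames = np.arange(300)
        t = frames / 50.0
        clean = np.column_stack([60 + 10 * np.sin(2 * np.pi * 0.5 * t),
                                 np.full_like(t, 100.0),
                                 60 + 5 * np.cos(2 * np.pi * 0.5 * t)])
        noisy = clean + rng.normal(0, 0.3, size=clean.shape)
        track = make_track(frames, noisy)
        out = smooth_track(track, CleaningConfig(smoothing_parameter=0.09))
        rms_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_after = np.sqrt(np.mean((out.xyz - clean) ** 2))
        assert rms_after < rms_before

    def test_short_track_returned_unsmoothed_with_warning(self):
        track = straight_track(3)
        with pytest.warns(UserWarning, match="too short"):
            out = smooth_track(track)
        assert not out.smoothed
        assert np.allclose(out.xyz, track.xyz)


class TestCuboids:
    def test_buffer_and_height_for_horizontal_target(self):
        cub = build_cuboid((45.0, 75.0), (130.0, 170.0), "horizontal")
        assert cub.x_range == (35.0, 85.0)    # 30 -> 50 cm
        assert cub.y_range == (120.0, 180.0)  # 40 -> 60 cm
        assert cub.z_range == (0.0, 30.0)

    def test_vertical_target_height_and_plane(self):
        cub = build_cuboid((45.0, 75.0), (149.0, 151.0), "vertical")
        assert cub.z_range == (0.0, 60.0)
        assert cub.plane_y == 150.0

    def test_zero_buffer_equals_footprint(self):
        cub = build_cuboid((45.0, 75.0), (130.0, 170.0), "horizontal",
                           buffer_cm=0.0)
        assert cub.x_range == (45.0, 75.0) and cub.y_range == (130.0, 170.0)

    def test_footprint_near_wall_is_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            cub = build_cuboid((0.0, 30.0), (130.0, 170.0), "horizontal")
        assert cub.x_range[0] == 0.0

    def test_no_target_control_matches_large_target_dimensions(self):
        cub = no_target_cuboid()
        assert cub.x_range[1] - cub.x_range[0] == 50.0
        assert cub.y_range[1] - cub.y_range[0] == 60.0
        assert cub.z_range == (0.0, 30.0)
        assert cub.y_range[1] < 100.0  # downwind half of the arena


class TestVisits:
    def cuboid(self):
        return build_cuboid((45.0, 75.0), (130.0, 170.0), "horizontal")

    def through_track(self):
        # along y at fixed x/z inside the footprint; crosses the cuboid twice
        n = 300
        y = np.concatenate([np.linspace(100, 190, 100),
                            np.linspace(190, 100, 100),
                            np.linspace(100, 60, 100)])
        xyz = np.column_stack([np.full(n, 60.0), y, np.full(n, 15.0)])
        return make_track(np.arange(n), xyz)

    def test_track_through_the_cuboid_twice_gives_two_visits(self):
        visits = segment_visits(self.through_track(), self.cuboid())
        assert len(visits) == 2
        for v in visits:
            assert v.label == "target"
            assert v.duration_s > 0

    def test_track_never_entering_gives_no_visits(self):
        track = straight_track(50, start=(10.0, 10.0, 80.0), step=(0.1, 0.1, 0.0))
        assert segment_visits(track, self.cuboid()) == []

    def test_single_inside_point_is_discarded(self):
        xyz = np.array([[60.0, 100.0, 15.0], [60.0, 150.0, 15.0],
                        [60.0, 190.0, 15.0]])
        track = make_track([0, 1, 2], xyz)
        assert segment_visits(track, self.cuboid()) == []

    def test_half_open_membership_excludes_the_upper_face(self):
        cub = self.cuboid()
        on_top = np.array([[60.0, 150.0, 30.0], [60.0, 150.0, 30.0]])
        inside = np.array([[60.0, 150.0, 29.9], [60.0, 150.0, 29.9]])
        assert not cub.contains(on_top).any()
        assert cub.contains(inside).all()

    def test_upwind_downwind_labeling_for_vertical_targets(self):
        cub = build_cuboid((45.0, 75.0), (149.0, 151.0), "vertical")
        frames = np.arange(10)
        up = np.column_stack([np.full(10, 60.0), np.linspace(152, 158, 10),
                              np.full(10, 20.0)])
        down = np.column_stack([np.full(10, 60.0), np.linspace(148, 142, 10),
                                np.full(10, 20.0)])
        (vu,) = segment_visits(make_track(frames, up), cub)
        (vd,) = segment_visits(make_track(frames, down), cub)
        assert vu.side == "upwind" and vd.side == "downwind"


class TestVisitMetrics:
    def test_straight_segment_at_constant_speed(self):
        frames = np.arange(51)
        xyz = np.column_stack([np.zeros(51), frames * 24.0 / 50.0, np.zeros(51)])
        m = visit_metrics(xyz, frames, 50.0)
        assert m["duration_s"] == pytest.approx(1.0)
        assert m["path_length_cm"] == pytest.approx(24.0)
        assert m["tortuosity"] == pytest.approx(1.0)
        assert m["mean_speed_cms"] == pytest.approx(24.0)

    def test_out_and_back_has_undefined_tortuosity(self):
        y = np.concatenate([np.linspace(0, 10, 11), np.linspace(9, 0, 10)])
        xyz = np.column_stack([np.zeros(21), y, np.zeros(21)])
        m = visit_metrics(xyz, np.arange(21), 50.0)
        assert math.isnan(m["tortuosity"])
        assert m["path_length_cm"] == pytest.approx(20.0)

    def test_right_angle_path(self):
        leg1 = np.column_stack([np.linspace(0, 30, 31), np.zeros(31), np.zeros(31)])
        leg2 = np.column_stack([np.full(30, 30.0), np.linspace(1, 30, 30),
                                np.zeros(30)])
        xyz = np.vstack([leg1, leg2])
        m = visit_metrics(xyz, np.arange(61), 50.0)
        assert m["path_length_cm"] == pytest.approx(60.0)
        assert m["chord_cm"] == pytest.approx(42.43, abs=0.01)
        assert m["tortuosity"] == pytest.approx(math.sqrt(2), abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    def test_path_is_never_shorter_than_the_chord(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        xyz = np.cumsum(rng.normal(0, 1.0, size=(n, 3)), axis=0)
        m = visit_metrics(xyz, np.arange(n), 50.0)
        assert m["path_length_cm"] >= m["chord_cm"] - 1e-9
        if not math.isnan(m["tortuosity"]):
            assert m["tortuosity"] >= 1.0 - 1e-9


class TestSummaries:
    def visit(self, duration, path, chord=None, side=None):
        from mozsight import Visit
        chord = path / 1.5 if chord is None else chord
        return Visit("t", "target", 0, 10, np.arange(2), np.zeros((2, 3)),
                     duration, path, chord, path / chord if chord else float("nan"),
                     path / duration, side)

    @pytest.mark.parametrize("landings,area,expected", [
        (4, 1200.0, 0.333), (2, 300.0, 0.667)])
    def test_landing_density_per_100cm2(self, landings, area, expected):
        summary = summarize_target([self.visit(1.0, 30.0)], landings, area)
        assert summary.landing_density_per_100cm2 == pytest.approx(expected, abs=5e-4)

    def test_totals_are_sums_over_visits(self):
        visits = [self.visit(1.0, 30.0), self.visit(2.0, 50.0)]
        summary = summarize_target(visits, 0, 1200.0)
        assert summary.n_visits == 2
        assert summary.total_time_s == pytest.approx(3.0)
        assert summary.total_distance_cm == pytest.approx(80.0)

    def test_no_visits_zero_landings(self):
        summary = summarize_target([], 0, 300.0, label="empty")
        assert summary.n_visits == 0
        assert summary.total_time_s == 0.0
        assert summary.landing_density_per_100cm2 == 0.0

    def test_zero_area_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="area"):
            summarize_target([], 0, 0.0, label="bad")

    def test_upwind_downwind_breakdown(self):
        visits = [self.visit(1.0, 30.0, side="upwind"),
                  self.visit(2.0, 40.0, side="downwind"),
                  self.visit(3.0, 50.0, side="downwind")]
        summary = summarize_target(visits, 0, 1200.0)
        assert summary.n_visits_upwind == 1
        assert summary.n_visits_downwind == 2
        assert summary.time_downwind_s == pytest.approx(5.0)
        assert summary.distance_upwind_cm == pytest.approx(30.0)


class TestHeatmap:
    def test_grid_sums_to_point_count(self, rng):
        tracks = []
        for i in range(3):
            xyz = np.column_stack([rng.uniform(0, 120, 100),
                                   rng.uniform(0, 200, 100),
                                   rng.uniform(0, 120, 100)])
            tracks.append(make_track(np.arange(100), xyz, track_id=f"t{i}"))
        grid, _, _ = heatmap_density(tracks, "XY", bin_cm=2.0)
        assert grid.sum() == 300

    def test_all_points_in_one_bin(self):
        xyz = np.tile([[10.5, 20.5, 30.5]], (25, 1))
        grid, _, _ = heatmap_density([make_track(np.arange(25), xyz)], "YZ", 2.0)
        assert (grid > 0).sum() == 1
        assert grid.max() == 25

    def test_empty_input_gives_zero_grid(self):
        grid, ex, ey = heatmap_density([], "XY", 5.0)
        assert grid.sum() == 0
        assert grid.shape == (len(ex) - 1, len(ey) - 1)
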
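"""Kymographs, track linking and axis projection."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from stereomotion.kymotrack import (
    Kymograph, OrganellePath, Track, build_kymograph, link_tracks,
    project_to_axis, tracks_to_csv,
)
from stereomotion.simcore import (MotilityModel, PhotophysicsModel,
                                  SimulationConfig, StereociliumGeometry,
                                  Movie, simulate_movie)
from stereomotion.spots import SpotDetection, detect_puncta

PX = 162.5


def _axis_path(length_px=200, y=20.0, half_width=2.0):
    return OrganellePath(control_points=[(2.0, y), (2.0 + length_px, y)],
                         half_width=half_width, pixel_size=PX)


def _detections(positions_by_frame):
    """positions_by_frame: list of [(x, y), ...] per frame."""
    return {t: [SpotDetection(frame=t, x=float(x), y=float(y))
                for x, y in pts]
            for t, pts in enumerate(positions_by_frame)}


class TestOrganellePath:
    def test_needs_two_distinct_points(self):
        with pytest.raises(ValueError):
            OrganellePath(control_points=[(1.0, 1.0)])
        with pytest.raises(ValueError, match="zero arc length"):
            OrganellePath(control_points=[(1.0, 1.0), (1.0, 1.0)])

    def test_arc_length_calibration(self):
        p = _axis_path(length_px=100)
        assert p.length_nm == pytest.approx(100 * PX)

    def test_json_roundtrip(self, tmp_path):
        p = _axis_path()
        p.to_json(tmp_path / "p.json")
        q = OrganellePath.from_json(tmp_path / "p.json")
        np.testing.assert_allclose(q.control_points, p.control_points)
        assert q.half_width == p.half_width


class TestKymograph:
    def _render_movie(self, emitters, n_frames=30, shape=(48, 256)):
        geo = StereociliumGeometry((325.0, 3250.0), (39000.0, 3250.0))
        cfg = SimulationConfig(image_shape=shape, n_frames=n_frames,
                               quantal_yield=1000.0, seed=1)
        return simulate_movie(cfg, geo, emitters)[0]

    def test_static_emitter_constant_bright_row(self):
        movie = self._render_movie([(MotilityModel(mode="static"),
                                     PhotophysicsModel(), 16250.0)])
        path = OrganellePath(control_points=[(2.0, 20.0), (239.0, 20.0)],
                             half_width=2.0, pixel_size=PX)
        kymo = build_kymograph(movie, path)
        assert kymo.data.shape[1] == movie.n_frames
        rows = kymo.data.argmax(axis=0)
        assert np.all(rows == rows[0])

    def test_moving_emitter_slope_matches_velocity(self):
        v = 500.0  # nm/s -> ~3 px/frame
        movie = self._render_movie(
            [(MotilityModel(mode="processive", speed=v),
              PhotophysicsModel(), 2000.0)], n_frames=40)
        path = OrganellePath(control_points=[(2.0, 20.0), (239.0, 20.0)],
                             half_width=2.0, pixel_size=PX)
        kymo = build_kymograph(movie, path)
        rows = kymo.data.argmax(axis=0)
        slope = np.polyfit(np.arange(len(rows)), rows * kymo.nm_per_row, 1)[0]
        assert slope == pytest.approx(v, rel=0.05)

    def test_empty_movie_background_only(self):
        movie = self._render_movie([], n_frames=5)
        path = OrganellePath(control_points=[(2.0, 20.0), (239.0, 20.0)],
                             half_width=2.0, pixel_size=PX)
        kymo = build_kymograph(movie, path)
        # all values near the camera baseline, no bright streaks
        assert kymo.data.max() < 140.0  # offset 100 + background + noise

    def test_path_outside_frame_rejected(self):
        movie = self._render_movie([], n_frames=2)
        path = OrganellePath(control_points=[(2.0, 20.0), (500.0, 20.0)])
        with pytest.raises(ValueError, match="outside"):
            build_kymograph(movie, path)

    def test_exports(self, tmp_path):
        movie = self._render_movie([], n_frames=3)
        path = OrganellePath(control_points=[(2.0, 20.0), (100.0, 20.0)],
                             pixel_size=PX)
        kymo = build_kymograph(movie, path)
        kymo.to_tiff(tmp_path / "k.tif")
        kymo.to_png(tmp_path / "k.png")
        assert (tmp_path / "k.tif").exists() and (tmp_path / "k.png").exists()


class TestLinking:
    def test_single_emitter_single_track(self):
        dets = _detections([[(10.0 + t, 5.0)] for t in range(20)])
        tracks = link_tracks(dets, max_jump_nm=500.0, pixel_size=PX)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 20

    def test_two_static_emitters_no_swaps(self):
        dets = _detections([[(10.0, 5.0), (30.0, 5.0)] for _ in range(15)])
        tracks = link_tracks(dets, max_jump_nm=500.0, pixel_size=PX)
        assert len(tracks) == 2
        for tr in tracks:
            xs = tr.xy[:, 0]
            assert np.all(xs == xs[0])

    def test_gap_closing_bridges_missed_frames(self):
        pts = [[(10.0, 5.0)]] * 5 + [[]] + [[(10.0, 5.0)]] * 5
        tracks = link_tracks(_detections(pts), max_jump_nm=500.0, max_gap=2,
                             pixel_size=PX)
        assert len(tracks) == 1
        assert tracks[0].n_gaps == 1

    def test_crossing_trajectories_match_optimal_assignment(self):
        # brute-force minimum-total-displacement oracle per frame
        rng = np.random.default_rng(2)
        true = np.array([[5.0 + 0.4 * t for t in range(30)],
                         [17.0 - 0.4 * t for t in range(30)],
                         [3.0 + 0.1 * t for t in range(30)]])  # x per frame
        ys = [2.0, 6.0, 10.0]
        frames = [[(true[i][t], ys[i]) for i in range(3)] for t in range(30)]
        tracks = link_tracks(_detections(frames), max_jump_nm=1e6,
                             pixel_size=PX)
        assert len(tracks) == 3
        # oracle: frame-by-frame optimal assignment starting from frame 0
        oracle = {i: [frames[0][i]] for i in range(3)}
        for t in range(1, 30):
            prev = np.array([oracle[i][-1] for i in range(3)])
            cur = np.array(frames[t])
            cost = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
            rr, cc = linear_sum_assignment(cost)
            for i, j in zip(rr, cc):
                oracle[i].append(tuple(cur[j]))
        for tr in tracks:
            i = ys.index(tr.detections[0].y)
            got = [(d.x, d.y) for d in tr.detections]
            assert got == oracle[i]

    def test_empty_input_empty_output(self):
        assert link_tracks({}) == []


class TestProjection:
    def test_control_point_maps_to_its_arc_length(self):
        path = OrganellePath(control_points=[(0.0, 0.0), (10.0, 0.0),
                                             (10.0, 10.0)], pixel_size=PX)
        tr = Track(track_id=0,
                   detections=[SpotDetection(frame=0, x=10.0, y=0.0)])
        s = project_to_axis(tr, path)
        assert s[0] == pytest.approx(10.0 * PX, abs=PX * 0.3)

    def test_perpendicular_offset_removed(self):
        path = _axis_path(half_width=3.0)
        tr = Track(track_id=0,
                   detections=[SpotDetection(frame=0, x=52.0, y=20.0),
                               SpotDetection(frame=1, x=52.0, y=21.5)])
        s = project_to_axis(tr, path)
        assert s[1] == pytest.approx(s[0], abs=PX * 0.3)

    def test_far_detection_excluded(self):
        path = _axis_path(half_width=2.0)
        tr = Track(track_id=0,
                   detections=[SpotDetection(frame=0, x=52.0, y=30.0)])
        s = project_to_axis(tr, path)
        assert np.isnan(s[0])
        assert tr.excluded[0]

    def test_processive_groundtruth_recovery(self):
        # end-to-end: simulate, detect, link, project; compare with truth
        geo = StereociliumGeometry((325.0, 3250.0), (39000.0, 3250.0))
        cfg = SimulationConfig(image_shape=(48, 256), n_frames=40,
                               quantal_yield=800.0, seed=6)
        movie, truth = simulate_movie(
            cfg, geo, [(MotilityModel(mode="processive", speed=200.0),
                        PhotophysicsModel(), 2000.0)])
        dets = {}
        for t in range(movie.n_frames):
            ds = detect_puncta(movie.frames[t], psf_sigma_px=0.94)
            for d in ds:
                d.frame = t
            dets[t] = ds
        tracks = link_tracks(dets, max_jump_nm=600.0, pixel_size=PX)
        main = max(tracks, key=lambda tr: tr.n_frames)
        path = OrganellePath(control_points=[(2.0, 20.0), (239.0, 20.0)],
                             half_width=2.0, pixel_size=PX)
        s = project_to_axis(main, path)
        true_s = truth.emitters[0].axial_nm[main.frames] + (325.0 - 2.0 * PX)
        rms = np.sqrt(np.nanmean((s - true_s) ** 2))
        assert rms < PX  # within one pixel-equivalent

    def test_tracks_csv_export(self, tmp_path):
        dets = _detections([[(10.0, 5.0)]] * 4)
        tracks = link_tracks(dets, pixel_size=PX)
        project_to_axis(tracks[0], _axis_path(half_width=6.0, y=5.0))
        tracks_to_csv(tracks, tmp_path / "t.csv", frame_interval=0.5)
        import pandas as pd
        df = pd.read_csv(tmp_path / "t.csv")
        assert list(df.columns) == ["track_id", "frame", "t_s", "x_px",
                                    "y_px", "s_nm", "intensity"]
        assert len(df) == 4
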
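"""Spherical I-DT detection and per-trial movement measures."""

import numpy as np
import pandas as pd
import pytest

from oracles import angle_dot_oracle
from vrgaze import fixation, sphere
from vrgaze.synth import StudyConfig, make_scene, simulate_trial, _make_participant


def plateau_series(segments, rate_hz=250.0):
    """Build (t, lon, lat) from [(lon, lat, duration_ms), ...] segments."""
    dt = 1000.0 / rate_hz
    t, lon, lat = [], [], []
    t0 = 0.0
    for plon, plat, dur in segments:
        ts = np.arange(t0, t0 + dur, dt)
        t.extend(ts)
        lon.extend([plon] * ts.size)
        lat.extend([plat] * ts.size)
        t0 += dur
    return np.array(t), np.array(lon), np.array(lat)


def planar_idt_oracle(t, lon, lat, max_dispersion=3.0, min_duration=80.0):
    """Classic planar I-DT: dispersion = lon-range + lat-range.

    The naive algorithm a flat-screen pipeline would use; serves as the
    contrast case showing why thresholds must act on angular distance.
    """
    n = len(t)
    count = 0
    start = 0
    while start < n:
        end = start
        while end < n and t[end] - t[start] < min_duration:
            end += 1
        if end >= n:
            break
        w_lon = lon[start:end + 1]
        w_lat = lat[start:end + 1]
        disp = (w_lon.max() - w_lon.min()) + (w_lat.max() - w_lat.min())
        if disp > max_dispersion:
            start += 1
            continue
        j = end
        while j + 1 < n:
            w_lon = lon[start:j + 2]
            w_lat = lat[start:j + 2]
            if (w_lon.max() - w_lon.min()) + (w_lat.max() - w_lat.min()) \
                    > max_dispersion:
                break
            j += 1
        count += 1
        start = j + 1
    return count


class TestDetectFixationsIDT:
    def test_two_plateaus_recovered(self):
        t, lon, lat = plateau_series([(0, 0, 100), (10, 0, 100)])
        fx = fixation.detect_fixations_idt(t, lon, lat)
        assert len(fx) == 2
        assert fx["lon"].to_numpy() == pytest.approx([0.0, 10.0], abs=1e-9)
        assert list(fx["index"]) == [1, 2]

    def test_79ms_plateau_not_detected(self, rng):
        # 79 ms stable, then a fast sweep: nothing reaches min duration
        t1, lon1, lat1 = plateau_series([(0, 0, 79)])
        t2 = np.arange(80.0, 400.0, 4.0)
        lon2 = 20.0 + 0.5 * (t2 - 80.0)  # 125 deg/s drift
        t = np.concatenate([t1, t2])
        lon = np.concatenate([lon1, lon2])
        lat = np.zeros_like(lon)
        fx = fixation.detect_fixations_idt(t, lon, lat)
        assert len(fx) == 0

    def test_near_pole_plateau_stays_single(self, rng):
        # 1 deg angular jitter around latitude 89: one fixation on the sphere,
        # while the planar longitude-range criterion finds none
        n = 100
        t = np.arange(n) * 4.0
        center = sphere.sph_to_vec(0.0, 89.0)
        pts = []
        for _ in range(n):
            off = rng.normal(scale=0.4, size=3)
            v = center + np.deg2rad(1.0) * off
            pts.append(v / np.linalg.norm(v))
        lon, lat = sphere.vec_to_sph(np.array(pts))
        fx = fixation.detect_fixations_idt(t, lon, lat)
        assert len(fx) == 1
        assert fx["lat"].iloc[0] > 88.0
        assert planar_idt_oracle(t, lon, lat) == 0

    def test_rotation_invariance(self, rng):
        cfg = StudyConfig(trial_duration_ms=3000.0)
        scene = make_scene(2, 8, 8.0)
        part = _make_participant("P0", cfg, 3, 1.0)
        tr = simulate_trial(scene, part, "encoding", cfg, 4)
        from vrgaze.preprocess import build_gaze_series
        g = build_gaze_series(tr)
        t = g["t"].to_numpy()
        lon = g["eye_lon"].to_numpy()
        lat = g["eye_lat"].to_numpy()
        fx = fixation.detect_fixations_idt(t, lon, lat)
        q = sphere.quat_canonical(sphere.quat_normalize(rng.normal(size=4)))
        rlon, rlat = sphere.vec_to_sph(
            sphere.quat_rotate(q, sphere.sph_to_vec(lon, lat)))
        fx_rot = fixation.detect_fixations_idt(t, rlon, rlat)
        assert len(fx) == len(fx_rot) > 0
        expect = sphere.quat_rotate(
            q, sphere.sph_to_vec(fx["lon"].to_numpy(), fx["lat"].to_numpy()))
        elon, elat = sphere.vec_to_sph(expect)
        d = sphere.angular_distance(elon, elat, fx_rot["lon"].to_numpy(),
                                    fx_rot["lat"].to_numpy())
        assert np.max(d) < 1e-6

    def test_threshold_monotonicity(self):
        cfg = StudyConfig(trial_duration_ms=4000.0)
        for s in range(5):
            scene = make_scene(s, 8, 8.0)
            part = _make_participant("P0", cfg, 40 + s, 1.0)
            tr = simulate_trial(scene, part, "encoding", cfg, 80 + s)
            from vrgaze.preprocess import build_gaze_series
            g = build_gaze_series(tr)
            args = (g["t"].to_numpy(), g["eye_lon"].to_numpy(),
                    g["eye_lat"].to_numpy())
            tight = fixation.detect_fixations_idt(*args, 3.0, 80.0)
            loose_disp = fixation.detect_fixations_idt(*args, 5.0, 80.0)
            short_dur = fixation.detect_fixations_idt(*args, 3.0, 60.0)
            assert loose_disp["dur_ms"].sum() >= tight["dur_ms"].sum()
            assert len(short_dur) >= len(tight)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fixation.detect_fixations_idt([], [], [])
        with pytest.raises(ValueError):
            fixation.detect_fixations_idt([0.0, 0.0], [0, 0], [0, 0])


class TestHeadFixations:
    def _gaze_frame(self, t, hlon, hlat):
        z = np.zeros_like(t, dtype=float)
        return pd.DataFrame({"t": t, "eye_lon": z, "eye_lat": z,
                             "eih_lon": z, "eih_lat": z,
                             "head_lon": hlon, "head_lat": hlat})

    def test_constant_head_pose(self):
        t = np.arange(0, 200, 4.0)
        g = self._gaze_frame(t, np.full(t.size, 25.0), np.full(t.size, -10.0))
        fx = pd.DataFrame({"index": [1], "start_ms": [0.0], "end_ms": [200.0],
                           "dur_ms": [200.0], "lon": [0.0], "lat": [0.0]})
        hf = fixation.head_fixations(fx, g)
        assert hf["head_lon"].iloc[0] == pytest.approx(25.0, abs=1e-9)
        assert hf["head_lat"].iloc[0] == pytest.approx(-10.0, abs=1e-9)

    def test_sweeping_head_centroid_at_mid_sweep(self):
        # head sweeping 0 -> 40 deg longitude at constant rate
        t = np.arange(0, 400, 4.0)
        hlon = 40.0 * t / 400.0
        g = self._gaze_frame(t, hlon, np.zeros_like(t))
        fx = pd.DataFrame({"index": [1], "start_ms": [0.0], "end_ms": [400.0],
                           "dur_ms": [400.0], "lon": [0.0], "lat": [0.0]})
        hf = fixation.head_fixations(fx, g)
        # discrete mean over [0, 40) at step 0.4: midpoint minus half a step
        assert hf["head_lon"].iloc[0] == pytest.approx(19.8, abs=0.05)

    def test_window_without_samples_rejected(self):
        t = np.arange(0, 100, 4.0)
        g = self._gaze_frame(t, np.zeros_like(t), np.zeros_like(t))
        fx = pd.DataFrame({"index": [1], "start_ms": [500.0],
                           "end_ms": [600.0], "dur_ms": [100.0],
                           "lon": [0.0], "lat": [0.0]})
        with pytest.raises(ValueError):
            fixation.head_fixations(fx, g)


class TestMeasures:
    def test_saccade_amplitudes_axis_aligned(self):
        amp = fixation.saccade_amplitudes([0.0, 90.0, 90.0], [0.0, 0.0, 90.0])
        assert amp == pytest.approx([90.0, 90.0], abs=1e-9)
        assert fixation.saccade_amplitudes([5.0], [5.0]).size == 0

    def test_saccade_amplitudes_match_pairwise_oracle(self, rng):
        lon = rng.uniform(-180, 180, 30)
        lat = rng.uniform(-80, 80, 30)
        amp = fixation.saccade_amplitudes(lon, lat)
        for k in range(29):
            assert amp[k] == pytest.approx(
                angle_dot_oracle(lon[k], lat[k], lon[k + 1], lat[k + 1]),
                abs=1e-9)

    def test_exploration_tendency(self, rng):
        assert fixation.exploration_tendency([7.0, 7.0, 7.0],
                                             [3.0, 3.0, 3.0]) == 0.0
        assert fixation.exploration_tendency(
            [0.0, 60.0, -60.0], [0.0, 0.0, 0.0]) == pytest.approx(60.0,
                                                                  abs=1e-9)
        lon = rng.uniform(-180, 180, 50)
        lat = rng.uniform(-80, 80, 50)
        expect = np.mean([angle_dot_oracle(lon[k], lat[k], lon[0], lat[0])
                          for k in range(1, 50)])
        assert fixation.exploration_tendency(lon, lat) == pytest.approx(
            expect, abs=1e-9)

    def test_trial_measures_basic_and_degenerate(self):
        fx = pd.DataFrame({"index": [1, 2, 3],
                           "start_ms": [0.0, 150.0, 400.0],
                           "end_ms": [100.0, 350.0, 700.0],
                           "dur_ms": [100.0, 200.0, 300.0],
                           "lon": [0.0, 10.0, 20.0],
                           "lat": [0.0, 0.0, 0.0]})
        m = fixation.trial_measures(fx)
        assert m.n_fixations == 3
        assert m.mean_fixation_duration == pytest.approx(200.0)
        assert m.saccade_amplitudes == pytest.approx([10.0, 10.0], abs=1e-9)
        empty = fixation.trial_measures(fx.iloc[0:0])
        assert empty.n_fixations == 0
        assert np.isnan(empty.mean_fixation_duration)

    def test_fixation_count_matches_timing_budget(self):
        # fixed 200 ms plateaus over 10 s: n within +-1 of the budget estimate
        cfg = StudyConfig(noise_kappa=np.inf, fixation_duration_shape=1e9,
                          fixation_duration_mean_ms=200.0)
        scene = make_scene(14, 8, 8.0)
        part = _make_participant("P0", cfg, 15, 1.0)
        tr = simulate_trial(scene, part, "encoding", cfg, 16)
        mean_sacc = np.mean(tr.gt_on[1:] - tr.gt_off[:-1])
        budget = cfg.trial_duration_ms / (200.0 + mean_sacc)
        assert abs(tr.n_ground_truth - budget) <= 1.5
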
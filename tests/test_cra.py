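"""Cross-recurrence measures against brute-force enumeration oracles."""

import numpy as np
import pytest

from oracles import cra_oracle
from vrgaze import cra


def measures_dict(r, min_line=2, min_cluster=8):
    hlam, htt = cra.laminarity_horizontal(r, min_line)
    vlam, vtt = cra.laminarity_vertical(r, min_line)
    return {
        "rec": cra.rec_percent(r),
        "det": cra.det_percent(r, min_line),
        "hlam": hlam, "htt": htt, "vlam": vlam, "vtt": vtt,
        "corm": cra.corm_percent(r),
        "clust": cra.clust_percent(r, min_cluster),
        "ent": cra.diagonal_entropy(r, min_line),
    }


def assert_same(ours, oracle):
    for k, v in oracle.items():
        if np.isnan(v):
            assert np.isnan(ours[k]), k
        else:
            assert ours[k] == pytest.approx(v, abs=1e-12), k


class TestAdjustLengths:
    def test_truncates_to_shorter_keeping_head(self):
        e = (np.arange(30.0), np.zeros(30))
        r = (np.arange(25.0), np.zeros(25))
        (le, _), (lr, _) = cra.adjust_lengths(e, r)
        assert le.size == lr.size == 25
        assert np.array_equal(le, np.arange(25.0))

    def test_equal_lengths_unchanged(self):
        e = (np.arange(5.0), np.zeros(5))
        (le, _), (lr, _) = cra.adjust_lengths(e, e)
        assert le.size == lr.size == 5

    def test_degenerate_warns_and_empty_raises(self):
        e = (np.arange(40.0), np.zeros(40))
        one = (np.array([1.0]), np.array([0.0]))
        with pytest.warns(UserWarning):
            (le, _), _ = cra.adjust_lengths(e, one)
        assert le.size == 1
        with pytest.raises(ValueError):
            cra.adjust_lengths(e, (np.empty(0), np.empty(0)))


class TestRecurrenceMatrix:
    def test_full_and_identity(self):
        lon = np.array([0.0, 50.0, 120.0])
        lat = np.zeros(3)
        seq = (lon, lat)
        assert cra.recurrence_matrix(seq, seq, 180.0).all()
        assert np.array_equal(cra.recurrence_matrix(seq, seq, 0.0), np.eye(3))

    def test_tie_counts_as_recurrent(self):
        a = (np.array([0.0]), np.array([0.0]))
        b = (np.array([10.0]), np.array([0.0]))
        assert cra.recurrence_matrix(a, b, 10.0)[0, 0]

    def test_matches_double_loop_oracle(self, rng):
        lon_e = rng.uniform(-180, 180, 8)
        lat_e = rng.uniform(-60, 60, 8)
        lon_r = rng.uniform(-180, 180, 8)
        lat_r = rng.uniform(-60, 60, 8)
        r = cra.recurrence_matrix((lon_e, lat_e), (lon_r, lat_r), 40.0)
        from oracles import angle_dot_oracle
        for i in range(8):
            for j in range(8):
                d = angle_dot_oracle(lon_e[i], lat_e[i], lon_r[j], lat_r[j])
                assert r[i, j] == (d <= 40.0)


class TestMeasuresAnalytic:
    def test_identity_matrix(self):
        r = np.eye(6, dtype=bool)
        m = measures_dict(r)
        assert m["rec"] == pytest.approx(100.0 / 6)
        assert m["det"] == pytest.approx(100.0)  # one diagonal of length N
        assert m["corm"] == pytest.approx(0.0)
        assert m["ent"] == pytest.approx(0.0)    # single run length
        assert m["vlam"] == 0.0 and m["hlam"] == 0.0

    def test_all_ones(self):
        r = np.ones((5, 5), dtype=bool)
        m = measures_dict(r)
        assert m["rec"] == 100.0
        # the two length-1 corner diagonals fall below min_line
        assert m["det"] == pytest.approx(100.0 * 23 / 25)
        assert m["clust"] == 100.0
        assert m["vlam"] == 100.0 and m["vtt"] == 5.0

    def test_isolated_points_have_no_lines(self):
        # points spaced >= 2 cells apart in every direction: no run of length 2
        r = np.zeros((6, 6), dtype=bool)
        r[0, 0] = r[0, 3] = r[3, 0] = r[3, 3] = True
        m = measures_dict(r)
        assert m["det"] == 0.0
        assert m["vlam"] == 0.0 and m["hlam"] == 0.0

    def test_single_full_column(self):
        r = np.zeros((5, 5), dtype=bool)
        r[:, 2] = True
        vlam, vtt = cra.laminarity_vertical(r)
        hlam, htt = cra.laminarity_horizontal(r)
        assert vlam == 100.0 and vtt == 5.0
        assert hlam == 0.0 and np.isnan(htt)

    def test_corm_extremes_and_symmetry(self):
        n = 7
        r = np.zeros((n, n), dtype=bool)
        r[0, n - 1] = True
        assert cra.corm_percent(r) == pytest.approx(100.0)
        sym = np.zeros((n, n), dtype=bool)
        sym[1, 4] = sym[4, 1] = sym[3, 3] = True
        assert cra.corm_percent(sym) == pytest.approx(0.0)

    def test_clust_block_and_scatter(self):
        r = np.zeros((9, 9), dtype=bool)
        r[2:5, 3:6] = True  # 3x3 block: 9 points, one component
        assert cra.clust_percent(r) == 100.0
        s = np.zeros((9, 9), dtype=bool)
        s[0, 0] = s[4, 4] = s[8, 0] = True
        assert cra.clust_percent(s) == 0.0

    def test_entropy_two_outcome_uniform(self):
        r = np.zeros((9, 9), dtype=bool)
        r[0, 0] = r[1, 1] = True                  # diagonal run of length 2
        r[3, 5] = r[4, 6] = r[5, 7] = True        # diagonal run of length 3
        assert cra.diagonal_entropy(r) == pytest.approx(np.log(2))

    def test_empty_matrix_measures_missing(self):
        r = np.zeros((5, 5), dtype=bool)
        m = measures_dict(r)
        assert m["rec"] == 0.0
        for k in ["det", "hlam", "htt", "vlam", "vtt", "corm", "clust", "ent"]:
            assert np.isnan(m[k]), k


class TestOracleEquivalence:
    def test_random_matrices_match_enumeration(self, rng):
        for _ in range(60):
            n = rng.integers(2, 13)
            density = rng.uniform(0.05, 0.9)
            r = rng.random((n, n)) < density
            assert_same(measures_dict(r), cra_oracle(r.tolist()))

    def test_transpose_duality(self, rng):
        for _ in range(30):
            r = rng.random((10, 10)) < 0.4
            vlam, vtt = cra.laminarity_vertical(r)
            hlam_t, htt_t = cra.laminarity_horizontal(r.T)
            assert (vlam == hlam_t) or (np.isnan(vlam) and np.isnan(hlam_t))
            assert (vtt == htt_t) or (np.isnan(vtt) and np.isnan(htt_t))


class TestComputeAll:
    def test_identity_pair(self):
        lon = np.linspace(-120, 120, 10)
        lat = np.linspace(-40, 40, 10)
        m = cra.compute_all((lon, lat), (lon, lat), radius=0.5)
        assert m.rec == pytest.approx(100.0 / 10)
        assert m.det == pytest.approx(100.0)
        assert m.corm == pytest.approx(0.0)
        assert m.ent == pytest.approx(0.0)
        assert m.n == 10

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(20):
            e = (rng.uniform(-180, 180, 12), rng.uniform(-70, 70, 12))
            r = (rng.uniform(-180, 180, 9), rng.uniform(-70, 70, 9))
            m = cra.compute_all(e, r, radius=50.0)
            for k in ("rec", "det", "hlam", "vlam", "clust"):
                v = getattr(m, k)
                assert np.isnan(v) or 0.0 <= v <= 100.0
            assert np.isnan(m.corm) or -100.0 <= m.corm <= 100.0
            assert np.isnan(m.ent) or m.ent >= 0.0


class TestCalibrateRadius:
    def test_identical_single_point_pairs_return_zero(self):
        p = (np.array([10.0]), np.array([5.0]))
        assert cra.calibrate_radius([(p, p)], target_rec=7.0) == 0.0

    def test_rec_nondecreasing_in_radius(self, rng):
        e = (rng.uniform(-180, 180, 20), rng.uniform(-60, 60, 20))
        r = (rng.uniform(-180, 180, 20), rng.uniform(-60, 60, 20))
        radii = np.linspace(0, 180, 50)
        recs = [cra.rec_percent(cra.recurrence_matrix(e, r, x)) for x in radii]
        assert np.all(np.diff(recs) >= 0)

    def test_self_consistency_on_random_pairs(self, rng):
        pairs = []
        for _ in range(50):
            e = (rng.uniform(-180, 180, 25), rng.uniform(-60, 60, 25))
            r = (rng.uniform(-180, 180, 25), rng.uniform(-60, 60, 25))
            pairs.append((e, r))
        radius = cra.calibrate_radius(pairs, target_rec=7.0, tol=0.01)
        recs = [cra.rec_percent(cra.recurrence_matrix(e, r, radius))
                for e, r in pairs]
        assert np.mean(recs) == pytest.approx(7.0, abs=0.05)
        below = [cra.rec_percent(
            cra.recurrence_matrix(e, r, radius * (1 - 1e-9)))
            for e, r in pairs]
        assert np.mean(below) < 7.0  # smallest such radius

    def test_eye_radius_exceeds_head_radius_when_eye_spread_larger(self):
        # with a lag-free under-shooting head, head points are a contracted
        # copy of the eye points: smaller spread, so the 7% recurrence target
        # is reached at a smaller radius than for the eyes
        from vrgaze.study import (build_pairings, detect_study,
                                  fixation_sequences)
        from vrgaze.synth import StudyConfig, simulate_study

        cfg = StudyConfig(n_participants=2, n_scenes_encoding=8, n_old=4,
                          n_new=4, trial_duration_ms=5000.0,
                          head_gain=0.6, head_lag_ms=0.0,
                          mover_scale_range=(1.0, 1.0))
        st = simulate_study(cfg, 31)
        fix_table, _ = detect_study(st)
        seqs = fixation_sequences(fix_table)
        pairings = build_pairings(st.trial_table, seed=32)
        pairs = {t: [(seqs[(r.participant_enc, r.scene_enc, "enc")][t],
                      seqs[(r.participant_rec, r.scene_rec, "rec")][t])
                     for r in pairings["Sp-Si"].itertuples(index=False)]
                 for t in ("eye", "head")}
        from vrgaze.spatial import trial_spread
        eye_sd = np.mean([trial_spread(*p[0])[0] for p in pairs["eye"]])
        head_sd = np.mean([trial_spread(*p[0])[0] for p in pairs["head"]])
        assert eye_sd > head_sd  # the example's premise holds
        r_eye = cra.calibrate_radius(pairs["eye"], 7.0)
        r_head = cra.calibrate_radius(pairs["head"], 7.0)
        assert r_eye > r_head

    def test_bad_target_rejected(self):
        p = (np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            cra.calibrate_radius([(p, p)], target_rec=0.0)
        with pytest.raises(ValueError):
            cra.calibrate_radius([], target_rec=7.0)
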
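"""Drift correction, matching, track building, rates and depth binning."""

import numpy as np
import pytest

from remyelin.pipeline import cohort_statistics
from remyelin.tracking import (bin_by_depth, build_tracks, compute_rates,
                               correct_drift, match_cells,
                               project_full_recovery, track_cells)


class TestCorrectDrift:
    def test_pure_translation_recovered(self):
        a = np.array([[0, 0, 0], [30, 5, 2], [10, 40, 8.0]])
        b = a + np.array([5.0, 0.0, 0.0])
        corr, drift, ok = correct_drift(a, b)
        assert ok
        assert drift == pytest.approx([5, 0, 0])
        assert corr == pytest.approx(a)

    def test_mean_displacement_two_cells(self):
        a = np.array([[0, 0, 0], [100, 0, 0.0]])
        b = np.array([[2, 0, 0], [104, 0, 0.0]])
        corr, drift, _ = correct_drift(a, b)
        assert drift == pytest.approx([3, 0, 0])
        assert np.abs(corr[:, 0] - a[:, 0]) == pytest.approx([1, 1])

    def test_missing_cell_uses_remaining_pairs(self):
        a = np.array([[0, 0, 0], [100, 0, 0], [200, 0, 0.0]])
        b = np.array([[4, 0, 0], [204, 0, 0.0]])   # middle cell gone
        _, drift, _ = correct_drift(a, b)
        assert drift == pytest.approx([4, 0, 0])

    def test_idempotent_on_corrected_data(self, rng):
        a = rng.uniform(0, 200, size=(40, 3))
        b = a + np.array([6.0, -3.0, 2.0]) + rng.normal(0, 0.5, (40, 3))
        corr, _, _ = correct_drift(a, b)
        _, drift2, _ = correct_drift(a, corr)
        assert np.linalg.norm(drift2) < 0.2

    def test_no_match_returns_zero_with_warning(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[500.0, 500, 200]])
        with pytest.warns(UserWarning):
            _, drift, ok = correct_drift(a, b, max_match_dist=10)
        assert not ok and np.all(drift == 0)


class TestMatchCells:
    def test_identity_match(self):
        a = np.array([[0, 0, 0], [50, 0, 0.0]])
        pairs = match_cells(a, a.copy(), 10)
        assert [(i, j) for i, j, _ in pairs] == [(0, 0), (1, 1)]
        assert all(d == 0 for _, _, d in pairs)

    def test_two_cell_pairing_matches_exhaustive_oracle(self):
        a = np.array([[0, 0, 0], [100, 0, 0.0]])
        b = np.array([[2, 0, 0], [101, 0, 0.0]])
        pairs = {(i, j) for i, j, _ in match_cells(a, b, 10)}
        # oracle: all assignments, min total distance, within threshold
        import itertools
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(2)):
            cost = sum(np.linalg.norm(a[i] - b[perm[i]]) for i in range(2))
            if cost < best_cost:
                best_cost, best = cost, {(i, perm[i]) for i in range(2)}
        assert pairs == best

    def test_beyond_threshold_unmatched(self):
        pairs = match_cells(np.array([[0.0, 0, 0]]),
                            np.array([[15.0, 0, 0]]), 10)
        assert pairs == []

    def test_empty_inputs(self):
        assert match_cells(np.empty((0, 3)), np.array([[1.0, 1, 1]]), 10) == []


class TestBuildTracks:
    def _sessions(self, table):
        weeks = sorted(table)
        return weeks, {w: np.asarray(table[w], float).reshape(-1, 3)
                       for w in weeks}

    def test_single_stable_cell(self):
        weeks, pos = self._sessions({0: [[0, 0, 0]], 1: [[0, 0, 0]],
                                     2: [[0, 0, 0]]})
        tracks = build_tracks([[(0, 0)], [(0, 0)]], pos, weeks)
        assert len(tracks) == 1 and tracks[0].fate == "stable"

    def test_lost_after_week3(self):
        pos = {w: [[0, 0, 0.0]] for w in range(4)}
        pos[4] = np.empty((0, 3))
        pos[5] = np.empty((0, 3))
        weeks, pos = self._sessions(pos)
        corr = [[(0, 0)], [(0, 0)], [(0, 0)], [], []]
        tracks = build_tracks(corr, pos, weeks)
        assert tracks[0].fate == "lost"
        assert tracks[0].last_seen == 3

    def test_new_then_lost(self):
        pos = {0: np.empty((0, 3)), 2: [[1.0, 1, 1]], 4: [[1.0, 1, 1]],
               6: np.empty((0, 3)), 8: np.empty((0, 3))}
        weeks, pos = self._sessions(pos)
        corr = [[], [(0, 0)], [], []]
        tracks = build_tracks(corr, pos, weeks)
        assert len(tracks) == 1 and tracks[0].fate == "new_then_lost"

    def test_duplicate_correspondence_rejected(self):
        weeks, pos = self._sessions({0: [[0, 0, 0], [10, 0, 0]],
                                     1: [[0, 0, 0]]})
        with pytest.raises(ValueError):
            build_tracks([[(0, 0), (1, 0)]], pos, weeks)


class TestComputeRates:
    def test_rate_arithmetic(self):
        """100 baseline; at week 1, 90 remain and 5 new appeared."""
        from remyelin.tracking import CellTrack
        tracks = []
        for i in range(100):
            t = CellTrack(track_id=i)
            t.positions[0] = np.zeros(3)
            if i < 90:
                t.positions[1] = np.zeros(3)
            tracks.append(t)
        for i in range(5):
            t = CellTrack(track_id=100 + i)
            t.positions[1] = np.zeros(3)
            tracks.append(t)
        for t in tracks:
            t.fate = "x"
        rs = compute_rates(tracks, [0, 1])
        assert rs.loss_rate[0] == pytest.approx(10.0)
        assert rs.addition_rate[0] == pytest.approx(5.0)
        assert rs.baseline_remaining_pct[-1] == pytest.approx(90.0)

    def test_no_changes_zero_rates(self):
        from remyelin.tracking import CellTrack
        tracks = []
        for i in range(10):
            t = CellTrack(track_id=i)
            t.positions.update({0: np.zeros(3), 1: np.zeros(3)})
            tracks.append(t)
        rs = compute_rates(tracks, [0, 1])
        assert rs.loss_rate[0] == 0 and rs.addition_rate[0] == 0

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            compute_rates([], [0, 1])


class TestBinByDepth:
    @pytest.mark.parametrize("z,zone", [(50, 0), (100, 1), (0, 0),
                                        (199.9, 1), (250, 2)])
    def test_half_open_zones(self, z, zone):
        assert bin_by_depth(z, (0, 100, 200, 300))[0] == zone

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            bin_by_depth(-1.0, (0, 100, 200, 300))

    def test_synthetic_zone_counts_match_truth(self, noisefree_control):
        obs, truth, cfg = noisefree_control
        base = obs[obs["week"] == 0]
        zones = bin_by_depth(base["z_um"].to_numpy(), (0, 100, 200, 300))
        for m in truth["mice"]:
            sel = base["mouse_id"] == m["mouse_id"]
            for zi in range(3):
                n_true = sum(1 for c in m["cells"].values()
                             if c["appear_week"] == 0 and c["zone"] == zi)
                assert int((zones[sel.to_numpy()] == zi).sum()) == n_true


class TestProjection:
    def test_recovery_extrapolation_worked_example(self):
        """Roughly three more months at the late addition rate."""
        assert project_full_recovery(55.2, 3.5) == pytest.approx(12.8)

    @pytest.mark.parametrize("frac,rate,expect",
                             [(100.0, 3.0, 0.0), (50.0, 5.0, 10.0)])
    def test_projection_arithmetic(self, frac, rate, expect):
        assert project_full_recovery(frac, rate) == pytest.approx(expect)

    def test_nonpositive_rate_never_recovers(self):
        assert project_full_recovery(60.0, 0.0) == np.inf


class TestFullTracking:
    def test_noise_free_fates_exact(self, noisefree_control, volume):
        obs, truth, cfg = noisefree_control
        for m in truth["mice"]:
            sub = obs[obs["mouse_id"] == m["mouse_id"]].reset_index(drop=True)
            tracks, drift, corr = track_cells(sub)
            n_base_true = sum(1 for c in m["cells"].values()
                              if c["appear_week"] == 0)
            n_new_true = sum(1 for c in m["cells"].values()
                             if c["appear_week"] > 0)
            fates = [t.fate for t in tracks]
            assert fates.count("stable") == n_base_true  # control: no loss
            assert fates.count("new") == n_new_true
            assert all(np.allclose(d, 0) for d in drift.values())

    def test_default_noise_fate_error_below_2pct(self, cuprizone_cohort,
                                                 volume):
        obs, truth, cfg = cuprizone_cohort
        weeks = sorted(obs["week"].unique())
        errors = total = 0
        for m in truth["mice"]:
            cells = m["cells"]
            sub = obs[obs["mouse_id"] == m["mouse_id"]].reset_index(drop=True)
            by_week = {wk: sub[sub["week"] == wk].reset_index(drop=True)
                       for wk in weeks}
            tracks, _, _ = track_cells(sub)
            for t in tracks:
                cid = by_week[t.first_seen].loc[t.obs_rows[t.first_seen],
                                                "cell_id"]
                c = cells[cid]
                true_fate = ("stable" if c["appear_week"] == 0
                             and c["loss_week"] is None else
                             "lost" if c["appear_week"] == 0 else "new")
                total += 1
                errors += t.fate != true_fate
        assert errors / total < 0.02

    def test_session_conservation(self, cuprizone_cohort, volume):
        """stable + lost = baseline at every session, through the tracker."""
        obs, truth, cfg = cuprizone_cohort
        mouse = truth["mice"][0]["mouse_id"]
        sub = obs[obs["mouse_id"] == mouse].reset_index(drop=True)
        tracks, _, _ = track_cells(sub)
        weeks = sorted(obs["week"].unique())
        rs = compute_rates(tracks, weeks)
        base = rs.baseline_count
        for k, w in enumerate(weeks):
            remaining = rs.baseline_remaining_pct[k] * base / 100
            lost = base - remaining
            assert remaining + lost == pytest.approx(base)
            observed = len(sub[sub["week"] == w])
            # observed = stable(baseline cohort) + alive new tracks
            assert rs.observed_pct[k] * base / 100 == pytest.approx(
                observed, abs=1e-9)
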
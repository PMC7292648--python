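"""Sheath morphometry, attachment statistics and circular tests."""

import numpy as np
import pytest
from scipy.stats import kstest

from remyelin.config import default_morphology
from remyelin.morphometry import (OligMorphology, SheathTrace,
                                  attachment_position,
                                  classify_sheath_dynamics, hodges_ajne_test,
                                  kuiper_two_sample, paranode_orientation,
                                  sheath_census, smooth_and_measure)
from remyelin.synthetic import generate_oligo_morphology


def _line(length, spacing=1.0):
    n = int(length / spacing) + 1
    return np.column_stack([np.linspace(0, length, n),
                            np.zeros(n), np.zeros(n)])


class TestSmoothing:
    def test_straight_line_invariant(self):
        sm, L = smooth_and_measure(_line(60.0))
        assert L == pytest.approx(60.0)
        assert np.allclose(sm, _line(60.0))

    def test_zigzag_shortened(self):
        pts = _line(60.0)
        pts[:, 1] = np.where(np.arange(len(pts)) % 2, 1.0, -1.0)
        raw = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        _, L = smooth_and_measure(pts, window=3)
        assert L < raw

    def test_two_point_trace(self):
        _, L = smooth_and_measure(np.array([[0, 0, 0], [3.0, 4, 0]]))
        assert L == pytest.approx(5.0)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_and_measure(_line(10), window=0)


class TestCensus:
    def _morph(self, lengths):
        m = OligMorphology(cell_id="c", soma=(0, 0, 0),
                           day_from_appearance=14)
        for i, L in enumerate(lengths):
            m.sheaths.append(SheathTrace(f"s{i}", "c", _line(L),
                                         attachment_arc=L / 2))
        return m

    def test_census_arithmetic(self):
        row = sheath_census(self._morph([50, 60, 70]))
        assert row.sheath_count == 3
        assert row.total_length_mm == pytest.approx(0.180)
        assert row.mean_length_um == pytest.approx(60.0)

    def test_empty_morphology_flagged(self):
        row = sheath_census(self._morph([]))
        assert row.sheath_count == 0 and row.total_length_mm == 0
        assert np.isnan(row.mean_length_um)

    def test_mature_census_recovers_configured_mean(self, rng):
        mcfg = default_morphology("control")
        rows = [sheath_census(generate_oligo_morphology((0, 0, 50), mcfg,
                                                        seed=rng),
                              day=mcfg.mature_day) for _ in range(200)]
        counts = [r.sheath_count for r in rows]
        sem = mcfg.sheath_count_sd / np.sqrt(200)
        assert abs(np.mean(counts) - mcfg.sheath_count_mean) <= 3 * sem


class TestDynamics:
    @pytest.mark.parametrize("lengths,label",
                             [((50, 55), "growth"), ((50, 51), "stable"),
                              ((50, 47), "retraction")])
    def test_threshold_rules(self, lengths, label):
        labels, _ = classify_sheath_dynamics([0, 2], lengths,
                                             length_threshold=2.0)
        assert labels == [label]

    def test_pruned_lifecycle(self):
        labels, life = classify_sheath_dynamics(
            [0, 2, 4, 6, 8], [50, 52, 51, None, None])
        assert life == "pruned"

    def test_non_monotonic_days_rejected(self):
        with pytest.raises(ValueError):
            classify_sheath_dynamics([0, 2, 2], [1, 2, 3])


class TestAttachment:
    def test_midpoint(self):
        sh = SheathTrace("s", "c", _line(60.0), attachment_arc=30.0)
        assert attachment_position(sh) == pytest.approx(0.5)

    def test_start(self):
        sh = SheathTrace("s", "c", _line(60.0), attachment_arc=0.0)
        assert attachment_position(sh) == 0.0

    def test_outside_trace_rejected(self):
        sh = SheathTrace("s", "c", _line(60.0), attachment_arc=70.0)
        with pytest.raises(ValueError):
            attachment_position(sh)

    def test_uniformity_not_rejected_on_synthetic(self, rng):
        mcfg = default_morphology("control")
        pos = []
        while len(pos) < 500:
            m = generate_oligo_morphology((0, 0, 50), mcfg, seed=rng)
            pos.extend(attachment_position(sh) for sh in m.sheaths)
        stat = kstest(pos[:500], "uniform")
        assert stat.pvalue > 0.01


class TestOrientation:
    def _morph_with_endpoints(self, endpoints):
        m = OligMorphology(cell_id="c", soma=(0, 0, 0))
        for i, (a, b) in enumerate(endpoints):
            poly = np.array([list(a), list(b)], float)
            m.sheaths.append(SheathTrace(f"s{i}", "c", poly,
                                         attachment_arc=0.0))
        return m

    def test_symmetric_cross_zero_resultant(self):
        eps = 1e-6  # sheath needs two distinct points
        m = self._morph_with_endpoints([
            ((10, 0, 0), (10 + eps, 0, 0)), ((-10, 0, 0), (-10 - eps, 0, 0)),
            ((0, 10, 0), (0, 10 + eps, 0)), ((0, -10, 0), (0, -10 - eps, 0))])
        res = paranode_orientation(m)
        assert np.linalg.norm(res["resultant"]) < 1e-3

    def test_all_east_zero_dispersion(self):
        m = self._morph_with_endpoints([((10, 0, 0), (11, 0, 0)),
                                        ((20, 0, 0), (21, 0, 0))])
        res = paranode_orientation(m)
        assert res["mean_angle"] == pytest.approx(0.0, abs=1e-9)
        assert res["circ_std"] == pytest.approx(0.0, abs=1e-6)

    def test_coincident_paranode_skipped_with_warning(self):
        m = self._morph_with_endpoints([((0, 0, 5), (10, 0, 0))])
        with pytest.warns(UserWarning):
            res = paranode_orientation(m)
        assert len(res["angles"]) == 1

    def test_isotropic_synthetic_mean_near_zero(self, rng):
        mcfg = default_morphology("control")
        means = [paranode_orientation(
            generate_oligo_morphology((0, 0, 50), mcfg, seed=rng))
            ["mean_angle"] for _ in range(20)]
        assert abs(np.mean(means)) < 0.2


class TestHodgesAjne:
    def test_identical_angles_exact_p(self):
        m, p = hodges_ajne_test(np.zeros(10))
        assert m == 0
        assert p == pytest.approx(10 * 2 ** -9)

    def test_cross_maximally_uniform_for_n4(self):
        m, p = hodges_ajne_test([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert m == 1
        assert p > 0.5

    def test_m_matches_exhaustive_halfplane_sweep(self, rng):
        from remyelin.morphometry import _hodges_ajne_m
        for _ in range(20):
            theta = rng.uniform(0, 2 * np.pi, 15)
            m_fast = _hodges_ajne_m(theta)
            # oracle: dense sweep of open half-planes
            phis = np.linspace(0, 2 * np.pi, 3601)
            counts = [np.sum((np.mod(theta - phi, 2 * np.pi) > 1e-9)
                             & (np.mod(theta - phi, 2 * np.pi)
                                < np.pi - 1e-9)) for phi in phis]
            assert m_fast == min(counts)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hodges_ajne_test([0.0, 1.0, 2.0])

    def test_mc_fallback_agrees_with_exact_formula(self):
        """where the exact combinatorial tail is valid, the Monte-Carlo
        null gives the same probability within sampling error."""
        from math import comb
        from remyelin.morphometry import _ha_null
        n = 10
        null = _ha_null(n, 20000, seed=3)
        for m in (0, 1, 2):
            exact = 2.0 ** (1 - n) * (n - 2 * m) * comb(n, m)
            mc = (np.searchsorted(null, m, side="right") + 1) / (null.size + 1)
            assert mc == pytest.approx(min(exact, 1.0), abs=0.02)


class TestKuiper:
    def test_identical_samples(self, rng):
        x = rng.uniform(0, 2 * np.pi, 40)
        v, p = kuiper_two_sample(x, x)
        assert v == 0.0 and p == 1.0

    def test_separated_point_masses_reject(self):
        """complete separation gives D+=1, D-=0, so V=1 and p tiny."""
        v, p = kuiper_two_sample(np.zeros(50), np.full(50, np.pi))
        assert v == pytest.approx(1.0)
        assert p < 1e-6

    def test_rotation_invariance_machine_tolerance(self, rng):
        a = rng.uniform(0, 2 * np.pi, 60)
        b = rng.uniform(0, 2 * np.pi, 45)
        v0, _ = kuiper_two_sample(a, b)
        for shift in (0.7, 2.1, 5.5):
            v, _ = kuiper_two_sample(a + shift, b + shift)
            assert v == pytest.approx(v0, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            kuiper_two_sample([], [1.0])
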
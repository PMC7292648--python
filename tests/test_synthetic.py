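"""Generator-level checks: trivial/degenerate cases, parameter recovery
against ground truth, and conservation bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from remyelin.config import (AxonFieldConfig, PunctaConfig, VolumeSpec,
                             default_axon_field, default_cohort,
                             default_morphology, default_puncta)
from remyelin.synthetic import (generate_axon_field, generate_cell_population,
                                generate_nodal_puncta,
                                generate_oligo_morphology)


class TestCellPopulation:
    def test_zero_density_gives_empty_table(self, volume):
        cfg = default_cohort("control", n_mice=2,
                            baseline_density_by_zone=(0, 0, 0))
        obs, truth = generate_cell_population(volume, cfg, seed=0)
        assert len(obs) == 0
        assert list(obs.columns) == ["mouse_id", "cell_id", "week",
                                     "x_um", "y_um", "z_um"]

    def test_zero_extent_volume_rejected(self):
        with pytest.raises(ValueError):
            VolumeSpec(x_extent=0.0)

    def test_empty_session_list_rejected(self, volume):
        with pytest.raises(ValueError):
            default_cohort("control", session_weeks=())

    def test_noise_free_stable_cells_static(self, noisefree_control):
        obs, truth, cfg = noisefree_control
        for (mouse, cid), g in obs.groupby(["mouse_id", "cell_id"]):
            pos = g[["x_um", "y_um", "z_um"]].to_numpy()
            assert np.allclose(pos, pos[0])

    def test_realized_loss_within_binomial_ci(self, cuprizone_cohort):
        obs, truth, cfg = cuprizone_cohort
        surv = 1.0
        for h in cfg.loss_schedule.values():
            surv *= 1.0 - h
        p_loss = 1.0 - surv
        n = lost = 0
        for m in truth["mice"]:
            base = [c for c in m["cells"].values() if c["appear_week"] == 0]
            n += len(base)
            lost += sum(1 for c in base if c["loss_week"] is not None)
        phat = lost / n
        half = 1.96 * np.sqrt(p_loss * (1 - p_loss) / n)
        assert abs(phat - p_loss) <= half + 1e-12

    def test_conservation_bookkeeping(self, cuprizone_cohort):
        """baseline = stable + lost and observed = stable + new, per week."""
        obs, truth, cfg = cuprizone_cohort
        for m in truth["mice"]:
            cells = m["cells"]
            base = {cid for cid, c in cells.items() if c["appear_week"] == 0}
            for wk in truth["session_weeks"]:
                stable = sum(1 for cid in base
                             if cells[cid]["loss_week"] is None
                             or cells[cid]["loss_week"] > wk)
                lost = len(base) - stable
                new = sum(1 for cid, c in cells.items()
                          if 0 < c["appear_week"] <= wk)
                observed = len(obs[(obs["mouse_id"] == m["mouse_id"])
                                   & (obs["week"] == wk)])
                assert stable + lost == len(base)
                assert observed == stable + new

    def test_new_cells_respect_displacement_minimum(self, cuprizone_cohort):
        obs, truth, cfg = cuprizone_cohort
        for m in truth["mice"]:
            cells = m["cells"]
            base_pos = np.array([c["pos"] for c in cells.values()
                                 if c["appear_week"] == 0])
            for c in cells.values():
                if c["appear_week"] == 0:
                    continue
                d = np.linalg.norm(base_pos - np.array(c["pos"]), axis=1)
                # placed relative to a baseline reference at >= the
                # configured minimum radial distance (unless the fallback
                # uniform placement fired, which is rare in a full volume)
                assert d.min() >= cfg.displacement_min - 1e-6 or d.min() > 5


class TestOligoMorphology:
    def test_degenerate_distribution_exact(self):
        mcfg = default_morphology(
            "control", sheath_count_mean=3, sheath_count_sd=0,
            sheath_length_mean=60, sheath_length_sd=0, prune_fraction=0.0)
        m = generate_oligo_morphology((0, 0, 50), mcfg, seed=0)
        assert len(m.sheaths) == 3
        for sh in m.sheaths:
            assert sh.length == pytest.approx(60.0, abs=1e-6)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            default_morphology("control", arbor_xy_radius=-1)

    def test_sample_mean_count_near_configured(self, rng):
        mcfg = default_morphology("control")
        counts = [len(generate_oligo_morphology((0, 0, 50), mcfg, seed=rng)
                      .sheaths)
                  for _ in range(200)]
        # mature + pruned transient sheaths; census at maturity filters the
        # pruned ones, here we count the mature complement directly
        mature = [sum(sh.present_on(mcfg.mature_day) for sh in
                      generate_oligo_morphology((0, 0, 50), mcfg,
                                                seed=rng).sheaths)
                  for _ in range(200)]
        sem = mcfg.sheath_count_sd / np.sqrt(200)
        assert abs(np.mean(mature) - mcfg.sheath_count_mean) <= 3 * sem
        del counts

    def test_isotropic_arbor_has_zero_mean_resultant(self, rng):
        mcfg = default_morphology("control", radial_isotropy=True)
        vecs = []
        for _ in range(100):
            m = generate_oligo_morphology((0, 0, 50), mcfg, seed=rng)
            for sh in m.sheaths:
                for end in (sh.polyline[0], sh.polyline[-1]):
                    v = end[:2] - m.soma[:2]
                    vecs.append(v / np.linalg.norm(v))
        resultant = np.mean(vecs, axis=0)
        assert np.linalg.norm(resultant) < 0.05


class TestAxonField:
    def test_all_stable_final_equals_baseline(self):
        cfg = default_axon_field("control", destroy_prob=0.0, novel_rate=0.0,
                                 n_axons=20)
        f = generate_axon_field(cfg, seed=0)
        base = f.internodes[f.internodes["session"] == 0]
        final = f.internodes[f.internodes["session"] == 2]
        pd.testing.assert_frame_equal(
            base.drop(columns="session").reset_index(drop=True),
            final.drop(columns="session").reset_index(drop=True))

    def test_zero_axons_empty_field(self):
        f = generate_axon_field(default_axon_field("control", n_axons=0),
                                seed=0)
        assert len(f.internodes) == 0

    def test_invalid_fate_probabilities_rejected(self):
        with pytest.raises(ValueError):
            AxonFieldConfig(replace_prob_by_class=(1.4, 0.5, 0.5))

    def test_conditional_replacement_within_binomial_ci(self):
        cfg = default_axon_field("cuprizone")
        counts = {0: [0, 0], 1: [0, 0]}   # class-key -> [replaced, destroyed]
        for seed in range(3):
            f = generate_axon_field(cfg, seed=seed)
            for iid, fate in f.truth["fates"].items():
                if fate == "stable":
                    continue
                key = min(f.truth["neighbor_class"][iid], 1)
                counts[key][1] += 1
                counts[key][0] += fate == "replaced"
        for key, p_cfg in ((0, cfg.replace_prob_by_class[0]),
                           (1, cfg.replace_prob_by_class[1])):
            rep, n = counts[key]
            half = 1.96 * np.sqrt(p_cfg * (1 - p_cfg) / n)
            assert abs(rep / n - p_cfg) <= half

    def test_replacement_coverage_meets_threshold(self):
        cfg = default_axon_field("cuprizone", n_axons=40)
        f = generate_axon_field(cfg, seed=3)
        inter = f.internodes.set_index(["internode_id", "session"])
        for iid, rid in f.truth["replacement_map"].items():
            b = inter.loc[(iid, 0)]
            r = inter.loc[(rid, 2)]
            ov = max(0.0, min(b.s_end, r.s_end) - max(b.s_start, r.s_start))
            assert ov / (b.s_end - b.s_start) >= cfg.replace_coverage_min - 1e-9


class TestNodalPuncta:
    def test_zero_density_empty(self):
        nodal, para, truth = generate_nodal_puncta(
            default_puncta("control", 6, n_nodal=0), seed=0)
        assert len(nodal) == 0 and len(para) == 0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            PunctaConfig(n_nodal=-5)

    def test_flank_probabilities_recovered(self):
        pcfg = default_puncta("cuprizone", 4, n_nodal=400, ais_fraction=0.0)
        nodal, para, truth = generate_nodal_puncta(pcfg, seed=5)
        partners = [v for v in truth["partners"].values() if v is not None]
        for n_partner, p_cfg in zip((2, 1, 0), pcfg.flank_probs):
            phat = np.mean([v == n_partner for v in partners])
            half = 1.96 * np.sqrt(p_cfg * (1 - p_cfg) / len(partners))
            assert abs(phat - p_cfg) <= half + 1e-12
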
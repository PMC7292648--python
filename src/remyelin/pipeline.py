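"""End-to-end orchestration: simulate -> track -> displace -> morpho ->
territory -> sheaths -> nodes, with one machine-readable summary.

The stage functions here are the same ones used for headline statistics
(loss/addition fractions by depth zone, displacement means, census means,
territory overlap, internode-fate and nodal-class proportions); the
runner wires them together, manages seeds and writes per-stage outputs
plus a summary JSON.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import (VolumeSpec, default_axon_field, default_cohort,
                     default_morphology, default_puncta)
from .displacement import nearest_neighbor_displacement, self_self_displacement
from .morphometry import paranode_orientation, sheath_census
from .nodal import classify_puncta, exclude_ais, rotation_null
from .sheath_fate import classify_internode_fate, myelination_matrix, \
    select_window
from .synthetic import (generate_axon_field, generate_cell_population,
                        generate_nodal_puncta, generate_oligo_morphology)
from .territory import fit_containment_ellipsoid, random_placement_null, \
    rasterize_territories, territory_overlap
from .tracking import compute_rates, track_cells, track_zone

SCHEMA_VERSION = "1"
log = logging.getLogger("remyelin")

__all__ = [
    "cohort_statistics",
    "field_fate_statistics",
    "census_statistics",
    "run_pipeline",
    "summarize_report",
    "SCHEMA_VERSION",
]


def cohort_statistics(obs: pd.DataFrame, volume: VolumeSpec, cfg,
                      max_match_dist: float = 15.0) -> dict:
    """Track a simulated (or measured) cohort and summarize its kinetics.

    Returns per-mouse and mouse-averaged loss/addition statistics: the
    cumulative lost fraction of the baseline cohort at the end of the loss
    phase, the cumulative new-cell fraction at the final session, and
    zone-resolved final recovery (% of zone baseline), plus weekly rates.
    """
    weeks = sorted(obs["week"].unique())
    per_mouse = []
    all_tracks = {}
    for mouse, sub in obs.groupby("mouse_id"):
        tracks, drift, corrected = track_cells(sub, max_match_dist)
        all_tracks[mouse] = tracks
        rates = compute_rates(tracks, weeks)
        k_loss = weeks.index(min(cfg.loss_phase_end, weeks[-1]))
        zones = {t.track_id: track_zone(t, volume.zone_edges)
                 for t in tracks}
        zone_stats = []
        for zi in range(volume.n_zones):
            base = [t for t in tracks if t.first_seen == weeks[0]
                    and zones[t.track_id] == zi]
            present_final = [t for t in tracks if zones[t.track_id] == zi
                             and t.last_seen == weeks[-1]]
            zone_stats.append(dict(
                zone=zi, baseline=len(base),
                final_count=len(present_final),
                recovery_pct=(100.0 * len(present_final) / len(base))
                if base else float("nan")))
        per_mouse.append(dict(
            mouse_id=mouse,
            baseline_count=rates.baseline_count,
            lost_pct_at_loss_end=100.0 - rates.baseline_remaining_pct[k_loss],
            cumulative_new_pct_final=rates.cumulative_new_pct[-1],
            observed_pct_final=rates.observed_pct[-1],
            addition_rate_last=rates.addition_rate[-1],
            zones=zone_stats,
        ))
    mean = lambda key: float(np.mean([m[key] for m in per_mouse]))
    # zone recovery is pooled over mice (total final count / total
    # baseline): with only ~17 baseline cells per mouse in the top zone, a
    # mean of per-mouse ratios would be dominated by small-denominator
    # noise
    zone_pooled = []
    for zi in range(volume.n_zones):
        nb = sum(m["zones"][zi]["baseline"] for m in per_mouse)
        nf = sum(m["zones"][zi]["final_count"] for m in per_mouse)
        zone_pooled.append(100.0 * nf / nb if nb else float("nan"))
    return dict(
        weeks=list(weeks),
        per_mouse=per_mouse,
        lost_pct_at_loss_end=mean("lost_pct_at_loss_end"),
        cumulative_new_pct_final=mean("cumulative_new_pct_final"),
        observed_pct_final=mean("observed_pct_final"),
        zone_recovery_pct=zone_pooled,
        tracks=all_tracks,
    )


def field_fate_statistics(field, window_origin=None,
                          window_size: float = 100.0,
                          coverage_threshold: float = 0.5,
                          gap_threshold: float = 5.0) -> dict:
    """Internode fate proportions for one axon field, within one window.

    Classifies baseline-vs-final fates, measures destruction at the peak
    session, and cross-tabulates replacement against the baseline neighbor
    class.  Proportions are % of baseline internodes crossing the window.
    """
    inter = field.internodes
    base = inter[inter["session"] == 0]
    final = inter[inter["session"] == 2]
    peak_ids = set(inter.loc[inter["session"] == 1, "internode_id"])
    new_owners = set(field.truth["new_owners"])
    fates = classify_internode_fate(base, final, new_owners,
                                    coverage_threshold=coverage_threshold,
                                    gap_threshold=gap_threshold)
    if window_origin is not None:
        included = select_window(field, window_origin, window_size)
    else:
        included = set(inter["internode_id"])
    b = fates[(fates["session"] == "baseline")
              & fates["internode_id"].isin(included)]
    n = len(b)
    if n == 0:
        return dict(n_baseline=0)
    destroyed = int((~b["internode_id"].isin(peak_ids)).sum())
    repl = b[b["fate"] == "replaced"]
    fin_novel = fates[(fates["session"] == "final")
                      & (fates["fate"] == "novel")
                      & fates["internode_id"].isin(included)]
    stats = dict(
        n_baseline=n,
        stable_pct=100.0 * (b["fate"] == "stable").mean(),
        lost_pct=100.0 * (b["fate"] == "lost").mean(),
        replaced_pct=100.0 * (b["fate"] == "replaced").mean(),
        destroyed_at_peak_pct=100.0 * destroyed / n,
        novel_pct=100.0 * len(fin_novel) / n,
        replaced_ge1_neighbor_pct=(
            100.0 * (repl["neighbor_class"] >= 1).mean()
            if len(repl) else float("nan")),
        n_replaced=int(len(repl)),
    )
    stats["fates_frame"] = fates
    return stats


def census_statistics(morphs, day=None) -> dict:
    """Sheath census means over a set of morphologies."""
    rows = [sheath_census(m, day=day) for m in morphs]
    counts = np.array([r.sheath_count for r in rows], float)
    means = np.array([r.mean_length_um for r in rows], float)
    totals = np.array([r.total_length_mm for r in rows], float)
    return dict(
        n_cells=len(rows),
        mean_sheath_count=float(counts.mean()),
        mean_sheath_length_um=float(np.nanmean(means)),
        mean_total_length_mm=float(totals.mean()),
        rows=rows,
    )


def _aggregate_fields(field_stats) -> dict:
    keys = ["stable_pct", "lost_pct", "replaced_pct", "destroyed_at_peak_pct",
            "novel_pct", "replaced_ge1_neighbor_pct"]
    out = {}
    for k in keys:
        vals = [fs[k] for fs in field_stats if fs.get("n_baseline", 0) > 0]
        out[k] = float(np.nanmean(vals)) if vals else float("nan")
    out["n_baseline_total"] = int(sum(fs.get("n_baseline", 0)
                                      for fs in field_stats))
    return out


DEFAULT_STAGES = ("simulate", "track", "displace", "morpho", "territory",
                  "sheaths", "nodes")


def run_pipeline(outdir, seed: int = 0, condition: str = "cuprizone",
                 stages=DEFAULT_STAGES, volume: VolumeSpec | None = None,
                 n_morphologies: int = 60, n_fields: int = 3,
                 territory_null_reps: int = 10,
                 config_overrides: dict | None = None) -> dict:
    """Run the toggled stages end to end; returns the summary dict.

    Per-stage CSV/JSON land in ``outdir``; a single ``summary.json``
    collects the headline statistics.  All randomness derives from
    ``seed``.  Any stage failure raises with a stage-tagged message
    (partial outputs are retained on disk).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    volume = volume or VolumeSpec()
    overrides = config_overrides or {}
    stages = set(stages)
    summary = {"schema_version": SCHEMA_VERSION, "seed": seed,
               "condition": condition, "stages": sorted(stages)}
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(DEFAULT_STAGES,
                                      ss.spawn(len(DEFAULT_STAGES)))}
    state = {}

    def run_stage(name, fn):
        if name not in stages:
            return
        log.info("stage %s (seed %d)", name, stage_seeds[name])
        try:
            fn(stage_seeds[name])
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def _simulate(sd):
        cfg = default_cohort(condition, **overrides.get("cohort", {}))
        obs, truth = generate_cell_population(volume, cfg, seed=sd)
        rio.write_cells_csv(obs, outdir / "cells.csv")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        state["obs"], state["truth"], state["cohort_cfg"] = obs, truth, cfg
        summary["simulate"] = {"n_observations": int(len(obs)),
                               "n_mice": cfg.n_mice}

    def _track(sd):
        cfg = state.get("cohort_cfg") or default_cohort(condition)
        obs = state.get("obs")
        if obs is None:
            obs = rio.read_cells_csv(outdir / "cells.csv")
        stats = cohort_statistics(obs, volume, cfg)
        tracks_frames = []
        offset = 0
        for mouse, tracks in stats["tracks"].items():
            frame = rio.tracks_to_frame(tracks)
            frame["track_id"] += offset
            offset += len(tracks)
            frame.insert(0, "mouse_id", mouse)
            tracks_frames.append(frame)
        pd.concat(tracks_frames).to_csv(outdir / "tracks.csv", index=False)
        state["tracking"] = stats
        summary["tracking"] = {
            k: stats[k] for k in ("lost_pct_at_loss_end",
                                  "cumulative_new_pct_final",
                                  "observed_pct_final", "zone_recovery_pct")}

    def _displace(sd):
        stats = state.get("tracking")
        if stats is None:
            return
        weeks = stats["weeks"]
        nn_all, selfself = [], []
        final_by_zone0 = {}
        for mouse, tracks in stats["tracks"].items():
            base = np.array([t.positions[weeks[0]] for t in tracks
                             if weeks[0] in t.positions])
            fin = np.array([t.positions[t.last_seen] for t in tracks
                            if t.last_seen == weeks[-1]])
            if len(base) and len(fin):
                nn_all.append(nearest_neighbor_displacement(fin, base))
            selfself.append(self_self_displacement(tracks, weeks[0],
                                                   weeks[-1]))
            final_by_zone0[mouse] = [
                t.positions[t.last_seen] for t in tracks
                if t.last_seen == weeks[-1]
                and track_zone(t, volume.zone_edges) == 0]
        state["final_top_zone_cells"] = final_by_zone0
        all_d = np.concatenate([r.distances for r in nn_all]) \
            if nn_all else np.array([])
        ss_d = np.concatenate([r.distances for r in selfself]) \
            if selfself else np.array([])
        summary["displacement"] = {
            "all_cells_mean_um": float(all_d.mean()) if all_d.size else None,
            "self_self_mean_um": float(ss_d.mean()) if ss_d.size else None,
            "n_all": int(all_d.size), "n_self": int(ss_d.size)}

    def _morpho(sd):
        mcfg = default_morphology(
            "control" if condition == "control" else "regenerated",
            **overrides.get("morphology", {}))
        rng = np.random.default_rng(sd)
        morphs = []
        for i in range(n_morphologies):
            soma = np.array([rng.uniform(100, volume.x_extent - 100),
                             rng.uniform(100, volume.y_extent - 100),
                             rng.uniform(20, 80)])
            morphs.append(generate_oligo_morphology(
                soma, mcfg, seed=rng, cell_id=f"cell{i:03d}",
                condition=condition))
        stats = census_statistics(morphs, day=mcfg.mature_day)
        orient = [paranode_orientation(m)["mean_angle"] for m in morphs[:20]]
        pd.DataFrame([r.__dict__ for r in stats["rows"]]).to_csv(
            outdir / "census.csv", index=False)
        state["morphs"] = morphs
        summary["morphometry"] = {
            "mean_sheath_count": stats["mean_sheath_count"],
            "mean_sheath_length_um": stats["mean_sheath_length_um"],
            "mean_total_length_mm": stats["mean_total_length_mm"],
            "mean_orientation_rad": float(np.mean(orient))}

    def _territory(sd):
        morphs = state.get("morphs")
        if not morphs:
            return
        fits = []
        for m in morphs[:10]:
            pts = np.vstack([sh.polyline for sh in m.sheaths])
            fits.append(fit_containment_ellipsoid(pts))
        rx = float(np.mean([f.rx for f in fits]))
        rz = float(np.mean([f.rz for f in fits]))
        top = VolumeSpec(x_extent=volume.x_extent, y_extent=volume.y_extent,
                         z_extent=volume.zone_edges[1],
                         zone_edges=(0.0, volume.zone_edges[1]),
                         xy_voxel=volume.xy_voxel, z_voxel=volume.z_voxel)
        tr = state.get("tracking")
        result = {"model_rx_um": rx, "model_rz_um": rz}
        if tr is not None:
            weeks = tr["weeks"]
            mouse0 = sorted(tr["tracks"])[0]
            tracks = tr["tracks"][mouse0]
            base_c = [t.positions[weeks[0]] for t in tracks
                      if weeks[0] in t.positions
                      and track_zone(t, volume.zone_edges) == 0]
            rec_c = [t.positions[t.last_seen] for t in tracks
                     if t.last_seen == weeks[-1] and t.fate in ("new",)
                     and track_zone(t, volume.zone_edges) == 0]
            if base_c and rec_c:
                gb = rasterize_territories(np.array(base_c), rx, rz, top)
                gr = rasterize_territories(np.array(rec_c), rx, rz, top)
                ov = territory_overlap(gb, gr, len(base_c), len(rec_c))
                null = random_placement_null(
                    len(rec_c), rx, rz, top, gb, len(base_c),
                    reps=territory_null_reps, seed=sd)
                rio.write_grid(outdir / "baseline_grid", gb, top,
                               {"session": "baseline", "mouse": mouse0})
                result.update(
                    scaled_overlap=ov["scaled_overlap"],
                    extra_volume_fraction=ov["extra_volume_fraction"],
                    random_null_mean=null["mean"],
                    random_null_sem=null["sem"],
                    n_baseline=len(base_c), n_recovery=len(rec_c))
        summary["territory"] = result

    def _sheaths(sd):
        fcfg = default_axon_field(condition, **overrides.get("axon_field", {}))
        rng = np.random.default_rng(sd)
        stats = []
        for i in range(n_fields):
            field = generate_axon_field(
                fcfg, seed=int(rng.integers(2 ** 31)))
            origin = rng.uniform(0, fcfg.extent - 100.0, size=3)
            fs = field_fate_statistics(field, window_origin=origin)
            if i == 0:
                rio.write_internodes_csv(field.internodes,
                                         outdir / "internodes.csv")
                mat, summ = myelination_matrix(fs.pop("fates_frame"))
                np.savetxt(outdir / "myelination_matrix.csv", mat,
                           fmt="%d", delimiter=",")
            else:
                fs.pop("fates_frame", None)
            stats.append(fs)
        summary["sheaths"] = _aggregate_fields(stats)

    def _nodes(sd):
        result = {}
        rng = np.random.default_rng(sd)
        for duration in (4, 6):
            pcfg = default_puncta(condition, duration,
                                  **overrides.get("puncta", {}))
            nodal, para, truth = generate_nodal_puncta(
                pcfg, seed=int(rng.integers(2 ** 31)))
            kept, n_excl = exclude_ais(nodal)
            classed, counts = classify_puncta(kept, para)
            _rot, rot_counts = rotation_null(kept, para)
            rio.write_puncta_csv(pd.concat([nodal, para]),
                                 outdir / f"puncta_{duration}wk.csv")
            result[f"{duration}wk"] = {
                "proportions": counts["proportions"],
                "rotated_proportions": rot_counts["proportions"],
                "n": counts["n"], "ais_excluded": n_excl}
        summary["nodes"] = result

    run_stage("simulate", _simulate)
    run_stage("track", _track)
    run_stage("displace", _displace)
    run_stage("morpho", _morpho)
    run_stage("territory", _territory)
    run_stage("sheaths", _sheaths)
    run_stage("nodes", _nodes)

    serializable = _strip_unserializable(summary)
    (outdir / "summary.json").write_text(
        json.dumps(serializable, indent=1, sort_keys=True))
    return serializable


def _strip_unserializable(obj):
    if isinstance(obj, dict):
        return {k: _strip_unserializable(v) for k, v in obj.items()
            if not isinstance(v, (pd.DataFrame,))}
    if isinstance(obj, (list, tuple)):
        return [_strip_unserializable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        elif isinstance(v, (int, float)) and not isinstance(v, bool):
            out[key] = float(v)
    return out


def summarize_report(summary: dict, reference: pd.DataFrame) -> pd.DataFrame:
    """Compare a summary JSON against a reference-value table.

    ``reference`` needs columns statistic (dotted summary path), reference,
    tolerance.  Returns one row per reference entry with computed value,
    signed deviation and pass/fail; a missing statistic is a fail row, not
    an abort.  Summaries from a different schema version are refused.
    """
    if summary.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("summary schema version mismatch")
    flat = _flatten(summary)
    rows = []
    for row in reference.itertuples():
        computed = flat.get(row.statistic)
        if computed is None:
            rows.append(dict(statistic=row.statistic, computed=None,
                             reference=row.reference,
                             tolerance=row.tolerance, deviation=None,
                             passed=False))
            continue
        dev = computed - row.reference
        rows.append(dict(statistic=row.statistic, computed=computed,
                         reference=row.reference, tolerance=row.tolerance,
                         deviation=dev, passed=bool(abs(dev) <= row.tolerance)))
    return pd.DataFrame(rows)
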
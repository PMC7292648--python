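"""Synthetic longitudinal cortex datasets with known ground truth.

Four generators emulate the point/trace data the analysis pipeline
consumes: a longitudinal cell population with depth-dependent density,
scheduled loss and addition, rigid per-session registration drift and
detection jitter; single-cell sheath arbors; fields of intermittently
myelinated axons with session-resolved internode fates; and nodal /
paranodal immunopuncta fields.  Every generator returns observations plus
the ground truth needed to score downstream stages, and all randomness
flows from a single integer seed through deterministic per-unit substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import (AxonFieldConfig, CohortConfig, MorphologyConfig,
                     PunctaConfig, VolumeSpec)
from .morphometry import OligMorphology, SheathTrace

__all__ = [
    "generate_cell_population",
    "generate_oligo_morphology",
    "generate_axon_field",
    "generate_nodal_puncta",
    "AxonField",
]

CELL_COLUMNS = ["mouse_id", "cell_id", "week", "x_um", "y_um", "z_um"]


def _rng_of(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


# ---------------------------------------------------------------------------
# Cell population

def _sample_loss_week(weeks, schedule, rng) -> Optional[int]:
    for wk in weeks[1:]:
        h = schedule.get(wk, 0.0)
        if h > 0 and rng.random() < h:
            return wk
    return None


def generate_cell_population(volume: VolumeSpec, cfg: CohortConfig,
                             seed: int = 0):
    """Simulate a longitudinal cohort of oligodendrocyte soma detections.

    Baseline cells are uniform in x-y and zone-density-weighted in depth;
    each carries a ground-truth loss week drawn from the hazard schedule.
    New cells appear per the zone-resolved addition schedule, displaced
    from a uniformly chosen reference cell of the same zone by a lognormal
    radial kernel.  Observed coordinates are truth + per-session rigid
    drift + i.i.d. jitter.

    Returns ``(observations, truth)``: a DataFrame with columns
    mouse_id, cell_id, week, x_um, y_um, z_um, and a dict holding per-mouse
    ground truth (cells, fate timing, zones, drift vectors).
    """
    if min(volume.x_extent, volume.y_extent, volume.z_extent) <= 0:
        raise ValueError("zero-extent volume")
    weeks = list(cfg.session_weeks)
    if not weeks:
        raise ValueError("empty session list")
    n_zones = volume.n_zones
    addition = cfg.addition_schedule or tuple({} for _ in range(n_zones))
    if len(addition) != n_zones:
        raise ValueError("addition_schedule must have one entry per zone")

    streams = np.random.SeedSequence(seed).spawn(cfg.n_mice)
    rows, truth_mice = [], []
    for mi, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        mouse = f"m{mi}"
        cells = []  # dicts: id, true position, zone, appear_week, loss_week
        for zi in range(n_zones):
            lo, hi = volume.zone_edges[zi], volume.zone_edges[zi + 1]
            n0 = int(rng.poisson(cfg.baseline_density_by_zone[zi])) \
                if zi < len(cfg.baseline_density_by_zone) else 0
            for _ in range(n0):
                pos = np.array([rng.uniform(0, volume.x_extent),
                                rng.uniform(0, volume.y_extent),
                                rng.uniform(lo, hi)])
                cells.append(dict(
                    cell_id=f"{mouse}_c{len(cells):04d}", pos=pos, zone=zi,
                    appear_week=weeks[0],
                    loss_week=_sample_loss_week(weeks, cfg.loss_schedule, rng),
                ))
        baseline_by_zone = [[c for c in cells if c["zone"] == zi]
                            for zi in range(n_zones)]
        # additions: schedule is relative to the realized zone baseline
        for zi in range(n_zones):
            refs = baseline_by_zone[zi]
            lo, hi = volume.zone_edges[zi], volume.zone_edges[zi + 1]
            # error-diffusion rounding: the cumulative addition count stays
            # the nearest integer to the configured cumulative schedule
            # (starting the residual at 1/2 makes the rounding unbiased)
            resid = 0.5
            for wk in weeks[1:]:
                rate = addition[zi].get(wk, 0.0)
                x = rate * len(refs) + resid
                n_new = int(np.floor(x))
                resid = x - n_new
                for _ in range(n_new):
                    pos = None
                    if refs:
                        ref = refs[rng.integers(len(refs))]["pos"]
                        excess = max(cfg.displacement_mean
                                     - cfg.displacement_min, 1e-6)
                        mu = np.log(excess) - cfg.displacement_sigma ** 2 / 2
                        for _try in range(60):
                            r = cfg.displacement_min + rng.lognormal(
                                mu, cfg.displacement_sigma)
                            u = rng.normal(size=3)
                            u /= np.linalg.norm(u)
                            cand = ref + r * u
                            if (0 <= cand[0] < volume.x_extent
                                    and 0 <= cand[1] < volume.y_extent
                                    and lo <= cand[2] < hi):
                                pos = cand
                                break
                    if pos is None:
                        pos = np.array([rng.uniform(0, volume.x_extent),
                                        rng.uniform(0, volume.y_extent),
                                        rng.uniform(lo, hi)])
                    cells.append(dict(
                        cell_id=f"{mouse}_c{len(cells):04d}", pos=pos,
                        zone=zi, appear_week=wk, loss_week=None))
        drift = {weeks[0]: np.zeros(3)}
        for wk in weeks[1:]:
            drift[wk] = rng.normal(0, cfg.drift_sd, size=3)
        for wk in weeks:
            for c in cells:
                if c["appear_week"] > wk:
                    continue
                if c["loss_week"] is not None and wk >= c["loss_week"]:
                    continue
                obs = c["pos"] + drift[wk] + rng.normal(0, cfg.jitter_sd, 3)
                rows.append((mouse, c["cell_id"], wk, *obs))
        truth_mice.append(dict(
            mouse_id=mouse,
            cells={c["cell_id"]: dict(pos=c["pos"].tolist(), zone=c["zone"],
                                      appear_week=c["appear_week"],
                                      loss_week=c["loss_week"])
                   for c in cells},
            drift={wk: v.tolist() for wk, v in drift.items()},
        ))
    obs = pd.DataFrame(rows, columns=CELL_COLUMNS)
    truth = dict(condition=cfg.condition, session_weeks=weeks,
                 zone_edges=list(volume.zone_edges), mice=truth_mice)
    return obs, truth


# ---------------------------------------------------------------------------
# Single-cell morphology

def _draw_lengths(n, cfg: MorphologyConfig, rng) -> np.ndarray:
    mean, sd = cfg.sheath_length_mean, cfg.sheath_length_sd
    if sd <= 0:
        return np.full(n, mean)
    if cfg.length_dist == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, mean / shape, size=n)


def _sheath_polyline(midpoint, direction, length, spacing) -> np.ndarray:
    n = max(2, int(np.ceil(length / spacing)) + 1)
    t = np.linspace(-length / 2.0, length / 2.0, n)
    return midpoint[None, :] + t[:, None] * direction[None, :]


def generate_oligo_morphology(soma, mcfg: MorphologyConfig, seed=0,
                              cell_id: str = "cell",
                              condition: str = "") -> OligMorphology:
    """Generate one mature oligodendrocyte arbor around ``soma``.

    Sheath midpoints are uniform within the configured arbor ellipsoid;
    sheaths are near-horizontal straight segments with uniform azimuth
    (radially isotropic by default); process attachment points are uniform
    along each internode.  A ``prune_fraction`` of extra transient sheaths
    carries day-resolved length records ending in removal, emulating the
    refinement period before the mature form.
    """
    rng = _rng_of(seed)
    soma = np.asarray(soma, float).reshape(3)
    n_mature = max(0, int(round(rng.normal(mcfg.sheath_count_mean,
                                           mcfg.sheath_count_sd)))) \
        if mcfg.sheath_count_sd > 0 else int(round(mcfg.sheath_count_mean))
    n_pruned = _stochastic_round(mcfg.prune_fraction * n_mature, rng)
    lengths = np.clip(_draw_lengths(n_mature + n_pruned, mcfg, rng), 5.0, None)

    morph = OligMorphology(cell_id=cell_id, soma=soma,
                           day_from_appearance=mcfg.mature_day,
                           condition=condition)
    days = list(range(0, mcfg.mature_day + 1, 2))
    for i, length in enumerate(lengths):
        # uniform point in the arbor ellipsoid
        while True:
            u = rng.uniform(-1, 1, size=3)
            if u @ u <= 1.0:
                break
        mid = soma + u * np.array([mcfg.arbor_xy_radius,
                                   mcfg.arbor_xy_radius, mcfg.arbor_z_radius])
        phi = rng.uniform(0, 2 * np.pi) if mcfg.radial_isotropy \
            else rng.normal(0, 0.3)
        tilt = rng.normal(0, 0.1)
        direction = np.array([np.cos(phi), np.sin(phi), tilt])
        direction /= np.linalg.norm(direction)
        poly = _sheath_polyline(mid, direction, float(length),
                                mcfg.point_spacing)
        attach = rng.uniform(0, float(length))
        pruned = i >= n_mature
        day_lengths = {}
        if pruned:
            gone = int(rng.integers(4, 9))
            for d in days:
                day_lengths[d] = float(length) * min(1.0, 0.6 + 0.05 * d) \
                    if d < gone else None
        sh = SheathTrace(sheath_id=f"{cell_id}_s{i:03d}", cell_id=cell_id,
                         polyline=poly, attachment_arc=attach,
                         day_lengths=day_lengths)
        morph.sheaths.append(sh)
        # cytoplasmic process: straight run from soma to the attachment point
        arc = np.cumsum(np.r_[0.0, np.linalg.norm(np.diff(poly, axis=0),
                                                  axis=1)])
        k = int(np.searchsorted(arc, attach))
        k = min(k, poly.shape[0] - 1)
        morph.processes.append(np.vstack([soma, poly[k]]))
    return morph


# ---------------------------------------------------------------------------
# Axon fields

INTERNODE_COLUMNS = ["axon_id", "internode_id", "session",
                     "s_start", "s_end", "owner"]


@dataclass
class AxonField:
    """Axon polylines plus a session-resolved internode table.

    ``internodes`` is a long-format DataFrame (one row per internode per
    session present); ``axon_paths`` maps axon_id to an (n, 3) polyline
    sampled at fixed arc-length spacing; ``truth`` records per-baseline-
    internode fate and neighbor class, the replacement map and the set of
    regenerated (new) owner cells.
    """

    internodes: pd.DataFrame
    axon_paths: dict
    truth: dict = field(default_factory=dict)


def _axon_polyline(rng, extent: float, spacing: float,
                   total_len: float) -> np.ndarray:
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [np.zeros(3)]
    n = int(total_len / spacing)
    for _ in range(n):
        d = d + rng.normal(0, 0.03, size=3)   # slow direction wander
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + d * spacing)
    pts = np.asarray(pts)
    # anchor the arc midpoint inside the field so that window inclusion is
    # symmetric along the arc (no systematic in-field bias toward low s)
    anchor = rng.uniform(0, extent, size=3)
    return pts - pts[n // 2] + anchor


def generate_axon_field(cfg: AxonFieldConfig, seed: int = 0) -> AxonField:
    """Generate one field of intermittently myelinated axons with fates.

    Sessions are 0 (baseline), 1 (peak demyelination) and 2 (final
    recovery).  Baseline internodes are laid out in runs separated by node
    gaps (<5 um) inside runs and long bare gaps between runs; ground-truth
    fates are drawn per internode with replacement probability conditional
    on the baseline neighbor class.  Replaced internodes are covered by a
    new-owner sheath occupying >= the configured coverage fraction of the
    baseline interval; novel internodes appear on bare stretches.
    """
    for probs in (cfg.replace_prob_by_class,):
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("fate probabilities must lie in [0,1]")
    rng = _rng_of(seed)
    spacing = cfg.point_spacing
    total_len = 3.0 * cfg.extent
    rows = []
    axon_paths = {}
    fates, classes, repl_map = {}, {}, {}
    new_owners = set()
    novel_ids = []
    n_new_cells = 0

    baseline = []   # (axon, iid, s0, s1, owner)
    bare_gaps = []  # (axon, g0, g1)
    for ai in range(cfg.n_axons):
        axon = f"a{ai:03d}"
        s = rng.uniform(0, 15)
        idx = 0
        # every drawn run is emitted in full (a fit check at the axon end
        # would bias the surviving run-length mix toward singletons and
        # distort the neighbor-class distribution); the polyline below is
        # built to cover the realized arc
        while s < total_len:
            k = 1 + rng.choice(len(cfg.run_length_probs),
                               p=cfg.run_length_probs)
            for j in range(int(k)):
                L = float(np.clip(rng.lognormal(
                    np.log(cfg.internode_length_mean) - 0.045, 0.3),
                    20.0, 120.0))
                iid = f"{axon}_i{idx:03d}"
                owner = f"bcell_{axon}_{idx}"
                baseline.append((axon, iid, s, s + L, owner))
                idx += 1
                s += L
                if j < int(k) - 1:
                    s += rng.uniform(*cfg.node_gap_range)
            if s >= total_len:
                break
            g = rng.uniform(*cfg.bare_gap_range)
            if s + g < total_len:
                bare_gaps.append((axon, s, s + g))
            s += g
        axon_paths[axon] = _axon_polyline(rng, cfg.extent, spacing, s + 20.0)

    # ground-truth neighbor classes from the baseline layout
    by_axon = {}
    for rec in baseline:
        by_axon.setdefault(rec[0], []).append(rec)
    for axon, recs in by_axon.items():
        recs.sort(key=lambda r: r[2])
        for i, (ax, iid, s0, s1, owner) in enumerate(recs):
            c = 0
            if i > 0 and s0 - recs[i - 1][3] < 5.0:
                c += 1
            if i < len(recs) - 1 and recs[i + 1][2] - s1 < 5.0:
                c += 1
            classes[iid] = c

    for axon, iid, s0, s1, owner in baseline:
        rows.append((axon, iid, 0, s0, s1, owner))
        destroyed = rng.random() < cfg.destroy_prob
        if not destroyed:
            fates[iid] = "stable"
            rows.append((axon, iid, 1, s0, s1, owner))
            rows.append((axon, iid, 2, s0, s1, owner))
            continue
        p_rep = cfg.replace_prob_by_class[min(classes[iid], 2)]
        if rng.random() < p_rep:
            fates[iid] = "replaced"
            L = s1 - s0
            cov = rng.uniform(cfg.replace_coverage_min,
                              cfg.replace_coverage_max)
            slack = (1.0 - cov) * L
            a = rng.uniform(0, slack)
            owner_new = f"ncell_{n_new_cells:04d}"
            n_new_cells += 1
            new_owners.add(owner_new)
            rid = f"{iid}_r"
            repl_map[iid] = rid
            rows.append((axon, rid, 2, s0 + a, s1 - (slack - a), owner_new))
        else:
            fates[iid] = "lost"

    # novel internodes on bare stretches, never overlapping prior myelin
    n_novel = _stochastic_round(cfg.novel_rate * len(baseline), rng)
    usable = [g for g in bare_gaps if (g[2] - g[1]) >= 20.0]
    rng.shuffle(usable)
    for k in range(min(n_novel, len(usable))):
        axon, g0, g1 = usable[k]
        inner0, inner1 = g0 + 5.0, g1 - 5.0
        L = float(min(np.clip(rng.lognormal(
            np.log(cfg.internode_length_mean) - 0.045, 0.3), 15.0, 120.0),
            inner1 - inner0))
        start = rng.uniform(inner0, inner1 - L) if inner1 - L > inner0 \
            else inner0
        owner_new = f"ncell_{n_new_cells:04d}"
        n_new_cells += 1
        new_owners.add(owner_new)
        nid = f"{axon}_n{k:03d}"
        novel_ids.append(nid)
        rows.append((axon, nid, 2, start, start + L, owner_new))

    internodes = pd.DataFrame(rows, columns=INTERNODE_COLUMNS)
    truth = dict(fates=fates, neighbor_class=classes,
                 replacement_map=repl_map, new_owners=sorted(new_owners),
                 novel_ids=novel_ids)
    return AxonField(internodes=internodes, axon_paths=axon_paths,
                     truth=truth)


# ---------------------------------------------------------------------------
# Nodal / paranodal puncta

PUNCTA_COLUMNS = ["marker", "punctum_id", "x_um", "y_um", "z_um", "length_um"]


def generate_nodal_puncta(pcfg: PunctaConfig, seed: int = 0):
    """Generate nodal-marker and paranodal puncta fields with known classes.

    Nodal puncta are placed with a hard-core minimum separation; each
    non-AIS punctum receives 0/1/2 paranodal partners within the pairing
    distance per ``flank_probs``.  A fraction of elongated AIS-like
    structures (> 6 um) is included, and stray paranodal puncta are
    scattered away from nodal puncta.  Returns ``(nodal_df, paranodal_df,
    truth)`` with ground-truth partner counts.
    """
    if pcfg.n_nodal < 0:
        raise ValueError("negative density")
    rng = _rng_of(seed)
    ext = np.array([pcfg.field_xy, pcfg.field_xy, pcfg.field_z])
    centers = []
    tries = 0
    while len(centers) < pcfg.n_nodal and tries < 200 * max(pcfg.n_nodal, 1):
        tries += 1
        cand = rng.uniform(0, 1, 3) * ext
        if all(np.linalg.norm(cand - c) >= pcfg.min_separation
               for c in centers):
            centers.append(cand)

    nodal_rows, para_rows = [], []
    truth_partners = {}
    n_para = 0
    for i, c in enumerate(centers):
        pid = f"nd{i:04d}"
        is_ais = rng.random() < pcfg.ais_fraction
        length = rng.uniform(*(pcfg.ais_length_range if is_ais
                               else pcfg.punctum_length_range))
        nodal_rows.append(("nodal", pid, *c, length))
        if is_ais:
            truth_partners[pid] = None   # excluded upstream of classing
            continue
        k = rng.choice(3, p=pcfg.flank_probs)
        n_partners = (2, 1, 0)[k]
        truth_partners[pid] = n_partners
        for _ in range(n_partners):
            d = rng.uniform(*pcfg.partner_distance_range)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p = c + d * u
            para_rows.append(("paranodal", f"pp{n_para:04d}", *p,
                              rng.uniform(*pcfg.punctum_length_range)))
            n_para += 1
    n_stray = _stochastic_round(pcfg.stray_paranodal_fraction * len(centers),
                                rng)
    placed = 0
    tries = 0
    while placed < n_stray and tries < 200 * max(n_stray, 1):
        tries += 1
        cand = rng.uniform(0, 1, 3) * ext
        if all(np.linalg.norm(cand - c) >= 4.5 for c in centers):
            para_rows.append(("paranodal", f"pp{n_para:04d}", *cand,
                              rng.uniform(*pcfg.punctum_length_range)))
            n_para += 1
            placed += 1

    nodal = pd.DataFrame(nodal_rows, columns=PUNCTA_COLUMNS)
    para = pd.DataFrame(para_rows, columns=PUNCTA_COLUMNS)
    truth = dict(partners=truth_partners,
                 field_extent=[pcfg.field_xy, pcfg.field_xy, pcfg.field_z])
    return nodal, para, truth
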
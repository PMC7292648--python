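"""Longitudinal cell tracking: drift correction, matching, fate calling and
depth-resolved loss/addition rates.

Registration drift between sessions is removed with an iterative scheme
(mutual-nearest matching -> mean displacement of matched pairs -> subtract
-> re-match) that converges to the average movement vector of all cells
once the matching is correct.  Tracks are chained session to session; a
track absent for a single session may re-join (detection dropouts), and
"lost" means absent from some session through the end of the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "correct_drift",
    "match_cells",
    "CellTrack",
    "build_tracks",
    "track_cells",
    "RateSeries",
    "compute_rates",
    "bin_by_depth",
    "project_full_recovery",
]

DEFAULT_MAX_MATCH_DIST = 15.0


def match_cells(obs_a: np.ndarray, obs_b: np.ndarray,
                max_match_dist: float = DEFAULT_MAX_MATCH_DIST):
    """Mutual-nearest-neighbor correspondences between two point sets.

    Returns a list of ``(i, j, distance)`` sorted by distance then index.
    A pair is kept when a_i's nearest b is b_j, b_j's nearest a is a_i, and
    their distance is within ``max_match_dist``; unmatched points on either
    side are the candidate lost / new cells.
    """
    a = np.asarray(obs_a, float).reshape(-1, 3)
    b = np.asarray(obs_b, float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        return []
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tree_b.query(a)
    d_ba, i_ba = tree_a.query(b)
    pairs = []
    for i in range(a.shape[0]):
        j = int(j_ab[i])
        if i_ba[j] == i and d_ab[i] <= max_match_dist:
            pairs.append((i, j, float(d_ab[i])))
    pairs.sort(key=lambda t: (t[2], t[0]))
    return pairs


def correct_drift(obs_a: np.ndarray, obs_b: np.ndarray,
                  max_match_dist: float = DEFAULT_MAX_MATCH_DIST,
                  tol: float = 0.1, max_iter: int = 10):
    """Estimate and remove the rigid inter-session drift from ``obs_b``.

    Iterates matching and mean-displacement subtraction until the drift
    update changes by less than ``tol`` um or ``max_iter`` rounds.  Returns
    ``(obs_b_corrected, drift_vector, matched_flag)``; with no matched
    pairs the drift is zero and the flag False.
    """
    a = np.asarray(obs_a, float).reshape(-1, 3)
    b = np.asarray(obs_b, float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sessions must be non-empty")
    drift = np.zeros(3)
    prev_norm = np.inf
    matched = False
    for _ in range(max_iter):
        pairs = match_cells(a, b - drift, max_match_dist)
        if not pairs:
            if not matched:
                warnings.warn("no cells matched; returning zero drift")
                return b.copy(), np.zeros(3), False
            break
        matched = True
        idx_a = np.array([p[0] for p in pairs])
        idx_b = np.array([p[1] for p in pairs])
        delta = ((b - drift)[idx_b] - a[idx_a]).mean(axis=0)
        drift = drift + delta
        if abs(np.linalg.norm(drift) - prev_norm) < tol:
            break
        prev_norm = np.linalg.norm(drift)
    return b - drift, drift, matched


@dataclass
class CellTrack:
    """One soma followed across sessions, positions in the baseline frame."""

    track_id: int
    positions: dict = field(default_factory=dict)   # week -> (3,) array
    obs_rows: dict = field(default_factory=dict)    # week -> source row index
    fate: str = ""

    @property
    def first_seen(self):
        return min(self.positions)

    @property
    def last_seen(self):
        return max(self.positions)

    def position_at(self, week):
        return self.positions.get(week)


def _assign_fates(tracks, baseline_week, final_week):
    for t in tracks:
        at_baseline = t.first_seen == baseline_week
        to_end = t.last_seen == final_week
        if at_baseline:
            t.fate = "stable" if to_end else "lost"
        else:
            t.fate = "new" if to_end else "new_then_lost"


def build_tracks(correspondences, session_positions, weeks,
                 dropout_tolerance: int = 1):
    """Chain per-session correspondences into tracks and call fates.

    ``correspondences[k]`` lists ``(i, j)`` row pairs linking session
    ``weeks[k]`` to ``weeks[k+1]``; ``session_positions[week]`` holds the
    drift-corrected coordinate array of each session.  Fate rules: present
    at baseline and at the final session -> stable; present at baseline and
    absent from some session onward -> lost; first seen after baseline ->
    new (or new_then_lost when it also disappears).
    """
    weeks = list(weeks)
    tracks = []
    open_by_row = {}   # row index in latest session -> track
    for ti in range(len(session_positions[weeks[0]])):
        t = CellTrack(track_id=len(tracks))
        t.positions[weeks[0]] = np.asarray(
            session_positions[weeks[0]][ti], float)
        t.obs_rows[weeks[0]] = ti
        tracks.append(t)
        open_by_row[ti] = t
    for k, pairs in enumerate(correspondences):
        wk_next = weeks[k + 1]
        seen = set()
        next_open = {}
        for i, j in [(p[0], p[1]) for p in pairs]:
            if j in seen:
                raise ValueError(f"duplicate correspondence for cell {j}")
            seen.add(j)
            t = open_by_row.get(i)
            if t is None:
                continue
            t.positions[wk_next] = np.asarray(
                session_positions[wk_next][j], float)
            t.obs_rows[wk_next] = j
            next_open[j] = t
        for j in range(len(session_positions[wk_next])):
            if j not in seen:
                t = CellTrack(track_id=len(tracks))
                t.positions[wk_next] = np.asarray(
                    session_positions[wk_next][j], float)
                t.obs_rows[wk_next] = j
                tracks.append(t)
                next_open[j] = t
        open_by_row = next_open
    _assign_fates(tracks, weeks[0], weeks[-1])
    return tracks


def track_cells(obs: pd.DataFrame,
                max_match_dist: float = DEFAULT_MAX_MATCH_DIST,
                dropout_tolerance: int = 1):
    """Full tracking for one mouse: drift-correct, match, chain, call fates.

    ``obs`` needs columns week, x_um, y_um, z_um (one mouse).  Sessions are
    drift-corrected sequentially into the baseline frame.  Matching links
    consecutive sessions; detections unmatched at session t are offered to
    tracks last seen at t-2 (single-session dropout re-join) before
    becoming new tracks.  Returns ``(tracks, drift_by_week,
    corrected_positions_by_week)``.
    """
    weeks = sorted(obs["week"].unique())
    raw = {wk: obs.loc[obs["week"] == wk, ["x_um", "y_um", "z_um"]]
           .to_numpy() for wk in weeks}
    corrected = {weeks[0]: raw[weeks[0]]}
    drift = {weeks[0]: np.zeros(3)}
    for prev, wk in zip(weeks, weeks[1:]):
        if len(raw[wk]) == 0 or len(corrected[prev]) == 0:
            corrected[wk] = raw[wk].copy()
            drift[wk] = drift[prev].copy()
            continue
        corr, d, _ = correct_drift(corrected[prev], raw[wk], max_match_dist)
        corrected[wk] = corr
        drift[wk] = d

    tracks = []
    open_tracks = []   # tracks eligible for matching (recently seen)
    for ti, pos in enumerate(corrected[weeks[0]]):
        t = CellTrack(track_id=ti)
        t.positions[weeks[0]] = pos
        t.obs_rows[weeks[0]] = ti
        tracks.append(t)
        open_tracks.append(t)
    for k, wk in enumerate(weeks[1:], start=1):
        pts = corrected[wk]
        window = weeks[max(0, k - 1 - dropout_tolerance):k]
        candidates = [t for t in open_tracks if t.last_seen in window]
        if candidates and len(pts):
            ref = np.array([t.positions[t.last_seen] for t in candidates])
            pairs = match_cells(ref, pts, max_match_dist)
        else:
            pairs = []
        used_t, used_j = set(), set()
        for i, j, _d in pairs:
            if i in used_t or j in used_j:
                continue
            used_t.add(i)
            used_j.add(j)
            t = candidates[i]
            t.positions[wk] = pts[j]
            t.obs_rows[wk] = j
        for j in range(len(pts)):
            if j not in used_j:
                t = CellTrack(track_id=len(tracks))
                t.positions[wk] = pts[j]
                t.obs_rows[wk] = j
                tracks.append(t)
        open_tracks = [t for t in tracks
                       if t.last_seen in weeks[max(0, k - dropout_tolerance):k + 1]]
    _assign_fates(tracks, weeks[0], weeks[-1])
    return tracks, drift, corrected


@dataclass
class RateSeries:
    """Loss/addition rates per interval, as % of baseline per week."""

    weeks: list
    baseline_count: int
    loss_rate: np.ndarray        # aligned to weeks[1:]
    addition_rate: np.ndarray    # aligned to weeks[1:]
    baseline_remaining_pct: np.ndarray   # aligned to weeks
    cumulative_new_pct: np.ndarray       # aligned to weeks
    observed_pct: np.ndarray             # aligned to weeks


def compute_rates(tracks: Sequence[CellTrack], weeks: Sequence,
                  baseline_week=None) -> RateSeries:
    """Per-interval loss/addition rates and cumulative fraction curves.

    Rates are normalized to the baseline population and interval duration
    in weeks; cumulative curves report baseline cells remaining, new cells
    accumulated, and total observed cells, each as % of baseline.
    """
    weeks = sorted(weeks)
    if baseline_week is None:
        baseline_week = weeks[0]
    base = [t for t in tracks if t.first_seen == baseline_week]
    n0 = len(base)
    if n0 == 0:
        raise ValueError("baseline count is zero")
    loss_week = {}
    for t in base:
        if t.last_seen < weeks[-1]:
            later = [w for w in weeks if w > t.last_seen]
            loss_week[t.track_id] = later[0]
    appear_week = {t.track_id: t.first_seen for t in tracks
                   if t.first_seen > baseline_week}

    loss_rate, add_rate = [], []
    for a, b in zip(weeks, weeks[1:]):
        span = b - a
        nl = sum(1 for w in loss_week.values() if a < w <= b)
        na = sum(1 for w in appear_week.values() if a < w <= b)
        loss_rate.append(nl / (n0 * span) * 100.0)
        add_rate.append(na / (n0 * span) * 100.0)
    remaining, cum_new, observed = [], [], []
    for w in weeks:
        # remaining tolerates single-session dropouts (gap-filled); the
        # observed curve counts actual detections, which partition exactly
        # across tracks (conservation identity)
        nr = sum(1 for t in base if w in t.positions
                 or (t.last_seen >= w >= t.first_seen))
        nr_det = sum(1 for t in base if w in t.positions)
        nn_det = sum(1 for t in tracks if t.first_seen > baseline_week
                     and w in t.positions)
        remaining.append(nr / n0 * 100.0)
        cum_new.append(sum(1 for wk in appear_week.values() if wk <= w)
                       / n0 * 100.0)
        observed.append((nr_det + nn_det) / n0 * 100.0)
    return RateSeries(weeks=list(weeks), baseline_count=n0,
                      loss_rate=np.array(loss_rate),
                      addition_rate=np.array(add_rate),
                      baseline_remaining_pct=np.array(remaining),
                      cumulative_new_pct=np.array(cum_new),
                      observed_pct=np.array(observed))


def bin_by_depth(z, zone_edges) -> np.ndarray:
    """Half-open depth-zone labels [edge_i, edge_{i+1}) for z in um.

    Depths below zero are an error; depths at or beyond the last edge get
    label -1 (outside the zoned volume).
    """
    z = np.atleast_1d(np.asarray(z, float))
    if np.any(z < 0):
        raise ValueError("depth z must be >= 0 (um from pial surface)")
    edges = np.asarray(zone_edges, float)
    idx = np.searchsorted(edges, z, side="right") - 1
    idx[(z >= edges[-1]) | (idx < 0)] = -1
    return idx


def track_zone(track: CellTrack, zone_edges) -> int:
    """Zone membership frozen at the track's (first-seen) position.

    Somata are static, so the track's mean drift-corrected position over
    its observed sessions is the best estimate of that position; averaging
    suppresses single-session jitter at zone boundaries.
    """
    z = float(np.mean([p[2] for p in track.positions.values()]))
    return int(bin_by_depth(max(z, 0.0), zone_edges)[0])


def project_full_recovery(current_fraction_pct: float,
                          weekly_addition_rate_pct: float) -> float:
    """Weeks to reach 100% of baseline at the given weekly addition rate."""
    if current_fraction_pct >= 100.0:
        return 0.0
    if weekly_addition_rate_pct <= 0:
        return float("inf")
    return (100.0 - current_fraction_pct) / weekly_addition_rate_pct
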
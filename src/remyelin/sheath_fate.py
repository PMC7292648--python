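"""Internode fate and neighbor-class analysis across a demyelination series.

Internodes are arc-length intervals along axon paths.  Fate rules: an
internode supplied by the same cell at baseline and at the final session is
*stable*; a baseline internode covered over at least half its length (by
default) by sheath(s) of regenerated cells is *replaced*; otherwise it is
*lost*.  Final-session sheaths of regenerated cells not acting as
replacements are *novel*.  A sheath's neighbor class (0/1/2) counts its
ends that lie within a node-gap threshold (default 5 um) of another
internode on the same axon.  Nodes of Ranvier are detected from intensity
profiles as narrow dips (<5 um) between two local maxima, dipping below
the internode floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "NodeCall",
    "detect_nodes_from_profile",
    "neighbor_class",
    "classify_internode_fate",
    "myelination_matrix",
    "select_window",
    "FATES",
]

FATES = ("stable", "lost", "replaced", "novel", "undefined")


@dataclass(frozen=True)
class NodeCall:
    position_um: float
    gap_um: float
    left_max: float
    right_max: float
    dip_min: float


def detect_nodes_from_profile(positions, intensities,
                              gap_limit: float = 5.0,
                              max_pitch: float = 0.5) -> list:
    """Find node-of-Ranvier candidates in an intensity profile along a path.

    A candidate is a local minimum between two local maxima that dips below
    the flanking internode floor; its gap is the contiguous span below the
    mid-reference level (halfway between dip and the lower flanking peak).
    A node is called iff the gap is shorter than ``gap_limit``.
    """
    x = np.asarray(positions, float).ravel()
    y = np.asarray(intensities, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("positions and intensities must align, n >= 3")
    if x[-1] - x[0] < 5.0:
        raise ValueError("profile must span at least 5 um")
    pitch = np.diff(x)
    if np.any(pitch <= 0):
        raise ValueError("positions must be strictly increasing")
    if pitch.max() > max_pitch + 1e-9:
        raise ValueError(f"sampling pitch must be <= {max_pitch} um")

    # pad with -inf so flat internode levels running to the profile ends
    # still register as flanking maxima
    padded = np.concatenate([[-np.inf], y, [-np.inf]])
    peaks, _ = find_peaks(padded, plateau_size=1)
    peaks = peaks - 1
    calls = []
    for a, b in zip(peaks, peaks[1:]):
        seg = y[a:b + 1]
        k = a + int(np.argmin(seg))
        dip = float(y[k])
        # internode floor: lowest level on the outer flanks of the two peaks
        left_floor = float(y[:a + 1].min()) if a > 0 else float(y[a])
        right_floor = float(y[b:].min()) if b < y.size - 1 else float(y[b])
        floor = min(left_floor, right_floor)
        if dip >= floor:
            continue
        ref = 0.5 * (dip + min(y[a], y[b]))
        lo = k
        while lo > a and y[lo - 1] < ref:
            lo -= 1
        hi = k
        while hi < b and y[hi + 1] < ref:
            hi += 1
        # the gap spans between the nearest flanking samples at/above the
        # mid-reference level (the bright processes bounding the dark gap)
        lo_above = max(lo - 1, a)
        hi_above = min(hi + 1, b)
        gap = float(x[hi_above] - x[lo_above])
        if gap < gap_limit:
            calls.append(NodeCall(
                position_um=float((x[lo_above] + x[hi_above]) / 2),
                gap_um=gap, left_max=float(y[a]),
                right_max=float(y[b]), dip_min=dip))
    return calls


def _check_no_overlap(intervals) -> None:
    ivs = sorted(intervals)
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError("overlapping internodes on one axon "
                             "(invalid tracing)")


def neighbor_class(interval, co_axonal_intervals,
                   gap_threshold: float = 5.0) -> int:
    """Number of this internode's ends (0/1/2) with a neighbor within reach.

    Distances are measured end-to-end along the axon's arc-length
    coordinate.  All intervals must belong to one axon at one session;
    overlaps are an error.
    """
    s0, s1 = float(interval[0]), float(interval[1])
    if s1 <= s0:
        raise ValueError("internode interval must have s_end > s_start")
    others = [(float(a), float(b)) for a, b in co_axonal_intervals]
    _check_no_overlap(others + [(s0, s1)])
    left = any(0 <= s0 - b < gap_threshold for _, b in others)
    right = any(0 <= a - s1 < gap_threshold for a, _ in others)
    return int(left) + int(right)


def _overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _union_length(intervals) -> float:
    if not intervals:
        return 0.0
    ivs = sorted(intervals)
    total, cur0, cur1 = 0.0, ivs[0][0], ivs[0][1]
    for a, b in ivs[1:]:
        if a > cur1:
            total += cur1 - cur0
            cur0, cur1 = a, b
        else:
            cur1 = max(cur1, b)
    return total + (cur1 - cur0)


def classify_internode_fate(baseline: pd.DataFrame, final: pd.DataFrame,
                            new_owners, coverage_threshold: float = 0.5,
                            multi_sheath: bool = True,
                            gap_threshold: float = 5.0) -> pd.DataFrame:
    """Classify every baseline and final internode on shared axon coordinates.

    ``baseline`` and ``final`` need columns axon_id, internode_id, s_start,
    s_end, owner (single sessions each).  ``new_owners`` is the set of
    regenerated-cell ids.  Replacement coverage is the union of new-owner
    overlaps by default (``multi_sheath=False`` restricts to the single
    best sheath).  Returns one row per internode with columns session
    ('baseline'/'final'), fate, neighbor_class and replacement linkage;
    final sheaths with owners that are neither baseline owners nor listed
    new owners are 'undefined'.
    """
    new_owners = set(new_owners)
    base_owners = set(baseline["owner"])
    out = []
    replacement_of = {}

    fin_by_axon = {ax: g for ax, g in final.groupby("axon_id")}
    base_by_axon = {ax: g for ax, g in baseline.groupby("axon_id")}

    def classes_for(df):
        res = {}
        ivs = list(zip(df["s_start"], df["s_end"]))
        for i, row in enumerate(df.itertuples()):
            others = ivs[:i] + ivs[i + 1:]
            res[row.internode_id] = neighbor_class(
                (row.s_start, row.s_end), others, gap_threshold)
        return res

    base_class = {}
    for ax, g in base_by_axon.items():
        base_class.update(classes_for(g))
    final_class = {}
    for ax, g in fin_by_axon.items():
        final_class.update(classes_for(g))

    for ax, g in base_by_axon.items():
        fin = fin_by_axon.get(ax)
        for row in g.itertuples():
            L = row.s_end - row.s_start
            fate, repl_id, final_cls = None, None, None
            if fin is not None:
                same, news = [], []
                for f in fin.itertuples():
                    ov = _overlap(row.s_start, row.s_end, f.s_start, f.s_end)
                    if ov <= 0:
                        continue
                    if f.owner == row.owner:
                        same.append((ov, f.internode_id))
                    elif f.owner in new_owners:
                        news.append((ov, f.internode_id, f.s_start, f.s_end))
                if same:
                    fate = "stable"
                    final_cls = final_class[max(same)[1]]
                elif news:
                    if multi_sheath:
                        cov = _union_length(
                            [(max(row.s_start, a), min(row.s_end, b))
                             for _, _, a, b in news]) / L
                    else:
                        cov = max(ov for ov, *_ in news) / L
                    if cov >= coverage_threshold:
                        fate = "replaced"
                        # identity maps to the largest-overlap new sheath,
                        # ties toward the lower id
                        news.sort(key=lambda t: (-t[0], t[1]))
                        repl_id = news[0][1]
                        replacement_of[repl_id] = row.internode_id
                        final_cls = final_class[repl_id]
            if fate is None:
                fate = "lost"
            out.append(dict(session="baseline", axon_id=ax,
                            internode_id=row.internode_id, owner=row.owner,
                            s_start=row.s_start, s_end=row.s_end, fate=fate,
                            neighbor_class=base_class[row.internode_id],
                            final_neighbor_class=final_cls,
                            replacement_id=repl_id))

    repl_targets = set(replacement_of)
    for ax, g in fin_by_axon.items():
        for f in g.itertuples():
            if f.owner in base_owners:
                fate = "stable"
            elif f.owner in new_owners:
                fate = "replaced" if f.internode_id in repl_targets \
                    else "novel"
            else:
                fate = "undefined"
            out.append(dict(session="final", axon_id=ax,
                            internode_id=f.internode_id, owner=f.owner,
                            s_start=f.s_start, s_end=f.s_end, fate=fate,
                            neighbor_class=final_class[f.internode_id],
                            final_neighbor_class=final_class[f.internode_id],
                            replacement_id=replacement_of.get(f.internode_id)))
    return pd.DataFrame(out)


def myelination_matrix(fates: pd.DataFrame, max_class: int = 2):
    """Baseline-vs-final neighbor-class transition counts plus summaries.

    ``fates`` is the output of :func:`classify_internode_fate`.  The matrix
    counts internodes present at both endpoints (stable or replaced) by
    (baseline class, final class); summaries report isolated vs >= 1
    neighbor proportions per time-point and fate proportions conditioned on
    baseline class, excluding 'undefined' (whose count is reported).
    """
    base = fates[fates["session"] == "baseline"]
    both = base[base["fate"].isin(["stable", "replaced"])]
    m = np.zeros((max_class + 1, max_class + 1), dtype=int)
    for row in both.itertuples():
        if pd.isna(row.final_neighbor_class):
            continue
        m[int(row.neighbor_class), int(row.final_neighbor_class)] += 1

    def iso_split(df):
        n = len(df)
        if n == 0:
            return {"isolated": float("nan"), "ge1": float("nan"), "n": 0}
        iso = int((df["neighbor_class"] == 0).sum())
        return {"isolated": iso / n, "ge1": 1 - iso / n, "n": n}

    final = fates[(fates["session"] == "final")
                  & (fates["fate"] != "undefined")]
    defined = base[base["fate"] != "undefined"]
    fate_by_class = {}
    for cls_label, sub in (("0", defined[defined["neighbor_class"] == 0]),
                           ("ge1", defined[defined["neighbor_class"] >= 1])):
        n = len(sub)
        fate_by_class[cls_label] = {
            f: (int((sub["fate"] == f).sum()) / n if n else float("nan"))
            for f in ("stable", "lost", "replaced")}
    summaries = {
        "baseline": iso_split(defined),
        "final": iso_split(final),
        "fate_by_baseline_class": fate_by_class,
        "n_undefined": int((fates["fate"] == "undefined").sum()),
    }
    return m, summaries


def select_window(field, origin, size: float = 100.0) -> set:
    """Internode ids of a field crossing a cubic analysis window.

    ``field`` is a synthetic AxonField (axon paths sampled at fixed
    spacing); an internode is included if any sample point of its arc
    interval falls inside the axis-aligned cube at ``origin`` with edge
    ``size`` (it "passes through" the window).
    """
    o = np.asarray(origin, float).reshape(3)
    included = set()
    arcs = {}
    for ax, path in field.axon_paths.items():
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        arcs[ax] = np.concatenate([[0.0], np.cumsum(seg)])
    for row in field.internodes.itertuples():
        path = field.axon_paths[row.axon_id]
        arc = arcs[row.axon_id]
        sel = (arc >= row.s_start) & (arc <= row.s_end)
        pts = path[sel]
        if pts.size == 0:
            continue
        inside = np.all((pts >= o) & (pts <= o + size), axis=1)
        if inside.any():
            included.add(row.internode_id)
    return included
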
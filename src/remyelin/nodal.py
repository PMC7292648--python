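"""Node-of-Ranvier component analysis: proximity classification of nodal
(betaIV-spectrin) puncta against paranodal (Caspr) puncta.

A nodal punctum with >= 2 paranodal puncta within the pairing radius
(default 3.5 um) is a node, with exactly 1 a heminode, with none isolated.
Elongated axon-initial-segment structures are removed beforehand by a size
cutoff.  A 90-degree in-plane rotation of one channel about the field
center provides the chance-level control: genuine pairing collapses under
rotation, while proportions produced by density alone do not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "exclude_ais",
    "classify_puncta",
    "rotation_null",
    "NODE_CLASSES",
]

NODE_CLASSES = ("node", "heminode", "isolated")
_COORDS = ["x_um", "y_um", "z_um"]


def exclude_ais(puncta: pd.DataFrame, cutoff: float = 6.0,
                exclude_longer: bool = True):
    """Filter axon-initial-segment-like structures by size.

    AIS are elongated; by default structures with length > ``cutoff`` um
    are excluded and compact puncta retained (the direction is
    configurable).  Returns ``(retained, excluded_count)``.
    """
    lengths = puncta["length_um"].to_numpy(float)
    keep = lengths <= cutoff if exclude_longer else lengths > cutoff
    return puncta.loc[keep].reset_index(drop=True), int((~keep).sum())


def _count_partners(nodal: pd.DataFrame, paranodal: pd.DataFrame,
                    radius: float, exclusive: bool) -> np.ndarray:
    npts = nodal[_COORDS].to_numpy(float)
    if len(paranodal) == 0:
        return np.zeros(len(nodal), dtype=int)
    ppts = paranodal[_COORDS].to_numpy(float)
    tree = cKDTree(ppts)
    if not exclusive:
        return np.array([len(tree.query_ball_point(p, radius))
                         for p in npts], dtype=int)
    # sensitivity mode: each paranodal punctum serves at most one nodal
    # punctum, assigned greedily by distance
    pairs = []
    for i, p in enumerate(npts):
        for j in tree.query_ball_point(p, radius):
            pairs.append((float(np.linalg.norm(p - ppts[j])), i, j))
    pairs.sort()
    counts = np.zeros(len(nodal), dtype=int)
    used = set()
    for _, i, j in pairs:
        if j in used or counts[i] >= 2:
            continue
        used.add(j)
        counts[i] += 1
    return counts


def classify_puncta(nodal: pd.DataFrame, paranodal: pd.DataFrame,
                    radius: float = 3.5, exclusive: bool = False):
    """Classify each nodal punctum as node / heminode / isolated.

    Inputs are puncta tables with x_um, y_um, z_um columns (already AIS-
    filtered).  Returns ``(classified_df, counts)`` where ``counts`` maps
    class -> count and includes proportions; classes partition the nodal
    set.
    """
    out = nodal.copy()
    if len(nodal) == 0:
        out["n_partners"] = pd.Series(dtype=int)
        out["node_class"] = pd.Series(dtype=str)
        return out, {c: 0 for c in NODE_CLASSES} | {"n": 0}
    k = _count_partners(nodal, paranodal, radius, exclusive)
    cls = np.where(k >= 2, "node", np.where(k == 1, "heminode", "isolated"))
    out["n_partners"] = k
    out["node_class"] = cls
    n = len(out)
    counts = {c: int((cls == c).sum()) for c in NODE_CLASSES}
    counts["n"] = n
    counts["proportions"] = {c: counts[c] / n for c in NODE_CLASSES}
    return out, counts


def rotation_null(nodal: pd.DataFrame, paranodal: pd.DataFrame,
                  radius: float = 3.5, degrees: float = 90.0,
                  exclusive: bool = False):
    """Re-classify after rotating the paranodal channel in the x-y plane.

    The rotation is about the bounding-box center of the combined field
    (z unchanged); points may leave the field and simply stop pairing.
    Returns the same ``(classified_df, counts)`` structure as
    :func:`classify_puncta`.
    """
    allpts = pd.concat([nodal[_COORDS], paranodal[_COORDS]])
    cx = (allpts["x_um"].min() + allpts["x_um"].max()) / 2.0
    cy = (allpts["y_um"].min() + allpts["y_um"].max()) / 2.0
    th = np.deg2rad(degrees)
    rot = paranodal.copy()
    dx = paranodal["x_um"].to_numpy(float) - cx
    dy = paranodal["y_um"].to_numpy(float) - cy
    rot["x_um"] = cx + dx * np.cos(th) - dy * np.sin(th)
    rot["y_um"] = cy + dx * np.sin(th) + dy * np.cos(th)
    return classify_puncta(nodal, rot, radius=radius, exclusive=exclusive)
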
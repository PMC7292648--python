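"""Spatial displacement of regenerated cells relative to the baseline map.

Two complementary measures: the nearest-neighbor Euclidean distance from
each final-session cell to the closest baseline cell ("all cells"), and the
distance between a stable cell's own baseline and final positions
("self-self"), which calibrates the registration/movement wobble expected
in the absence of loss and regeneration.  Both assume positions already
drift-corrected into a common frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DisplacementResult",
    "nearest_neighbor_displacement",
    "self_self_displacement",
]


@dataclass
class DisplacementResult:
    category: str              # "all_cells" | "self_self"
    distances: np.ndarray      # per-cell d (um)
    bin_width: float = 5.0

    @property
    def mean(self) -> float:
        return float(self.distances.mean()) if self.distances.size else float("nan")

    @property
    def sem(self) -> float:
        n = self.distances.size
        return float(self.distances.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    def histogram(self):
        if self.distances.size == 0:
            return np.array([]), np.array([0.0])
        hi = np.ceil(self.distances.max() / self.bin_width) * self.bin_width
        edges = np.arange(0.0, max(hi, self.bin_width) + self.bin_width / 2,
                          self.bin_width)
        counts, edges = np.histogram(self.distances, bins=edges)
        return counts, edges

    def summary(self) -> dict:
        counts, edges = self.histogram()
        return {"category": self.category, "n": int(self.distances.size),
                "mean_um": self.mean, "sem_um": self.sem,
                "hist_counts": counts.tolist(),
                "hist_edges_um": edges.tolist()}


def nearest_neighbor_displacement(query_cells, reference_cells,
                                  bin_width: float = 5.0) -> DisplacementResult:
    """Distance from each query cell to its nearest reference cell.

    Ties (a query point equidistant from several references) yield that
    common distance.  Raises on an empty reference set.
    """
    q = np.asarray(query_cells, float).reshape(-1, 3)
    r = np.asarray(reference_cells, float).reshape(-1, 3)
    if r.shape[0] == 0:
        raise ValueError("reference set must be non-empty")
    if q.shape[0] == 0:
        return DisplacementResult("all_cells", np.array([]), bin_width)
    d, _ = cKDTree(r).query(q)
    return DisplacementResult("all_cells", np.asarray(d, float), bin_width)


def self_self_displacement(tracks, baseline_week, final_week,
                           bin_width: float = 5.0) -> DisplacementResult:
    """Distance between each stable cell's baseline and final positions."""
    ds = []
    for t in tracks:
        p0 = t.position_at(baseline_week)
        p1 = t.position_at(final_week)
        if p0 is not None and p1 is not None:
            ds.append(float(np.linalg.norm(np.asarray(p1) - np.asarray(p0))))
    return DisplacementResult("self_self", np.array(ds), bin_width)
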
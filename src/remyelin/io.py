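"""Readers/writers for the pipeline's table and trace formats.

All coordinates are micrometres, origin at one corner of the field at the
pial surface, z increasing with depth.  Cells, tracks, internodes and
puncta travel as strict-schema CSV; morphologies as SWC (type codes:
1 soma, 2 process, 7 sheath) with a JSON sidecar for attachment and
per-day metadata; territory grids as .npz arrays with a JSON header.
Validation errors name the offending column or row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import VolumeSpec
from .morphometry import OligMorphology, SheathTrace

__all__ = [
    "read_cells_csv", "write_cells_csv",
    "read_tracks_csv", "write_tracks_csv",
    "read_internodes_csv", "write_internodes_csv",
    "read_puncta_csv", "write_puncta_csv",
    "write_swc_morphology", "read_swc_morphology",
    "write_grid", "read_grid",
]

_SCHEMAS = {
    "cells": ["mouse_id", "cell_id", "week", "x_um", "y_um", "z_um"],
    "tracks": ["track_id", "week", "x_um", "y_um", "z_um", "fate"],
    "internodes": ["axon_id", "internode_id", "session", "s_start", "s_end",
                   "owner"],
    "puncta": ["marker", "punctum_id", "x_um", "y_um", "z_um", "length_um"],
}
_NUMERIC = {
    "cells": ["week", "x_um", "y_um", "z_um"],
    "tracks": ["week", "x_um", "y_um", "z_um"],
    "internodes": ["s_start", "s_end"],
    "puncta": ["x_um", "y_um", "z_um", "length_um"],
}


def _validate(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    for col in _SCHEMAS[kind]:
        if col not in df.columns:
            raise ValueError(f"{kind} table: missing column {col!r}")
    for col in _NUMERIC[kind]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{kind} table: non-numeric value in column {col!r} "
                f"at row {row}")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{kind} table: missing value in column {col!r} at row {row}")
        df[col] = vals
    return df


def _read_csv(path, kind: str) -> pd.DataFrame:
    return _validate(pd.read_csv(path), kind)


def _write_csv(df: pd.DataFrame, path, kind: str) -> None:
    _validate(df.copy(), kind).to_csv(path, index=False)


def read_cells_csv(path):
    return _read_csv(path, "cells")


def write_cells_csv(df, path):
    _write_csv(df, path, "cells")


def read_tracks_csv(path):
    return _read_csv(path, "tracks")


def write_tracks_csv(df, path):
    _write_csv(df, path, "tracks")


def read_internodes_csv(path):
    return _read_csv(path, "internodes")


def write_internodes_csv(df, path):
    _write_csv(df, path, "internodes")


def read_puncta_csv(path):
    return _read_csv(path, "puncta")


def write_puncta_csv(df, path):
    _write_csv(df, path, "puncta")


def tracks_to_frame(tracks) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for wk in sorted(t.positions):
            x, y, z = t.positions[wk]
            rows.append((t.track_id, wk, x, y, z, t.fate))
    return pd.DataFrame(rows, columns=_SCHEMAS["tracks"])


# ---------------------------------------------------------------------------
# SWC morphologies (one file per cell, type codes 1 soma / 2 process / 7
# sheath) plus a JSON sidecar for attachment and day-resolved metadata.

def write_swc_morphology(morph: OligMorphology, swc_path, json_path) -> None:
    lines = ["# id type x y z radius parent"]
    sx, sy, sz = morph.soma
    lines.append(f"1 1 {sx:.3f} {sy:.3f} {sz:.3f} 2.0 -1")
    next_id = 2
    meta_sheaths = []
    for proc, sh in zip(morph.processes, morph.sheaths):
        attach_id = None
        parent = 1
        for p in np.asarray(proc)[1:]:   # first process point is the soma
            lines.append(f"{next_id} 2 {p[0]:.3f} {p[1]:.3f} {p[2]:.3f} "
                         f"0.5 {parent}")
            parent = next_id
            next_id += 1
        attach_id = parent
        parent = attach_id
        first_sheath_id = next_id
        for p in sh.polyline:
            lines.append(f"{next_id} 7 {p[0]:.3f} {p[1]:.3f} {p[2]:.3f} "
                         f"0.8 {parent}")
            parent = next_id
            next_id += 1
        meta_sheaths.append(dict(
            sheath_id=sh.sheath_id,
            n_points=int(sh.polyline.shape[0]),
            first_node=first_sheath_id,
            attachment_arc=float(sh.attachment_arc),
            day_lengths={str(k): v for k, v in sh.day_lengths.items()},
        ))
    Path(swc_path).write_text("\n".join(lines) + "\n")
    meta = dict(cell_id=morph.cell_id, condition=morph.condition,
                day_from_appearance=morph.day_from_appearance,
                soma=[float(v) for v in morph.soma], sheaths=meta_sheaths)
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_swc_morphology(swc_path, json_path) -> OligMorphology:
    nodes = {}
    for ln in Path(swc_path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC row: {ln!r}")
        nid, ntype, x, y, z, radius, parent = parts
        nodes[int(nid)] = (int(ntype), np.array([float(x), float(y),
                                                 float(z)]), int(parent))
    for nid, (_t, _p, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise ValueError(f"SWC node {nid}: orphan (parent {parent} "
                             "missing)")
    meta = json.loads(Path(json_path).read_text())
    morph = OligMorphology(cell_id=meta["cell_id"],
                           soma=np.array(meta["soma"]),
                           day_from_appearance=meta["day_from_appearance"],
                           condition=meta.get("condition", ""))
    for sm in meta["sheaths"]:
        first, n = sm["first_node"], sm["n_points"]
        poly = np.array([nodes[first + k][1] for k in range(n)])
        day_lengths = {int(k): v for k, v in sm["day_lengths"].items()}
        morph.sheaths.append(SheathTrace(
            sheath_id=sm["sheath_id"], cell_id=meta["cell_id"],
            polyline=poly, attachment_arc=sm["attachment_arc"],
            day_lengths=day_lengths))
        # process polyline: soma plus chain down to the sheath anchor parent
        anchor_parent = nodes[first][2]
        chain = []
        nid = anchor_parent
        while nid != -1 and nodes[nid][0] == 2:
            chain.append(nodes[nid][1])
            nid = nodes[nid][2]
        chain.append(morph.soma)
        morph.processes.append(np.array(chain[::-1]))
    return morph


# ---------------------------------------------------------------------------
# Territory grids

def write_grid(base_path, grid: np.ndarray, volume: VolumeSpec,
               provenance: dict | None = None) -> None:
    base = Path(base_path)
    np.savez_compressed(base.with_suffix(".npz"), grid=grid)
    header = dict(dims=list(grid.shape),
                  xy_voxel=volume.xy_voxel, z_voxel=volume.z_voxel,
                  x_extent=volume.x_extent, y_extent=volume.y_extent,
                  z_extent=volume.z_extent,
                  provenance=provenance or {})
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))


def read_grid(base_path):
    base = Path(base_path)
    header = json.loads(base.with_suffix(".json").read_text())
    grid = np.load(base.with_suffix(".npz"))["grid"]
    if list(grid.shape) != header["dims"]:
        raise ValueError("grid dims do not match header")
    vol = VolumeSpec(x_extent=header["x_extent"], y_extent=header["y_extent"],
                     z_extent=header["z_extent"],
                     zone_edges=(0.0, header["z_extent"]),
                     xy_voxel=header["xy_voxel"], z_voxel=header["z_voxel"])
    return grid, vol, header.get("provenance", {})
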
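"""Point-cloud readers and writers.

Supported dialects:

``labeled-matrix`` / ``xyz``
    Whitespace- or comma-delimited text, one point per row:
    ``x y z [semantic [instance]]`` in meters.  Lines starting with ``#``
    are comments; the semantic column must be 0 or 1.  This is the n x 4
    (optionally n x 5) matrix format the pipeline uses between stages.
``ply``
    ASCII or binary PLY via :mod:`trimesh` (coordinates only).
``pcd``
    ASCII PCD with x/y/z fields (coordinates only).
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import trimesh

from .cloud import CloudError, LabeledCloud

__all__ = ["read_cloud", "write_cloud", "ParseError"]

_FORMATS = ("ply", "pcd", "xyz", "labeled-matrix")


class ParseError(CloudError):
    """A file could not be parsed; message names the offending line."""


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        return "ply"
    if ext == ".pcd":
        return "pcd"
    return "labeled-matrix"


def read_cloud(path: str, format: Optional[str] = None) -> LabeledCloud:
    """Read a point cloud; the 4th text column becomes the semantic label,
    a 5th becomes the instance id."""
    if format is None:
        format = _infer_format(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "ply":
        return _read_ply(path)
    if format == "pcd":
        return _read_pcd(path)
    return _read_matrix(path)


def write_cloud(cloud: LabeledCloud, path: str, format: Optional[str] = None) -> None:
    """Write a cloud; text formats keep semantic/instance columns,
    PLY/PCD store coordinates only."""
    if format is None:
        format = _infer_format(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "ply":
        trimesh.PointCloud(cloud.coords).export(path, file_type="ply")
        return
    if format == "pcd":
        _write_pcd(cloud, path)
        return
    _write_matrix(cloud, path)


# -- labeled-matrix text -------------------------------------------------

def _read_matrix(path: str) -> LabeledCloud:
    coords, semantic, instance = [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) < 3 or len(tokens) > 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 3-5 columns, got {len(tokens)}"
                )
            if ncols is None:
                ncols = len(tokens)
            elif len(tokens) != ncols:
                raise ParseError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(tokens)} vs {ncols})"
                )
            try:
                xyz = [float(t) for t in tokens[:3]]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
            coords.append(xyz)
            if ncols >= 4:
                try:
                    lab = int(float(tokens[3]))
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric label") from None
                if lab not in (0, 1):
                    raise ParseError(
                        f"{path}:{lineno}: semantic label must be 0 or 1, got {lab}"
                    )
                semantic.append(lab)
            if ncols == 5:
                try:
                    instance.append(int(float(tokens[4])))
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric instance id") from None
    if not coords:
        raise ParseError(f"{path}: empty file")
    return LabeledCloud(
        coords=np.array(coords, dtype=np.float64),
        semantic=np.array(semantic, dtype=np.int64) if semantic else None,
        instance=np.array(instance, dtype=np.int64) if instance else None,
    )


def _write_matrix(cloud: LabeledCloud, path: str) -> None:
    cols = [cloud.coords]
    header = "x y z"
    if cloud.semantic is not None:
        cols.append(cloud.semantic[:, None].astype(np.float64))
        header += " semantic"
        if cloud.instance is not None:
            cols.append(cloud.instance[:, None].astype(np.float64))
            header += " instance"
    mat = np.hstack(cols)
    fmts = ["%.9f"] * 3 + ["%d"] * (mat.shape[1] - 3)
    np.savetxt(path, mat, fmt=fmts, header=header)


# -- PLY (via trimesh) ---------------------------------------------------

def _read_ply(path: str) -> LabeledCloud:
    obj = trimesh.load(path, process=False)
    verts = np.asarray(obj.vertices if hasattr(obj, "vertices") else obj)
    if verts.size == 0:
        raise ParseError(f"{path}: PLY file contains no vertices")
    return LabeledCloud(coords=verts.astype(np.float64))


# -- PCD (ASCII, minimal) ------------------------------------------------

def _read_pcd(path: str) -> LabeledCloud:
    fields = None
    data_mode = None
    rows = []
    with open(path) as fh:
        in_header = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if in_header:
                key = line.split()[0].upper()
                if key == "FIELDS":
                    fields = line.split()[1:]
                elif key == "DATA":
                    data_mode = line.split()[1].lower()
                    if data_mode != "ascii":
                        raise ParseError(
                            f"{path}:{lineno}: only ascii PCD data supported"
                        )
                    in_header = False
                continue
            tokens = line.split()
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from None
    if fields is None or data_mode is None or not rows:
        raise ParseError(f"{path}: not a valid ASCII PCD file")
    try:
        ix, iy, iz = fields.index("x"), fields.index("y"), fields.index("z")
    except ValueError:
        raise ParseError(f"{path}: PCD header lacks x/y/z fields") from None
    arr = np.array(rows, dtype=np.float64)
    return LabeledCloud(coords=arr[:, [ix, iy, iz]])


def _write_pcd(cloud: LabeledCloud, path: str) -> None:
    n = cloud.n
    with open(path, "w") as fh:
        fh.write(
            "# .PCD v0.7 - Point Cloud Data file format\n"
            "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\n"
            f"COUNT 1 1 1\nWIDTH {n}\nHEIGHT 1\n"
            f"VIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
        )
        np.savetxt(fh, cloud.coords, fmt="%.9f")
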
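"""Writers for meshes, per-face scalar fields, tables and run reports.

Meshes go through trimesh's exporters (PLY binary little-endian, OFF, STL,
and ASCII PLY). Per-face scalar fields are written as CSV
(face_index, value, ...) and, when a PLY is requested, as an ASCII PLY
with one extra float property per field — a small writer of our own,
since arbitrary per-face properties are outside trimesh's export surface.

All floating-point output is printed with 9 significant digits so repeated
runs of the deterministic pipeline are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "write_mesh",
    "write_ply_with_face_scalars",
    "write_face_scalar_csv",
    "write_json",
    "read_config",
    "FLOAT_FMT",
]

FLOAT_FMT = "%.9g"


def write_mesh(mesh: trimesh.Trimesh, path: str | Path, ascii_ply: bool = False) -> Path:
    """Export a mesh; format chosen by extension (.ply, .off, .stl)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        data = trimesh.exchange.ply.export_ply(
            mesh, encoding="ascii" if ascii_ply else "binary_little_endian")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    elif suffix in (".off", ".stl"):
        mesh.export(path)
    else:
        raise ValueError(f"unsupported mesh format {suffix!r}")
    return path


def write_ply_with_face_scalars(mesh: trimesh.Trimesh, path: str | Path,
                                scalars: Mapping[str, np.ndarray]) -> Path:
    """ASCII PLY with extra per-face float properties (for external renderers)."""
    path = Path(path)
    nv, nf = len(mesh.vertices), len(mesh.faces)
    for name, vals in scalars.items():
        if len(vals) != nf:
            raise ValueError(f"scalar {name!r} has {len(vals)} values for {nf} faces")
    lines = [
        "ply", "format ascii 1.0", "comment rbcmesh per-face scalar export",
        f"element vertex {nv}",
        "property float x", "property float y", "property float z",
        f"element face {nf}",
        "property list uchar int vertex_indices",
    ]
    lines += [f"property float {name}" for name in scalars]
    lines.append("end_header")
    for v in mesh.vertices:
        lines.append(" ".join(FLOAT_FMT % c for c in v))
    cols = list(scalars.values())
    for i, f in enumerate(mesh.faces):
        row = "3 " + " ".join(str(int(j)) for j in f)
        if cols:
            row += " " + " ".join(FLOAT_FMT % col[i] for col in cols)
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_face_scalar_csv(path: str | Path, columns: Mapping[str, np.ndarray]) -> Path:
    """CSV with face_index plus one column per scalar field."""
    frame = pd.DataFrame({"face_index": np.arange(len(next(iter(columns.values()))))})
    for name, vals in columns.items():
        frame[name] = vals
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)
    return Path(path)


def _round_floats(obj):
    if isinstance(obj, float):
        return float(FLOAT_FMT % obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(FLOAT_FMT % float(obj))
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_json(path: str | Path, payload: dict) -> Path:
    """Deterministic JSON: floats at 9 significant digits, sorted keys."""
    path = Path(path)
    path.write_text(json.dumps(_round_floats(payload), indent=2, sort_keys=True) + "\n")
    return path


def read_config(path: str | Path) -> Dict[str, str]:
    """Flat key=value configuration file; '#' starts a comment."""
    out: Dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out
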
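"""Minimal legacy-ASCII VTK polydata reader/writer.

Only the subset needed here: POINTS, triangle POLYGONS, and POINT_DATA with
SCALARS / VECTORS arrays.  Text-based on purpose so pipeline outputs stay
diffable and portable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_polydata(
    path,
    points: np.ndarray,
    faces: np.ndarray | None = None,
    point_scalars: dict[str, np.ndarray] | None = None,
    point_vectors: dict[str, np.ndarray] | None = None,
) -> None:
    points = np.asarray(points, dtype=float)
    lines = [
        "# vtk DataFile Version 3.0",
        "shearhist polydata",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
    ]
    for p in points:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    if faces is not None and len(faces):
        faces = np.asarray(faces, dtype=int)
        lines.append(f"POLYGONS {len(faces)} {len(faces) * 4}")
        for f in faces:
            lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    if point_scalars or point_vectors:
        lines.append(f"POINT_DATA {len(points)}")
        for name, arr in (point_scalars or {}).items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in arr)
        for name, arr in (point_vectors or {}).items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"VECTORS {name} float")
            lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def read_polydata(path):
    """Return (points, faces, point_data) where point_data maps array name to
    an (n,) or (n, 3) float array."""
    tokens = Path(path).read_text().split()
    i = 0

    def take(n):
        nonlocal i
        out = tokens[i : i + n]
        i += n
        return out

    points = None
    faces = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok == "POINTS":
            n_points = int(tokens[i + 1])
            i += 3
            vals = np.array(take(3 * n_points), dtype=float)
            points = vals.reshape(n_points, 3)
        elif tok == "POLYGONS":
            n_faces = int(tokens[i + 1])
            i += 3
            out = []
            for _ in range(n_faces):
                k = int(tokens[i])
                out.append([int(v) for v in tokens[i + 1 : i + 1 + k]])
                i += 1 + k
            faces = np.array(out, dtype=int)
        elif tok == "POINT_DATA":
            i += 2
        elif tok == "SCALARS":
            name = tokens[i + 1]
            i += 4  # SCALARS name type ncomp
            if tokens[i] == "LOOKUP_TABLE":
                i += 2
            point_data[name] = np.array(take(n_points), dtype=float)
        elif tok == "VECTORS":
            name = tokens[i + 1]
            i += 3
            point_data[name] = np.array(take(3 * n_points), dtype=float).reshape(
                n_points, 3
            )
        else:
            i += 1
    if points is None:
        raise ValueError(f"no POINTS section found in {path}")
    return points, faces, point_data
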
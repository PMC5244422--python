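"""Minimal legacy-ASCII VTK writers (structured points and polydata).

Only the subset needed to hand stages, field snapshots, streamlines and
isobar contours to ParaView is implemented; files are plain text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_structured_points(
    path: str | Path,
    spacing_mm: tuple[float, float, float],
    cell_arrays: dict[str, np.ndarray] | None = None,
    vector_arrays: dict[str, np.ndarray] | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    title: str = "ivs_hemoflow structured grid",
) -> None:
    """Write per-cell scalar/vector arrays of shape (nx, ny, nz[, 3]) as
    STRUCTURED_POINTS cell data (dimensions are point counts = cells + 1)."""
    cell_arrays = cell_arrays or {}
    vector_arrays = vector_arrays or {}
    arrs = list(cell_arrays.values()) + list(vector_arrays.values())
    if not arrs:
        raise ValueError("nothing to write")
    shape = arrs[0].shape[:3]
    nx, ny, nz = shape
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing_mm[0]} {spacing_mm[1]} {spacing_mm[2]}\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in cell_arrays.items():
            if arr.shape[:3] != shape:
                raise ValueError(f"array {name} shape mismatch")
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            flat = arr.transpose(2, 1, 0).ravel()  # VTK is x-fastest
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%d" if kind == "int" else "%.9g")
        for name, arr in vector_arrays.items():
            if arr.shape != shape + (3,):
                raise ValueError(f"vector array {name} shape mismatch")
            fh.write(f"VECTORS {name} float\n")
            flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.9g")


def write_polydata(
    path: str | Path,
    points: np.ndarray,
    lines: list[list[int]] | None = None,
    polygons: list[list[int]] | None = None,
    point_scalars: dict[str, np.ndarray] | None = None,
    title: str = "ivs_hemoflow polydata",
) -> None:
    lines = lines or []
    polygons = polygons or []
    points = np.asarray(points, float).reshape(-1, 3)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        np.savetxt(fh, points, fmt="%.9g")
        if lines:
            total = sum(len(l) + 1 for l in lines)
            fh.write(f"LINES {len(lines)} {total}\n")
            for l in lines:
                fh.write(" ".join(str(x) for x in [len(l), *l]) + "\n")
        if polygons:
            total = sum(len(pg) + 1 for pg in polygons)
            fh.write(f"POLYGONS {len(polygons)} {total}\n")
            for pg in polygons:
                fh.write(" ".join(str(x) for x in [len(pg), *pg]) + "\n")
        if point_scalars:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_scalars.items():
                if len(arr) != len(points):
                    raise ValueError(f"scalar {name} length mismatch")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr, float).reshape(-1, 1), fmt="%.9g")


def write_streamlines(path: str | Path, streamline_set) -> None:
    """StreamlineSet polylines with a per-point class code (0 top, 1 recirc, 2 stalled)."""
    code = {"reached_top": 0.0, "recirculated": 1.0, "stalled": 2.0}
    pts = []
    lines = []
    scal = []
    base = 0
    for p, cls in zip(streamline_set.paths, streamline_set.classes):
        pts.append(p)
        lines.append(list(range(base, base + len(p))))
        scal += [code[cls]] * len(p)
        base += len(p)
    write_polydata(path, np.concatenate(pts), lines=lines,
                   point_scalars={"class": np.array(scal)})
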
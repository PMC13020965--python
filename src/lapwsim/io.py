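"""File I/O for the geometry and electrogram containers.

Formats kept deliberately plain: XYZ delimited text for point clouds, STL for
surfaces (via trimesh), legacy ASCII VTK unstructured grids for tetrahedral
meshes (element/point data carried as named fields), and CSV + JSON sidecar
for electrogram sets.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_stl",
    "write_stl",
    "write_vtk_unstructured",
    "read_vtk_unstructured",
    "write_egm_csv",
    "read_egm_csv",
]


def read_xyz(path):
    """Read an N×3 point cloud from whitespace- or comma-delimited text."""
    pts = np.loadtxt(path, delimiter=None if _sniff_ws(path) else ",")
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 columns, got {pts.shape[1]}")
    return pts[:, :3]


def _sniff_ws(path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True


def write_xyz(path, points) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.9g")


def read_stl(path):
    """Return (vertices, faces) from a binary or ASCII STL file."""
    import trimesh

    m = trimesh.load_mesh(str(path), file_type="stl", process=False)
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)


def write_stl(path, vertices, faces) -> None:
    import trimesh

    trimesh.Trimesh(vertices=vertices, faces=faces, process=False).export(
        str(path), file_type="stl_ascii"
    )


def write_vtk_unstructured(path, vertices, tets, cell_data=None, point_data=None):
    """Write a tetrahedral mesh as a legacy ASCII VTK unstructured grid.

    ``cell_data``/``point_data`` map field names to per-cell/per-point arrays;
    scalar fields and 3-vector fields are supported.
    """
    vertices = np.asarray(vertices, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "lapwsim unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(vertices)} double",
    ]
    lines += [" ".join(f"{x:.12g}" for x in p) for p in vertices]
    lines.append(f"CELLS {len(tets)} {5 * len(tets)}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)
    for header, data in (("CELL_DATA", cell_data), ("POINT_DATA", point_data)):
        if not data:
            continue
        n = len(tets) if header == "CELL_DATA" else len(vertices)
        lines.append(f"{header} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.12g}" for v in arr.astype(float)]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.12g}" for x in row) for row in arr.astype(float)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_unstructured(path):
    """Read a legacy ASCII VTK unstructured tet grid written by this package.

    Returns (vertices, tets, cell_data, point_data).
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    vertices = tets = None
    cell_data: dict = {}
    point_data: dict = {}
    current = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vertices = np.array(
                [[float(x) for x in tokens[i + 1 + k].split()] for k in range(n)]
            )
            i += n
        elif line.startswith("CELLS"):
            n = int(line.split()[1])
            tets = np.array(
                [[int(x) for x in tokens[i + 1 + k].split()[1:]] for k in range(n)],
                dtype=np.int64,
            )
            i += n
        elif line.startswith("CELL_DATA"):
            current = cell_data
        elif line.startswith("POINT_DATA"):
            current = point_data
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            n = len(tets) if current is cell_data else len(vertices)
            vals = np.array([float(tokens[i + 2 + k]) for k in range(n)])
            current[name] = vals
            i += n + 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            n = len(tets) if current is cell_data else len(vertices)
            vals = np.array(
                [[float(x) for x in tokens[i + 1 + k].split()] for k in range(n)]
            )
            current[name] = vals
            i += n
        i += 1
    return vertices, tets, cell_data, point_data


def write_egm_csv(csv_path, time_ms, traces, electrode_positions, sidecar=None):
    """Write an electrogram set: CSV (time + one column per electrode) plus a
    JSON sidecar holding electrode coordinates and any extra metadata."""
    time_ms = np.asarray(time_ms, dtype=float)
    traces = np.asarray(traces, dtype=float)  # (n_samples, n_electrodes)
    header = "time_ms," + ",".join(f"e{k}" for k in range(traces.shape[1]))
    np.savetxt(
        csv_path,
        np.column_stack([time_ms, traces]),
        delimiter=",",
        header=header,
        comments="",
        fmt="%.9g",
    )
    meta = dict(sidecar or {})
    meta["electrode_positions_mm"] = np.asarray(electrode_positions, float).tolist()
    Path(str(csv_path) + ".json").write_text(json.dumps(meta, indent=1))


def read_egm_csv(csv_path):
    """Read an electrogram set written by :func:`write_egm_csv`.

    Returns (time_ms, traces, electrode_positions, sidecar_dict).
    """
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    time_ms, traces = data[:, 0], data[:, 1:]
    sidecar_path = Path(str(csv_path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    electrodes = np.asarray(meta.get("electrode_positions_mm", []), dtype=float)
    return time_ms, traces, electrodes, meta
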
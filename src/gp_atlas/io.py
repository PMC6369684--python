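"""Reading and writing surface meshes and tabular records.

Supported mesh formats: ASCII PLY, Wavefront OBJ, legacy ASCII VTK polydata,
and the canonical CSV dialect (vertices.csv + faces.csv) that stands in for
electroanatomic-system exports.  Region labels travel in a sidecar CSV
(vertex_id, label) for formats without attributes; the CSV dialect carries
them inline.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from gp_atlas.errors import MeshValidationError
from gp_atlas.surface import AtrialSurface

__all__ = ["load_surface", "save_surface", "read_labels_csv", "write_labels_csv"]

_FORMATS = ("ply", "obj", "vtk", "csv")


def _infer_format(path: pathlib.Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if path.is_dir() or suffix == "":
        return "csv"
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer mesh format from '{path}'")


def load_surface(
    path,
    fmt: str | None = None,
    labels_path=None,
    surface_id: str | None = None,
    validate: bool = True,
) -> AtrialSurface:
    """Load a labeled atrial surface.

    ``path`` is a mesh file (.ply/.obj/.vtk) or a directory containing
    ``vertices.csv`` and ``faces.csv``.  For non-CSV formats, labels come
    from ``labels_path`` (CSV with columns vertex_id, label); vertices
    default to BODY when no sidecar is given.
    """
    path = pathlib.Path(path)
    fmt = (fmt or _infer_format(path)).lower()
    if fmt == "csv":
        vertices, faces, labels = _read_csv_dialect(path)
    elif fmt == "ply":
        vertices, faces = _read_ply(path)
        labels = None
    elif fmt == "obj":
        vertices, faces = _read_obj(path)
        labels = None
    elif fmt == "vtk":
        vertices, faces = _read_vtk(path)
        labels = None
    else:
        raise ValueError(f"unsupported mesh format '{fmt}'")

    if labels is None:
        if labels_path is not None:
            labels = read_labels_csv(labels_path, n_vertices=len(vertices))
        else:
            labels = np.full(len(vertices), "BODY", dtype="U8")

    surf = AtrialSurface(
        vertices=vertices,
        faces=faces,
        labels=labels,
        surface_id=surface_id or path.stem,
    )
    return surf.validate() if validate else surf


def save_surface(surface: AtrialSurface, path, fmt: str | None = None, labels_path=None):
    """Write a surface; labels go inline (CSV dialect) or to a sidecar CSV."""
    path = pathlib.Path(path)
    fmt = (fmt or _infer_format(path)).lower()
    if fmt == "csv":
        _write_csv_dialect(surface, path)
        return
    if fmt == "ply":
        _write_ply(surface, path)
    elif fmt == "obj":
        _write_obj(surface, path)
    elif fmt == "vtk":
        _write_vtk(surface, path)
    else:
        raise ValueError(f"unsupported mesh format '{fmt}'")
    if labels_path is not None:
        write_labels_csv(surface.labels, labels_path)


# -- sidecar labels ---------------------------------------------------------


def read_labels_csv(path, n_vertices: int) -> np.ndarray:
    df = pd.read_csv(path)
    labels = np.full(n_vertices, "BODY", dtype="U8")
    labels[df["vertex_id"].to_numpy(int)] = df["label"].to_numpy(str)
    return labels


def write_labels_csv(labels: np.ndarray, path) -> None:
    pd.DataFrame({"vertex_id": np.arange(len(labels)), "label": labels}).to_csv(
        path, index=False
    )


# -- CSV dialect ------------------------------------------------------------


def _read_csv_dialect(path: pathlib.Path):
    vdf = pd.read_csv(path / "vertices.csv")
    fdf = pd.read_csv(path / "faces.csv")
    order = np.argsort(vdf["vertex_id"].to_numpy())
    vdf = vdf.iloc[order]
    vertices = vdf[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    labels = vdf["label"].to_numpy(str)
    faces = fdf[["v0", "v1", "v2"]].to_numpy(int)
    return vertices, faces, labels


def _write_csv_dialect(surface: AtrialSurface, path: pathlib.Path):
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "vertex_id": np.arange(len(surface.vertices)),
            "x_mm": surface.vertices[:, 0],
            "y_mm": surface.vertices[:, 1],
            "z_mm": surface.vertices[:, 2],
            "label": surface.labels,
        }
    ).to_csv(path / "vertices.csv", index=False)
    pd.DataFrame(surface.faces, columns=["v0", "v1", "v2"]).to_csv(
        path / "faces.csv", index=False
    )


# -- PLY (ascii) ------------------------------------------------------------


def _read_ply(path: pathlib.Path):
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise MeshValidationError(f"{path}: not a PLY file")
        n_vert = n_face = 0
        fmt_line = ""
        for line in fh:
            line = line.strip()
            if line.startswith("format"):
                fmt_line = line
            elif line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        if "ascii" not in fmt_line:
            raise MeshValidationError(
                f"{path}: only ascii PLY is supported; convert binary exports first"
            )
        vertices = np.array(
            [[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)]
        )
        faces = []
        for _ in range(n_face):
            row = fh.readline().split()
            if int(row[0]) != 3:
                raise MeshValidationError(f"{path}: non-triangular face encountered")
            faces.append([int(row[1]), int(row[2]), int(row[3])])
    return vertices, np.array(faces, dtype=int)


def _write_ply(surface: AtrialSurface, path: pathlib.Path):
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(surface.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(surface.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in surface.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in surface.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# -- OBJ --------------------------------------------------------------------


def _read_obj(path: pathlib.Path):
    vertices, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise MeshValidationError(f"{path}: non-triangular face encountered")
                faces.append(idx)
    return np.array(vertices, float), np.array(faces, int)


def _write_obj(surface: AtrialSurface, path: pathlib.Path):
    with open(path, "w") as fh:
        for v in surface.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in surface.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# -- legacy VTK polydata (ascii) -------------------------------------------


def _read_vtk(path: pathlib.Path):
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    vertices = faces = None
    while i < len(lines):
        line = lines[i].strip()
        if line.upper().startswith("POINTS"):
            n = int(line.split()[1])
            vals: list[float] = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            vertices = np.array(vals).reshape(n, 3)
            continue
        if line.upper().startswith("POLYGONS"):
            m = int(line.split()[1])
            ints: list[int] = []
            i += 1
            while i < len(lines) and len(ints) < 4 * m:
                ints.extend(int(x) for x in lines[i].split())
                i += 1
            arr = np.array(ints).reshape(m, -1)
            if not np.all(arr[:, 0] == 3):
                raise MeshValidationError(f"{path}: non-triangular polygon encountered")
            faces = arr[:, 1:4]
            continue
        i += 1
    if vertices is None or faces is None:
        raise MeshValidationError(f"{path}: POINTS/POLYGONS sections not found")
    return vertices, faces


def _write_vtk(surface: AtrialSurface, path: pathlib.Path, scalars: dict | None = None):
    """Write legacy ascii VTK polydata; optional named per-vertex scalars."""
    v, f = surface.vertices, surface.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngp_atlas surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if scalars:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, arr in scalars.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for x in np.asarray(arr, float):
                    fh.write(f"{x:.9g}\n")


def write_vtk_with_scalars(surface: AtrialSurface, path, scalars: dict) -> None:
    """Public helper for atlas export: VTK polydata with named vertex scalars."""
    _write_vtk(surface, pathlib.Path(path), scalars=scalars)
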
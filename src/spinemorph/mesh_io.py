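"""Reading, writing and validating dendritic-spine surface meshes.

Meshes are carried as :class:`trimesh.Trimesh` objects throughout the
package; coordinates are micrometers. Insertion points (the 3D location
where a spine emerges from its dendritic shaft) and per-spine metadata
live in sidecar CSV tables because no standard mesh format carries them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "InsertionPoint",
    "SpineRecord",
    "ValidationReport",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "read_insertion_points",
    "write_insertion_points",
    "read_metadata",
]

_FORMATS = ("ply", "obj", "off", "stl")


class MeshFormatError(ValueError):
    """Raised when a mesh file violates the triangle-mesh contract."""


@dataclass(frozen=True)
class InsertionPoint:
    """Marked attachment point of a spine on its dendritic shaft (μm)."""

    spine_id: str
    position: np.ndarray  # shape (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError("insertion position must be a 3-vector")


@dataclass
class SpineRecord:
    """One spine: its surface mesh, insertion point and optional metadata."""

    spine_id: str
    mesh: trimesh.Trimesh
    insertion: InsertionPoint
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ValidationReport:
    n_components: int
    watertight: bool
    n_nonmanifold_edges: int
    bbox: np.ndarray  # (2, 3) min/max corners, μm


def _check_triangular_obj(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("f "):
            if len(line.split()) - 1 > 3:
                raise MeshFormatError(
                    f"{path}: non-triangular face at line {lineno} "
                    f"({len(line.split()) - 1} vertices)"
                )


def _check_triangular_off(path: Path) -> None:
    tokens: list[str] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line and line.upper() != "OFF":
            tokens.extend(line.split())
    if len(tokens) < 3:
        raise MeshFormatError(f"{path}: truncated OFF header")
    n_v, n_f = int(tokens[0]), int(tokens[1])
    idx = 3 + 3 * n_v
    for face_i in range(n_f):
        if idx >= len(tokens):
            raise MeshFormatError(f"{path}: truncated OFF face list")
        degree = int(tokens[idx])
        if degree != 3:
            raise MeshFormatError(
                f"{path}: non-triangular face at index {face_i} ({degree} vertices)"
            )
        idx += 1 + degree


def read_mesh(path: str | Path, fmt: str = "auto", weld: bool = False,
              weld_tol: float = 1e-6) -> trimesh.Trimesh:
    """Load a triangle mesh, preserving vertex order and without welding.

    Parameters
    ----------
    path : file in PLY (ascii or binary little-endian), OBJ, OFF or STL format.
    fmt : one of ``{"ply", "obj", "off", "stl", "auto"}``; ``auto`` uses the
        file suffix.
    weld : merge vertices closer than ``weld_tol`` μm. Off by default — spine
        meshes come pre-welded from marching cubes.

    Raises
    ------
    MeshFormatError
        If a face is not a triangle (the offending face is named).
    IOError
        If the file does not exist or cannot be parsed.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} for {path}")
    # OBJ/OFF are plain text: verify the triangle contract before trimesh
    # silently triangulates polygons.
    if fmt == "obj":
        _check_triangular_obj(path)
    elif fmt == "off":
        _check_triangular_off(path)
    try:
        loaded = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except MeshFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as I/O failure
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise IOError(f"{path} contains no triangle mesh")
    mesh = trimesh.Trimesh(
        vertices=np.asarray(loaded.vertices, dtype=float),
        faces=np.asarray(loaded.faces, dtype=np.int64),
        process=False,
    )
    if mesh.faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: faces are not triangles")
    if weld:
        mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=int(-np.log10(weld_tol)))
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path, fmt: str = "auto") -> None:
    """Write a mesh; format from suffix unless given explicitly."""
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    kwargs = {"encoding": "ascii"} if fmt == "ply" else {}
    data = trimesh.exchange.export.export_mesh(mesh, None, file_type=fmt, **kwargs)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def _edge_face_counts(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """Unique undirected edges and the number of faces incident to each."""
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq, counts


def validate_mesh(mesh: trimesh.Trimesh) -> ValidationReport:
    """Report connectivity and manifoldness of a spine mesh.

    ``n_components`` counts edge-connected face components; ``watertight``
    is true iff every edge borders exactly two faces (a disjoint union of
    closed surfaces is watertight). Degenerate meshes raise ``ValueError``.
    """
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise ValueError("cannot validate an empty mesh")
    faces = np.asarray(mesh.faces)
    if np.any(faces < 0) or np.any(faces >= len(mesh.vertices)):
        raise ValueError("face references out-of-range vertex")
    if np.any(faces[:, 0] == faces[:, 1]) or np.any(faces[:, 1] == faces[:, 2]) \
            or np.any(faces[:, 0] == faces[:, 2]):
        raise ValueError("degenerate face with repeated vertices")
    adjacency = mesh.face_adjacency
    n_components = len(
        trimesh.graph.connected_components(adjacency, nodes=np.arange(len(faces)))
    )
    _, counts = _edge_face_counts(mesh)
    n_bad = int(np.sum(counts != 2))
    bbox = np.vstack([mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)])
    return ValidationReport(
        n_components=n_components,
        watertight=bool(n_bad == 0),
        n_nonmanifold_edges=n_bad,
        bbox=bbox,
    )


def read_insertion_points(path: str | Path) -> dict[str, InsertionPoint]:
    """Read the sidecar CSV (header ``spine_id,x,y,z``)."""
    df = pd.read_csv(path)
    required = {"spine_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"insertion CSV must have columns {sorted(required)}")
    return {
        str(row.spine_id): InsertionPoint(str(row.spine_id),
                                          np.array([row.x, row.y, row.z], dtype=float))
        for row in df.itertuples()
    }


def write_insertion_points(points: dict[str, InsertionPoint] | list[InsertionPoint],
                           path: str | Path) -> None:
    if isinstance(points, dict):
        points = list(points.values())
    rows = [{"spine_id": p.spine_id, "x": p.position[0], "y": p.position[1],
             "z": p.position[2]} for p in points]
    pd.DataFrame(rows, columns=["spine_id", "x", "y", "z"]).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-spine metadata (``spine_id,compartment,age,distance_um``)."""
    df = pd.read_csv(path)
    if "spine_id" not in df.columns:
        raise ValueError("metadata CSV must have a spine_id column")
    df["spine_id"] = df["spine_id"].astype(str)
    return df.set_index("spine_id")


def insertion_is_attached(mesh: trimesh.Trimesh, insertion: InsertionPoint,
                          tol: float = 0.05) -> bool:
    """Whether the insertion point lies within ``tol`` μm of the surface
    (nearest-vertex distance; adequate at spine mesh resolutions)."""
    d = np.min(np.linalg.norm(mesh.vertices - insertion.position, axis=1))
    return bool(d <= tol)
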
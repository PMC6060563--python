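"""Repair of fragmented and detached spine meshes.

Confocal reconstructions of dendritic spines commonly come out broken in
two ways: *fragmentation* (the surface splits into several closed
pieces, typically across the thin neck) and *detachment* (the mesh ends
above the marked insertion point on the dendritic shaft). Both repairs
work in a voxel domain:

* fragmentation — voxelize, apply a morphological closing with a
  spherical structuring element (joining pieces within the element's
  reach), and re-extract the surface by marching cubes;
* detachment — rotate the spine so the gap runs along −z, then grow the
  missing neck slice by slice: each empty slice between the spine base
  and the insertion point is a Gaussian-blurred, thresholded copy of the
  slice above it.

A curvature-flow smoother removes voxel staircase artefacts, and a
quality gate discards spines whose repair changed them too much.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .mesh_io import InsertionPoint, validate_mesh

__all__ = [
    "RepairParams",
    "RepairFailure",
    "NoOpWarning",
    "VoxelGrid",
    "voxelize",
    "mesh_from_voxels",
    "repair_fragmentation",
    "reconstruct_neck",
    "smooth_curvature_flow",
    "quality_gate",
    "repair_spine",
]


class RepairFailure(RuntimeError):
    """Repair could not produce a single connected spine."""

    def __init__(self, message: str, n_components: int | None = None):
        super().__init__(message)
        self.n_components = n_components


class NoOpWarning(UserWarning):
    """The requested repair was unnecessary."""


@dataclass(frozen=True)
class RepairParams:
    """Voxel-domain repair settings.

    voxel_spacing : isotropic voxel edge (μm); default matches the
        0.075 μm in-plane sampling of the source microscopy.
    closing_radius : spherical structuring element radius in voxels; the
        closing can bridge gaps up to twice this reach
        (2 × radius × spacing μm).
    gaussian_sigma / fill_threshold : the slice-growing filter for neck
        reconstruction.
    smoothing_iterations / smoothing_step : curvature-flow smoothing.
    """

    voxel_spacing: float = 0.075
    closing_radius: int = 18
    gaussian_sigma: float = 1.0
    fill_threshold: float = 0.35
    smoothing_iterations: int = 10
    smoothing_step: float = 0.1

    def __post_init__(self) -> None:
        if self.voxel_spacing <= 0 or self.closing_radius <= 0 \
                or self.gaussian_sigma <= 0 or self.smoothing_step <= 0:
            raise ValueError("repair parameters must be positive")
        if not 0 < self.fill_threshold < 1:
            raise ValueError("fill_threshold must lie in (0, 1)")


@dataclass
class VoxelGrid:
    """Binary occupancy grid in world micrometers."""

    origin: np.ndarray       # (3,) world position of voxel (0,0,0) centre
    spacing: float
    occupancy: np.ndarray    # 3D bool

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.occupancy.size == 0:
            raise ValueError("occupancy grid is empty")


def voxelize(mesh: trimesh.Trimesh, spacing: float, pad: int = 2) -> VoxelGrid:
    """Solid voxelization of a watertight mesh (center-inside sampling).

    A voxel is occupied iff its centre lies inside the surface, decided
    by z-ray crossing parity per grid column. Centre sampling is
    unbiased: together with the marching-cubes 0.5 iso-level it neither
    dilates nor erodes thin structures systematically (surface-touching
    voxelizations fatten a thin spine neck by half a voxel on every
    side, which distorts volumes badly).
    """
    lo, hi = mesh.bounds
    # jitter the grid so columns never pass exactly through vertices/edges
    jitter = spacing * 0.282842712474619
    origin = lo - pad * spacing - jitter
    dims = np.ceil((hi - origin) / spacing).astype(int) + pad + 1
    occ = np.zeros(dims, dtype=bool)

    tri = mesh.triangles  # (n, 3, 3)
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        i_min = max(int(np.ceil((min(x0, x1, x2) - origin[0]) / spacing)), 0)
        i_max = min(int(np.floor((max(x0, x1, x2) - origin[0]) / spacing)),
                    dims[0] - 1)
        j_min = max(int(np.ceil((min(y0, y1, y2) - origin[1]) / spacing)), 0)
        j_max = min(int(np.floor((max(y0, y1, y2) - origin[1]) / spacing)),
                    dims[1] - 1)
        if i_min > i_max or j_min > j_max:
            continue
        xs = origin[0] + np.arange(i_min, i_max + 1) * spacing
        ys = origin[1] + np.arange(j_min, j_max + 1) * spacing
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        # barycentric column-in-triangle test in the xy projection
        d = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(d) < 1e-14:
            continue  # triangle vertical in z: never crossed transversally
        a = ((y1 - y2) * (X - x2) + (x2 - x1) * (Y - y2)) / d
        b = ((y2 - y0) * (X - x2) + (x0 - x2) * (Y - y2)) / d
        c = 1.0 - a - b
        hit = (a >= 0) & (b >= 0) & (c >= 0)
        if not hit.any():
            continue
        Z = a * z0 + b * z1 + c * z2
        # toggle parity above each crossing: voxels with center z > Z flip
        ii, jj = np.nonzero(hit)
        kk = np.ceil((Z[ii, jj] - origin[2]) / spacing).astype(int)
        kk = np.clip(kk, 0, dims[2])
        for i, j, k in zip(i_min + ii, j_min + jj, kk):
            occ[i, j, k:] ^= True
    return VoxelGrid(origin=origin, spacing=spacing, occupancy=occ)


def mesh_from_voxels(grid: VoxelGrid, level: float = 0.5) -> trimesh.Trimesh:
    """Marching-cubes surface of a binary grid, welded, in world μm."""
    vol = np.pad(grid.occupancy.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(vol, level=level,
                                        spacing=(grid.spacing,) * 3)
    verts = verts + (grid.origin - grid.spacing)
    mesh = trimesh.Trimesh(verts, faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _spherical_closing(occ: np.ndarray, radius: float) -> np.ndarray:
    """Morphological closing with an exact Euclidean ball.

    Implemented with two distance transforms (dilation = within ``radius``
    of the set; erosion = deeper than ``radius`` inside the dilation), so
    the cost is independent of the radius.
    """
    dilated = ndimage.distance_transform_edt(~occ) <= radius
    return ndimage.distance_transform_edt(dilated) > radius


def repair_fragmentation(mesh: trimesh.Trimesh,
                         params: RepairParams = RepairParams()
                         ) -> trimesh.Trimesh:
    """Join fragmented spine pieces by voxel closing + marching cubes.

    The smallest structuring element (radius 3, 5, ... up to
    ``closing_radius`` voxels) that yields a single component is used,
    so well-separated fragments get bridged while the rest of the spine
    is distorted as little as possible. Raises :class:`RepairFailure`
    (carrying the residual component count) when pieces remain out of
    the largest element's reach.
    """
    grid = voxelize(mesh, params.voxel_spacing, pad=params.closing_radius + 2)
    radii = sorted({r for r in (3, 5, 8, 12, params.closing_radius)
                    if r <= params.closing_radius})
    out = None
    out_report = None
    for radius in radii:
        closed = _spherical_closing(grid.occupancy, radius)
        closed |= grid.occupancy
        out = mesh_from_voxels(VoxelGrid(grid.origin, grid.spacing, closed))
        out_report = validate_mesh(out)
        if out_report.n_components == 1:
            return out
    raise RepairFailure(
        f"{out_report.n_components} components remain after closing "
        f"(radius {params.closing_radius} voxels reaches "
        f"{2 * params.closing_radius * params.voxel_spacing:.3g} μm)",
        n_components=out_report.n_components,
    )


def reconstruct_neck(mesh: trimesh.Trimesh, insertion: InsertionPoint,
                     params: RepairParams = RepairParams(),
                     max_gap: int = 150, surface_tol: float = 0.05
                     ) -> trimesh.Trimesh:
    """Grow the missing neck of a detached spine down to its insertion point.

    The spine is rotated so the segment from its closest vertex to the
    insertion point runs along −z, voxelized, and the empty slices in
    between are filled top-down, each as a thresholded 2D Gaussian blur
    of the slice above. ``max_gap`` (voxel slices) guards against spines
    marked absurdly far from their dendrite.
    """
    pos = insertion.position
    d2 = np.linalg.norm(mesh.vertices - pos, axis=1)
    nearest = int(np.argmin(d2))
    gap_vec = pos - mesh.vertices[nearest]
    gap_len = float(np.linalg.norm(gap_vec))
    if gap_len <= surface_tol:
        warnings.warn("insertion point already on the surface; nothing to do",
                      NoOpWarning, stacklevel=2)
        return mesh.copy()
    n_slices_gap = int(np.ceil(gap_len / params.voxel_spacing))
    if n_slices_gap > max_gap:
        raise RepairFailure(
            f"gap of {n_slices_gap} voxel slices exceeds max_gap={max_gap}"
        )

    # rotate gap direction onto -z
    R = trimesh.geometry.align_vectors(gap_vec / gap_len, [0.0, 0.0, -1.0])
    work = mesh.copy()
    work.apply_transform(R)
    pos_r = (R[:3, :3] @ pos) + R[:3, 3]

    grid = voxelize(work, params.voxel_spacing, pad=3)
    occ = grid.occupancy
    # extend the grid downward to contain the insertion slice
    k_ins = int(np.floor((pos_r[2] - grid.origin[2]) / grid.spacing))
    if k_ins < 0:
        extra = -k_ins + 2
        occ = np.concatenate(
            [np.zeros((*occ.shape[:2], extra), dtype=bool), occ], axis=2
        )
        grid = VoxelGrid(grid.origin - [0, 0, extra * grid.spacing],
                         grid.spacing, occ)
        k_ins += extra

    filled = np.nonzero(occ.any(axis=(0, 1)))[0]
    k_base = int(filled.min())
    for k in range(k_base - 1, k_ins - 1, -1):
        blurred = ndimage.gaussian_filter(
            occ[:, :, k + 1].astype(float), sigma=params.gaussian_sigma
        )
        occ[:, :, k] = blurred > params.fill_threshold
        if not occ[:, :, k].any():
            raise RepairFailure(
                "neck growth died out before reaching the insertion point"
            )

    out = mesh_from_voxels(VoxelGrid(grid.origin, grid.spacing, occ))
    out.apply_transform(np.linalg.inv(R))
    return out


def smooth_curvature_flow(mesh: trimesh.Trimesh, iterations: int = 10,
                          step: float = 0.1) -> trimesh.Trimesh:
    """Umbrella-operator curvature flow.

    Each iteration moves every vertex a fraction ``step`` along its
    discrete mean-curvature (Laplacian) vector. Connectivity is
    unchanged; moderate defaults keep the enclosed volume within a few
    percent.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    if iterations == 0:
        return mesh.copy()
    V = np.asarray(mesh.vertices, dtype=float).copy()
    F = np.asarray(mesh.faces, dtype=np.int64)
    edges = np.sort(F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq = np.unique(edges, axis=0)
    n = len(V)
    for _ in range(iterations):
        nb_sum = np.zeros_like(V)
        deg = np.zeros(n)
        np.add.at(nb_sum, uniq[:, 0], V[uniq[:, 1]])
        np.add.at(nb_sum, uniq[:, 1], V[uniq[:, 0]])
        np.add.at(deg, uniq[:, 0], 1)
        np.add.at(deg, uniq[:, 1], 1)
        lap = nb_sum / np.maximum(deg, 1)[:, None] - V
        V += step * lap
    return trimesh.Trimesh(V, F.copy(), process=False)


@dataclass
class GateVerdict:
    accepted: bool
    reasons: list = field(default_factory=list)


def quality_gate(original: trimesh.Trimesh, repaired: trimesh.Trimesh,
                 max_volume_ratio_change: float = 2.0,
                 max_components: int = 1) -> GateVerdict:
    """Accept or discard a repaired spine.

    Rejects when the repaired/original volume ratio falls outside
    [1/max_volume_ratio_change, max_volume_ratio_change] ("volume_change")
    or when more than ``max_components`` closed components remain
    ("fragmentation"). All violated rules are listed.
    """
    reasons = []
    v0 = float(abs(original.volume))
    v1 = float(abs(repaired.volume))
    if v0 > 0:
        ratio = v1 / v0
        if ratio > max_volume_ratio_change or ratio < 1.0 / max_volume_ratio_change:
            reasons.append("volume_change")
    rep = validate_mesh(repaired)
    if rep.n_components > max_components:
        reasons.append("fragmentation")
    if not rep.watertight:
        reasons.append("not_watertight")
    return GateVerdict(accepted=not reasons, reasons=reasons)


def repair_spine(mesh: trimesh.Trimesh, insertion: InsertionPoint,
                 params: RepairParams = RepairParams(),
                 surface_tol: float = 0.05
                 ) -> tuple[trimesh.Trimesh, str]:
    """Full repair: close fragments, regrow the neck if detached, smooth.

    Returns the repaired mesh and the action taken
    (``none``/``closed``/``neck_grown``/``closed+neck_grown``).
    """
    actions = []
    out = mesh
    if validate_mesh(mesh).n_components > 1:
        out = repair_fragmentation(out, params)
        actions.append("closed")
    d = float(np.min(np.linalg.norm(out.vertices - insertion.position, axis=1)))
    if d > surface_tol:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NoOpWarning)
            out = reconstruct_neck(out, insertion, params,
                                   surface_tol=surface_tol)
        actions.append("neck_grown")
    if actions:
        out = smooth_curvature_flow(out, params.smoothing_iterations,
                                    params.smoothing_step)
    return out, "+".join(actions) if actions else "none"
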
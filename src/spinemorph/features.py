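"""Reeb-graph / ellipse-skeleton morphometry of spine meshes.

A spine surface is partitioned into K = 7 bands of equal geodesic width
measured from the insertion point. The six band boundaries are level-set
curves of the geodesic field; each is modelled as an ellipse in its
PCA best-fit plane. The ordered ellipses, together with the insertion
point (base) and the geodesically farthest vertex (apex), form the
spine's skeleton, from which 54 scalar features are read off:

==========================  ======  ==================================
feature block                count  meaning
==========================  ======  ==================================
height_1..7                      7  lengths of centroid-to-centroid links
major_axis_1..6                  6  ellipse semi-major lengths (μm)
minor_axis_1..6                  6  ellipse semi-minor lengths (μm)
bend_cos_1..6                    6  cosine between consecutive links
colatitude_2..7                  6  polar angle of each link (local frame)
normal_colatitude_1..6           6  polar angle of each ellipse normal
normal_azimuth_1..6              6  azimuth of each ellipse normal
area_ratio_2_4/2_6/4_6           3  ellipse-area ratios along the spine
region_volume_1..7               7  convex-hull volume of each band (μm³)
total_volume                     1  enclosed mesh volume (μm³)
==========================  ======  ==================================

The first 36 (heights, axes, bend cosines, ratios, volumes) describe
morphology; the remaining 18 (colatitudes and normal directions) fix
orientation and are what makes the descriptor invertible for simulation.
All angles are expressed in a spine-local frame (origin at the insertion
point, +z along the first link, +x along the first ellipse's major axis)
so the whole descriptor is invariant to rigid motion of the input mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel

from .geodesics import GeodesicField, geodesic_distances
from .mesh_io import InsertionPoint

__all__ = [
    "Ellipse",
    "Skeleton",
    "FeatureVector",
    "RegionPartition",
    "DegenerateBoundary",
    "FeatureExtractionError",
    "partition_regions",
    "extract_boundary_loops",
    "fit_boundary_ellipse",
    "region_volume",
    "extract_features",
    "feature_names",
    "geodesic_distances",
]

N_REGIONS = 7
N_FEATURES = 54


class DegenerateBoundary(ValueError):
    """A boundary loop is too degenerate for an ellipse fit."""


class FeatureExtractionError(RuntimeError):
    """Feature extraction failed; the message names the offending region."""


@dataclass
class Ellipse:
    """Planar ellipse in 3D: centroid, unit normal, in-plane major axis."""

    center: np.ndarray      # (3,) μm
    normal: np.ndarray      # unit
    major_dir: np.ndarray   # unit, ⟂ normal
    R: float                # semi-major (μm)
    r: float                # semi-minor (μm), R >= r > 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.major_dir = np.asarray(self.major_dir, dtype=float)
        if self.R < self.r:
            raise ValueError("semi-major R must be >= semi-minor r")
        if self.r <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def minor_dir(self) -> np.ndarray:
        return np.cross(self.normal, self.major_dir)

    @property
    def area(self) -> float:
        return float(np.pi * self.R * self.r)

    def sample(self, n: int) -> np.ndarray:
        """n parameter-uniform points on the ellipse, starting at major_dir."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return (self.center[None, :]
                + np.outer(self.R * np.cos(t), self.major_dir)
                + np.outer(self.r * np.sin(t), self.minor_dir))


@dataclass
class Skeleton:
    """Base point, six ordered boundary ellipses, apex point.

    Adjacent bands share their boundary ellipse exactly (the top of band
    i is the bottom of band i+1), so six ellipses bound the seven bands.
    """

    base: np.ndarray                # c_0, insertion point
    ellipses: list                  # E_1..E_6 (Ellipse)
    apex: np.ndarray                # c_7
    alpha: float | None = None      # max geodesic distance (μm), diagnostic

    @property
    def centroids(self) -> np.ndarray:
        """Chain c_0, c_1..c_6, c_7 as an (8, 3) array."""
        return np.vstack([self.base] + [e.center for e in self.ellipses] + [self.apex])

    @property
    def links(self) -> np.ndarray:
        """Vectors h_i = c_i - c_{i-1}, shape (7, 3)."""
        c = self.centroids
        return np.diff(c, axis=0)


@dataclass
class RegionPartition:
    labels: np.ndarray        # per-vertex label in 1..K
    K: int
    alpha: float
    bounds: np.ndarray        # interval edges, length K+1: 0, α/K, ..., α


def _names() -> list[str]:
    names = [f"height_{i}" for i in range(1, 8)]
    names += [f"major_axis_{e}" for e in range(1, 7)]
    names += [f"minor_axis_{e}" for e in range(1, 7)]
    names += [f"bend_cos_{i}" for i in range(1, 7)]
    names += [f"colatitude_{i}" for i in range(2, 8)]
    names += [f"normal_colatitude_{e}" for e in range(1, 7)]
    names += [f"normal_azimuth_{e}" for e in range(1, 7)]
    names += ["area_ratio_2_4", "area_ratio_2_6", "area_ratio_4_6"]
    names += [f"region_volume_{i}" for i in range(1, 8)]
    names += ["total_volume"]
    return names


_FEATURE_NAMES = _names()

MORPHOLOGICAL_FEATURES = tuple(
    n for n in _FEATURE_NAMES
    if n.split("_")[0] in {"height", "major", "minor", "bend", "area", "region", "total"}
)
DIRECTIONAL_FEATURES = tuple(
    n for n in _FEATURE_NAMES
    if n.startswith(("colatitude", "normal_colatitude", "normal_azimuth"))
)


def feature_names() -> list[str]:
    """The 54 feature names in canonical order."""
    return list(_FEATURE_NAMES)


@dataclass
class FeatureVector:
    """The 54-feature morphometric descriptor of one spine."""

    heights: np.ndarray            # (7,) |h_1..7| > 0, μm
    major_axes: np.ndarray         # (6,) μm
    minor_axes: np.ndarray         # (6,) μm
    bend_cosines: np.ndarray       # (6,) in [-1, 1]
    colatitudes: np.ndarray        # (6,) links 2..7, radians in [0, π]
    normal_colatitudes: np.ndarray  # (6,) radians in [0, π]
    normal_azimuths: np.ndarray    # (6,) radians in (-π, π]
    area_ratios: np.ndarray        # (3,) pairs (2,4), (2,6), (4,6), > 0
    region_volumes: np.ndarray     # (7,) μm³ > 0
    total_volume: float            # μm³ > 0
    spine_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name, size in [("heights", 7), ("major_axes", 6), ("minor_axes", 6),
                           ("bend_cosines", 6), ("colatitudes", 6),
                           ("normal_colatitudes", 6), ("normal_azimuths", 6),
                           ("area_ratios", 3), ("region_volumes", 7)]:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (size,):
                raise ValueError(f"{name} must have length {size}")
            setattr(self, name, arr)

    def validate(self) -> None:
        """Raise ValueError if any invariant is violated."""
        if not np.all(self.heights > 0):
            raise ValueError("heights must be positive")
        if not (np.all(self.major_axes >= self.minor_axes)
                and np.all(self.minor_axes > 0)):
            raise ValueError("semi-axes must satisfy R >= r > 0")
        if np.any(np.abs(self.bend_cosines) > 1 + 1e-12):
            raise ValueError("bend cosines must lie in [-1, 1]")
        for a in (self.colatitudes, self.normal_colatitudes):
            if np.any(a < -1e-12) or np.any(a > np.pi + 1e-12):
                raise ValueError("colatitudes must lie in [0, π]")
        if np.any(self.normal_azimuths <= -np.pi - 1e-12) \
                or np.any(self.normal_azimuths > np.pi + 1e-12):
            raise ValueError("azimuths must lie in (-π, π]")
        if not np.all(self.area_ratios > 0):
            raise ValueError("area ratios must be positive")
        if not np.all(self.region_volumes > 0) or self.total_volume <= 0:
            raise ValueError("volumes must be positive")

    def is_valid(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    def to_array(self) -> np.ndarray:
        return np.concatenate([
            self.heights, self.major_axes, self.minor_axes, self.bend_cosines,
            self.colatitudes, self.normal_colatitudes, self.normal_azimuths,
            self.area_ratios, self.region_volumes, [self.total_volume],
        ])

    @classmethod
    def from_array(cls, x: np.ndarray, spine_id: str | None = None) -> "FeatureVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_FEATURES,):
            raise ValueError(f"feature array must have length {N_FEATURES}")
        return cls(
            heights=x[0:7], major_axes=x[7:13], minor_axes=x[13:19],
            bend_cosines=x[19:25], colatitudes=x[25:31],
            normal_colatitudes=x[31:37], normal_azimuths=x[37:43],
            area_ratios=x[43:46], region_volumes=x[46:53],
            total_volume=float(x[53]), spine_id=spine_id,
        )


# ---------------------------------------------------------------------------
# partition and level-set boundary loops
# ---------------------------------------------------------------------------

def partition_regions(fieldv: GeodesicField, K: int = N_REGIONS) -> RegionPartition:
    """Split vertices into K equal-width geodesic-distance intervals.

    Region 1 is the closed interval [0, α/K]; region i > 1 is the
    half-open interval ((i-1)α/K, iα/K]. μ = 0 falls in region 1 and
    μ = α in region K by construction.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    alpha = fieldv.alpha
    if alpha <= 0:
        raise ValueError("geodesic field is constant (alpha = 0)")
    mu = fieldv.mu
    # ceil(mu*K/alpha) maps (0, α] onto 1..K; μ=0 special-cased to region 1
    labels = np.ceil(mu * K / alpha - 1e-12).astype(int)
    labels = np.clip(labels, 1, K)
    bounds = np.linspace(0.0, alpha, K + 1)
    return RegionPartition(labels=labels, K=K, alpha=alpha, bounds=bounds)


def _loops_at_level(mesh: trimesh.Trimesh, mu: np.ndarray, level: float
                    ) -> list[np.ndarray]:
    """Closed polylines where the μ field crosses ``level``.

    Each crossed edge contributes one interpolated point; faces with two
    crossed edges contribute a segment, and segments are chained into
    loops via shared edges.
    """
    below = mu <= level
    faces = mesh.faces
    segments: dict[tuple, list[tuple]] = {}
    pts: dict[tuple, np.ndarray] = {}
    for fi in range(len(faces)):
        tri = faces[fi]
        crossed = []
        for k in range(3):
            a, b = tri[k], tri[(k + 1) % 3]
            if below[a] != below[b]:
                key = (min(a, b), max(a, b))
                if key not in pts:
                    t = (level - mu[a]) / (mu[b] - mu[a])
                    pts[key] = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
                crossed.append(key)
        if len(crossed) == 2:
            segments.setdefault(crossed[0], []).append(crossed[1])
            segments.setdefault(crossed[1], []).append(crossed[0])
    loops: list[np.ndarray] = []
    visited: set[tuple] = set()
    for start in segments:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = None
            for cand in segments.get(cur, ()):
                if cand not in visited:
                    nxt = cand
                    break
            if nxt is None:
                break
            loop.append(nxt)
            visited.add(nxt)
            cur = nxt
        if len(loop) >= 3:
            loops.append(np.array([pts[k] for k in loop]))
    return loops


def _loop_area(loop: np.ndarray) -> float:
    """Enclosed area of a 3D loop projected on its best-fit plane."""
    c = loop.mean(axis=0)
    q = loop - c
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    xy = q @ vt[:2].T
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def extract_boundary_loops(mesh: trimesh.Trimesh, fieldv: GeodesicField,
                           K: int = N_REGIONS) -> list[np.ndarray]:
    """The K-1 region-boundary polylines (largest loop per level)."""
    alpha = fieldv.alpha
    loops_out = []
    for i in range(1, K):
        level = i * alpha / K
        # nudge off exact vertex values to keep crossings generic
        if np.any(np.abs(fieldv.mu - level) < 1e-12 * alpha):
            level += 1e-9 * alpha
        loops = _loops_at_level(mesh, fieldv.mu, level)
        if not loops:
            raise FeatureExtractionError(
                f"no boundary loop found at region boundary {i}"
            )
        loops_out.append(max(loops, key=_loop_area))
    return loops_out


# ---------------------------------------------------------------------------
# ellipse fitting and volumes
# ---------------------------------------------------------------------------

def fit_boundary_ellipse(points: np.ndarray) -> Ellipse:
    """Least-squares ellipse through an ordered 3D point loop.

    The plane is the span of the two leading principal directions of the
    points; a direct least-squares conic is fitted in-plane. The normal
    sign is left for the caller to orient; the major-axis sign is fixed
    intrinsically (non-negative dot with the first loop point) so results
    are rigid-motion covariant.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 6:
        raise DegenerateBoundary("need at least 6 points in 3D")
    c = points.mean(axis=0)
    q = points - c
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    scale = s[0] / np.sqrt(len(points))
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise DegenerateBoundary("points are collinear")
    u, v, n = vt[0], vt[1], vt[2]
    xy = q @ np.stack([u, v], axis=1)

    params = None
    try:
        model = EllipseModel.from_estimate(xy)
        ok = bool(model)
    except Exception:  # noqa: BLE001 - singular design matrix
        ok = False
    if ok:
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
        spread = np.abs(xy).max()
        if 0 < min(a, b) and max(a, b) < 5 * spread + 1e-12:
            params = (xc, yc, a, b, theta)
    if params is None:
        # moment fallback: exact for parameter-uniform samples
        cov = xy.T @ xy / len(xy)
        w, vecs = np.linalg.eigh(cov)
        a, b = np.sqrt(2 * w[1]), np.sqrt(2 * max(w[0], 1e-30))
        theta = np.arctan2(vecs[1, 1], vecs[0, 1])
        params = (0.0, 0.0, a, b, theta)
    xc, yc, a, b, theta = params
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    center = c + xc * u + yc * v
    major = np.cos(theta) * u + np.sin(theta) * v
    if np.dot(major, points[0] - center) < 0:
        major = -major
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    major -= np.dot(major, normal) * normal
    major /= np.linalg.norm(major)
    return Ellipse(center=center, normal=normal, major_dir=major,
                   R=float(a), r=float(max(b, 1e-9 * scale)))


def region_volume(bottom, top, samples_per_ellipse: int = 64) -> float:
    """Convex-hull volume between two band boundaries (μm³).

    ``bottom``/``top`` are each an :class:`Ellipse` or a 3D point (the
    base and apex bands are bounded by a point on one side).
    """
    def as_points(obj):
        if isinstance(obj, Ellipse):
            return obj.sample(samples_per_ellipse)
        return np.asarray(obj, dtype=float).reshape(1, 3)

    pb, pt = as_points(bottom), as_points(top)
    if pb.shape == pt.shape and np.allclose(pb, pt):
        raise ValueError("coincident boundaries enclose no volume")
    pts = np.vstack([pb, pt])
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate boundary pair (zero volume): {exc}") from exc
    if hull.volume <= 0:
        raise ValueError("degenerate boundary pair (zero volume)")
    return float(hull.volume)


# ---------------------------------------------------------------------------
# full descriptor
# ---------------------------------------------------------------------------

def _spherical(vec: np.ndarray, z: np.ndarray, x: np.ndarray, y: np.ndarray
               ) -> tuple[float, float]:
    """(colatitude, azimuth) of ``vec`` in the frame (x, y, z)."""
    n = np.linalg.norm(vec)
    col = float(np.arccos(np.clip(np.dot(vec, z) / n, -1.0, 1.0)))
    az = float(np.arctan2(np.dot(vec, y), np.dot(vec, x)))
    if az <= -np.pi:
        az = np.pi
    return col, az


def local_frame(skeleton: Skeleton) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spine-local orthonormal frame (x, y, z).

    Origin at the base; +z along the first link; +x along the first
    ellipse's major axis projected perpendicular to z.
    """
    h1 = skeleton.ellipses[0].center - skeleton.base
    z = h1 / np.linalg.norm(h1)
    x = skeleton.ellipses[0].major_dir.copy()
    x -= np.dot(x, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:  # major axis parallel to the first link; fall back
        x = np.array([1.0, 0.0, 0.0]) - z[0] * z
        if np.linalg.norm(x) < 1e-9:
            x = np.array([0.0, 1.0, 0.0]) - z[1] * z
        nx = np.linalg.norm(x)
    x /= nx
    y = np.cross(z, x)
    return x, y, z


def features_from_skeleton(skeleton: Skeleton, total_volume: float,
                           samples_per_ellipse: int = 64,
                           spine_id: str | None = None) -> FeatureVector:
    """Assemble the 54 features from a skeleton and a measured volume."""
    links = skeleton.links
    heights = np.linalg.norm(links, axis=1)
    if np.any(heights <= 0):
        raise FeatureExtractionError("zero-length link in skeleton")
    x, y, z = local_frame(skeleton)
    bend = np.array([
        float(np.dot(links[i], links[i + 1]) / (heights[i] * heights[i + 1]))
        for i in range(6)
    ])
    bend = np.clip(bend, -1.0, 1.0)
    colat = np.array([_spherical(links[i], z, x, y)[0] for i in range(1, 7)])
    ncol, naz = [], []
    for e, ell in enumerate(skeleton.ellipses):
        n = ell.normal if np.dot(ell.normal, links[e]) >= 0 else -ell.normal
        col, az = _spherical(n, z, x, y)
        ncol.append(col)
        naz.append(az)
    areas = np.array([e.area for e in skeleton.ellipses])
    ratios = np.array([areas[3] / areas[1], areas[5] / areas[1], areas[5] / areas[3]])
    bounds = [skeleton.base] + list(skeleton.ellipses) + [skeleton.apex]
    vols = np.array([
        region_volume(bounds[i], bounds[i + 1], samples_per_ellipse)
        for i in range(7)
    ])
    return FeatureVector(
        heights=heights,
        major_axes=np.array([e.R for e in skeleton.ellipses]),
        minor_axes=np.array([e.r for e in skeleton.ellipses]),
        bend_cosines=bend,
        colatitudes=colat,
        normal_colatitudes=np.array(ncol),
        normal_azimuths=np.array(naz),
        area_ratios=ratios,
        region_volumes=vols,
        total_volume=float(total_volume),
        spine_id=spine_id,
    )


def extract_features(mesh: trimesh.Trimesh, insertion, K: int = N_REGIONS,
                     method: str = "heat", samples_per_ellipse: int = 64,
                     spine_id: str | None = None
                     ) -> tuple[FeatureVector, Skeleton]:
    """Compute the 54-feature descriptor and skeleton of a repaired spine.

    The mesh must be watertight and single-component. The insertion point
    is snapped to the nearest vertex; the apex is the vertex of maximal
    geodesic distance (ties broken by lowest index).
    """
    if K != N_REGIONS:
        raise ValueError("the 54-feature descriptor is defined for K = 7")
    fieldv = geodesic_distances(mesh, insertion, method=method)
    base = mesh.vertices[fieldv.source_vertex].copy()
    mx = fieldv.mu.max()
    apex = mesh.vertices[int(np.argmax(fieldv.mu == mx))].copy()
    loops = extract_boundary_loops(mesh, fieldv, K)
    ellipses = []
    prev_center = base
    for i, loop in enumerate(loops, start=1):
        try:
            ell = fit_boundary_ellipse(loop)
        except DegenerateBoundary as exc:
            raise FeatureExtractionError(
                f"degenerate boundary at region {i}: {exc}"
            ) from exc
        if np.dot(ell.normal, ell.center - prev_center) < 0:
            ell.normal = -ell.normal
        ellipses.append(ell)
        prev_center = ell.center
    skeleton = Skeleton(base=base, ellipses=ellipses, apex=apex,
                        alpha=fieldv.alpha)
    total_volume = float(abs(mesh.volume))
    fv = features_from_skeleton(skeleton, total_volume,
                                samples_per_ellipse=samples_per_ellipse,
                                spine_id=spine_id)
    return fv, skeleton
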
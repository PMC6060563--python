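"""Parametric spine-like test geometry and feature populations.

Real dendritic-spine reconstructions are not redistributable, so every
stage of the pipeline is exercised on synthetic stand-ins generated here:

* :func:`make_synthetic_spine` — solids of revolution (a cylindrical neck
  with a flat base disk, optionally joined to a spherical head and bent
  along a circular arc) whose cross-section radius as a function of
  height is known in closed form, giving oracle values for the geodesic
  banding and ellipse fits. Dimensions default to the biological regime:
  spine extents of roughly 0.5–4 μm and volumes below ~1 μm³.
* :func:`corrupt_mesh` — emulates the two acquisition artefacts the
  repair stage targets: fragmentation (a band of surface deleted
  mid-neck, leaving two closed components) and detachment (the base
  removed and the insertion point left hanging below the mesh).
* :func:`sample_feature_population` — 54-feature populations drawn from
  a known Gaussian mixture, for parameter-recovery tests of the
  clustering stage.
* :func:`profile_feature_model` — a small mixture whose component means
  are descriptors measured from the parametric profiles; the geometric
  ground truth for simulation round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .cluster import MixtureModel
from .features import FeatureVector, extract_features, feature_names
from .geodesics import geodesic_distances
from .mesh_io import InsertionPoint, validate_mesh

__all__ = [
    "SpineSpec",
    "PROFILES",
    "default_spec",
    "make_synthetic_spine",
    "corrupt_mesh",
    "sample_feature_population",
    "template_feature_vector",
    "profile_feature_model",
]

PROFILES = ("stubby", "thin", "mushroom-like", "straight_tube")


@dataclass(frozen=True)
class SpineSpec:
    """Geometry of one parametric spine (lengths in μm)."""

    neck_length: float = 0.8
    neck_radius: float = 0.15
    head_radius: float = 0.30
    bend_angle: float = 0.0          # total axis turn, radians, [0, π/2]
    profile: str = "mushroom-like"
    mesh_resolution: int = 48        # points per ring; axial step scales with it
    twist_angle: float = 0.0         # azimuthal precession of the bend plane
    section_aspect: float = 1.0      # cross-section R/r (elliptical sections)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if min(self.neck_length, self.neck_radius, self.head_radius) <= 0:
            raise ValueError("all lengths must be positive")
        if not 0 <= self.bend_angle <= np.pi / 2:
            raise ValueError("bend_angle must lie in [0, π/2]")
        if self.profile != "straight_tube" and self.head_radius < self.neck_radius / 2:
            raise ValueError("head_radius < neck_radius/2 is not a spine geometry")
        if self.mesh_resolution < 12:
            raise ValueError("mesh_resolution must be at least 12")
        if self.section_aspect < 1.0:
            raise ValueError("section_aspect is R/r and must be >= 1")


_DEFAULTS = {
    "stubby": SpineSpec(neck_length=0.35, neck_radius=0.28, head_radius=0.38,
                        profile="stubby"),
    "thin": SpineSpec(neck_length=1.4, neck_radius=0.10, head_radius=0.22,
                      profile="thin"),
    "mushroom-like": SpineSpec(neck_length=0.8, neck_radius=0.15, head_radius=0.42,
                               profile="mushroom-like"),
    "straight_tube": SpineSpec(neck_length=2.0, neck_radius=0.3,
                               head_radius=0.3, profile="straight_tube"),
}


def default_spec(profile: str, **overrides) -> SpineSpec:
    """The default geometry for one of the four built-in profiles."""
    base = _DEFAULTS[profile]
    if overrides:
        from dataclasses import replace
        base = replace(base, **overrides)
    return base


def _radius_profile(spec: SpineSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Axial stations z, radii ρ(z), and total axis length.

    Flat disk at z = 0 (the base that meets the dendrite); for headed
    profiles the neck joins a sphere of radius head_radius tangentially
    and the surface closes at the head pole. straight_tube ends with a
    flat disk at the far end instead.
    """
    r_n, r_h, ln = spec.neck_radius, spec.head_radius, spec.neck_length
    n_axial = max(24, spec.mesh_resolution)
    if spec.profile == "straight_tube":
        z = np.linspace(0.0, ln, n_axial)
        rho = np.full_like(z, r_n)
        return z, rho, ln
    # sphere centre placed so the neck meets it tangentially
    zc = ln + np.sqrt(max(r_h ** 2 - r_n ** 2, 0.0))
    z_end = zc + r_h
    z_neck = np.linspace(0.0, ln, max(8, int(n_axial * ln / z_end) + 2),
                         endpoint=False)
    # denser sampling over the head where curvature is high
    t = np.linspace(0.0, 1.0, max(12, n_axial // 2))
    z_head = ln + (z_end - ln) * (1 - np.cos(t * np.pi / 2))  # cluster at tip
    z = np.concatenate([z_neck, z_head])
    rho = np.where(z <= ln, r_n, np.sqrt(np.maximum(r_h ** 2 - (z - zc) ** 2, 0.0)))
    keep = rho > 0.02 * r_h
    keep[0] = True
    return z[keep], rho[keep], z_end


def _bend_frames(z: np.ndarray, total_length: float, bend_angle: float,
                 twist_angle: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Ring centres and tangents for a bent (optionally twisted) axis.

    The tangent's colatitude grows linearly in arc length up to
    ``bend_angle``; ``twist_angle`` precesses the bending plane
    azimuthally, giving a helical (non-planar) axis. bend_angle = 0 gives
    the straight axis (0, 0, z); centres integrate the tangent.
    """
    if bend_angle == 0.0:
        centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        tangents = np.tile([0.0, 0.0, 1.0], (len(z), 1))
        return centers, tangents
    frac = z / total_length
    gamma = bend_angle * frac
    psi = twist_angle * frac
    tangents = np.column_stack([np.sin(gamma) * np.cos(psi),
                                np.sin(gamma) * np.sin(psi),
                                np.cos(gamma)])
    centers = np.zeros_like(tangents)
    if len(z) > 1:
        mid = 0.5 * (tangents[1:] + tangents[:-1]) * np.diff(z)[:, None]
        centers[1:] = np.cumsum(mid, axis=0)
    return centers, tangents


def make_synthetic_spine(spec: SpineSpec, seed: int = 0, roughness: float = 0.0
                         ) -> tuple[trimesh.Trimesh, InsertionPoint, dict]:
    """Build a watertight parametric spine mesh.

    Returns (mesh, insertion point at the base pole, ground truth). The
    ground-truth dict carries the axial stations, analytic cross-section
    radii and ring centres for oracle checks. ``roughness`` adds seeded
    radial noise (fraction of the local radius) for smoothing tests.
    """
    z, rho, total = _radius_profile(spec)
    # one extra station at the very tip of the axis for the closing pole
    centers, tangents = _bend_frames(np.append(z, total), total,
                                     spec.bend_angle, spec.twist_angle)
    centers, tip = centers[:-1], centers[-1]
    tangents = tangents[:-1]
    n_theta = spec.mesh_resolution
    rng = np.random.default_rng(seed)
    step = max(total / max(len(z) - 1, 1), 1e-3)

    # assemble rings: flat base-cap annuli, the side stations, and for the
    # tube profile flat far-cap annuli (heads close through the sphere
    # sampling). Concentric cap rings avoid the degenerate slivers a
    # single pole fan would create.
    # Caps are shallow domes (sagitta 25% of the cap radius) rather than
    # flat disks: a perfectly flat base makes the first geodesic band
    # coplanar with the insertion point on squat spines, which is a
    # degenerate (zero-volume) descriptor region. A gentle bulge also
    # matches how a spine base meets the curved dendritic shaft.
    # Cross-section anisotropy (R/r) applies along the neck and tapers to
    # a circular section at the tip: an elongated head would put the
    # geodesically farthest vertex (the descriptor's apex) off-axis at
    # the end of the major meridian, an unstable terminus.
    def aspect_at(zk: float) -> float:
        a = spec.section_aspect
        if a == 1.0 or spec.profile == "straight_tube":
            return a
        ln = spec.neck_length
        if zk <= ln:
            return a
        # fully circular from the head equator up, so the upper head is a
        # true sphere cap and the farthest vertex stays on-axis
        zc = total - spec.head_radius
        return max(1.0, a + (1.0 - a) * (zk - ln) / max(zc - ln, 1e-9))

    rings: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    sag = 0.25 * rho[0]
    n_cap = max(2, int(np.ceil(rho[0] / step)))
    for r in np.linspace(0.0, rho[0], n_cap + 1)[1:-1]:
        bulge = sag * (1.0 - (r / rho[0]) ** 2)
        rings.append((centers[0] - bulge * tangents[0], tangents[0], float(r),
                      aspect_at(0.0)))
    for k in range(len(z)):
        rings.append((centers[k], tangents[k], float(rho[k]), aspect_at(z[k])))
    if spec.profile == "straight_tube":
        sag_t = 0.25 * rho[-1]
        n_cap_t = max(2, int(np.ceil(rho[-1] / step)))
        for r in np.linspace(rho[-1], 0.0, n_cap_t + 1)[1:-1]:
            bulge = sag_t * (1.0 - (r / rho[-1]) ** 2)
            rings.append((centers[-1] + bulge * tangents[-1], tangents[-1],
                          float(r), spec.section_aspect))

    if spec.profile == "straight_tube":
        tip = centers[-1] + 0.25 * rho[-1] * tangents[-1]

    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    verts = [centers[0] - sag * tangents[0]]  # base pole at the dome apex
    base_pole = 0
    ring_start = []
    ref = np.array([1.0, 0.0, 0.0])
    for center, t_vec, radius, aspect in rings:
        u = ref - np.dot(ref, t_vec) * t_vec
        u /= np.linalg.norm(u)
        v = np.cross(t_vec, u)
        if roughness > 0:
            radius = radius * (1.0 + roughness * rng.standard_normal(n_theta))
        ring = (center[None, :]
                + np.outer(aspect * radius * np.cos(theta), u)
                + np.outer(radius * np.sin(theta), v))
        ring_start.append(len(verts))
        verts.extend(ring)
    tip_idx = len(verts)
    verts.append(tip)

    faces = []
    # base pole fan (wound so the normal points away from the spine body)
    s0 = ring_start[0]
    for j in range(n_theta):
        faces.append([base_pole, s0 + (j + 1) % n_theta, s0 + j])
    for k in range(len(rings) - 1):
        a, b = ring_start[k], ring_start[k + 1]
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a + j, a + jn, b + j])
            faces.append([a + jn, b + jn, b + j])
    sl = ring_start[-1]
    for j in range(n_theta):
        faces.append([tip_idx, sl + j, sl + (j + 1) % n_theta])

    mesh = trimesh.Trimesh(np.asarray(verts, dtype=float),
                           np.asarray(faces, dtype=np.int64), process=False)
    if mesh.volume < 0:
        mesh.invert()
    insertion = InsertionPoint("synthetic", np.asarray(verts[0], dtype=float).copy())
    truth = {
        "stations_z": z,
        "radii": rho,
        "ring_centers": centers,
        "total_length": total,
        "spec": spec,
    }
    return mesh, insertion, truth


def _boundary_loops(mesh: trimesh.Trimesh) -> list[list[int]]:
    """Ordered vertex loops of all open boundaries."""
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    loops, seen = [], set()
    for start in adj:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = start
        while True:
            nxt = next((n for n in adj[cur] if n not in seen), None)
            if nxt is None:
                break
            loop.append(nxt)
            seen.add(nxt)
            cur = nxt
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def _cap_boundaries(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Close every open boundary loop with a centroid fan."""
    verts = [np.asarray(mesh.vertices, dtype=float)]
    faces = [np.asarray(mesh.faces, dtype=np.int64)]
    n = len(mesh.vertices)
    for loop in _boundary_loops(mesh):
        centroid = mesh.vertices[loop].mean(axis=0)
        verts.append(centroid[None, :])
        fan = np.array([[loop[k], loop[(k + 1) % len(loop)], n]
                        for k in range(len(loop))], dtype=np.int64)
        faces.append(fan)
        n += 1
    out = trimesh.Trimesh(np.vstack(verts), np.vstack(faces), process=False)
    trimesh.repair.fix_normals(out)
    return out


def corrupt_mesh(mesh: trimesh.Trimesh, mode: str, magnitude: float,
                 insertion: InsertionPoint, seed: int = 0
                 ) -> tuple[trimesh.Trimesh, InsertionPoint]:
    """Damage a watertight spine the way confocal reconstructions fail.

    ``fragment`` deletes a band of faces of geodesic width ``magnitude``
    (μm) around the mid-level and recloses both sides, leaving two
    watertight components. ``detach`` removes the proximal part up to
    geodesic height ``magnitude`` and moves the insertion point the same
    distance below the new base. ``magnitude = 0`` returns the input
    unchanged.
    """
    if magnitude == 0:
        return mesh.copy(), insertion
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    field = geodesic_distances(mesh, insertion, method="graph")
    if magnitude > 0.5 * field.alpha:
        raise ValueError(
            f"magnitude {magnitude} exceeds half the spine extent "
            f"({0.5 * field.alpha:.3g})"
        )
    mu_face = field.mu[mesh.faces]
    if mode == "fragment":
        mid = 0.45 * field.alpha
        kill = np.all((mu_face > mid - magnitude / 2)
                      & (mu_face < mid + magnitude / 2), axis=1)
        if not kill.any():
            raise ValueError("band too narrow for this mesh resolution")
        kept = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces[~kill],
                               process=False)
        kept.remove_unreferenced_vertices()
        return _cap_boundaries(kept), insertion
    if mode == "detach":
        kill = np.all(mu_face < magnitude, axis=1)
        if not kill.any():
            raise ValueError("magnitude below mesh resolution")
        kept = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces[~kill],
                               process=False)
        kept.remove_unreferenced_vertices()
        capped = _cap_boundaries(kept)
        # the cap vertex added last is the new base centre
        cap_center = capped.vertices[-1]
        direction = insertion.position - cap_center
        nd = np.linalg.norm(direction)
        direction = direction / nd if nd > 1e-12 else np.array([0.0, 0.0, -1.0])
        new_pos = cap_center + magnitude * direction
        return capped, InsertionPoint(insertion.spine_id, new_pos)
    raise ValueError(f"unknown corruption mode {mode!r}")


# ---------------------------------------------------------------------------
# feature populations
# ---------------------------------------------------------------------------

def _base_template() -> np.ndarray:
    """A plausible 54-feature spine in the biological size regime."""
    heights = np.array([0.30, 0.28, 0.27, 0.27, 0.28, 0.30, 0.26])
    major = np.array([0.22, 0.18, 0.16, 0.18, 0.28, 0.24])
    minor = 0.85 * major
    bend = np.full(6, 0.97)
    colat = np.array([0.12, 0.15, 0.18, 0.20, 0.22, 0.20])
    ncol = np.array([0.10, 0.12, 0.15, 0.18, 0.20, 0.18])
    naz = np.array([0.0, 0.3, 0.5, 0.6, 0.7, 0.6])
    areas = np.pi * major * minor
    ratios = np.array([areas[3] / areas[1], areas[5] / areas[1], areas[5] / areas[3]])
    # frustum-like band volumes consistent with the axes
    vols = []
    a_seq = np.concatenate([[1e-3], areas, [1e-3]])
    for i in range(7):
        a1, a2 = a_seq[i], a_seq[i + 1]
        vols.append(heights[i] / 3.0 * (a1 + a2 + np.sqrt(a1 * a2)))
    vols = np.array(vols)
    return np.concatenate([heights, major, minor, bend, colat, ncol, naz,
                           ratios, vols, [vols.sum()]])


def sample_feature_population(n_clusters: int = 3, n_per_cluster: int = 500,
                              separation: float = 5.0, seed: int = 0
                              ) -> tuple[np.ndarray, np.ndarray, MixtureModel]:
    """Draw a 54-feature population from a known Gaussian mixture.

    Cluster means sit at the corners of a regular simplex embedded in
    feature space, with pairwise distance ``separation`` × the pooled
    per-feature standard deviation (root-mean-square of the diagonal
    sds). Covariances are diagonal-dominant random PD matrices. Rows
    violating descriptor invariants are redrawn, so every returned row is
    a valid feature vector. Returns (X, labels, generating model).
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    base = _base_template()
    d = base.size
    sd = 0.05 * np.abs(base) + 0.005
    pooled = float(np.sqrt(np.mean(sd ** 2)))

    # regular simplex directions in a random orthonormal subspace
    if n_clusters > 1:
        simplex = np.eye(n_clusters) - 1.0 / n_clusters
        simplex /= np.linalg.norm(simplex[0] - simplex[1])  # unit side
        Q, _ = np.linalg.qr(rng.standard_normal((d, n_clusters)))
        offsets = separation * pooled * (simplex @ Q.T)
    else:
        offsets = np.zeros((1, d))
    means = base[None, :] + offsets

    covs = np.empty((n_clusters, d, d))
    for c in range(n_clusters):
        A = rng.standard_normal((d, 4)) / 2.0
        corr = 0.1 * (A @ A.T)  # mild low-rank correlation, diagonal-dominant
        np.fill_diagonal(corr, 1.0)
        covs[c] = corr * np.outer(sd, sd)
        covs[c] += 1e-8 * np.eye(d)

    def rows_valid(draw: np.ndarray) -> np.ndarray:
        ok = np.all(draw[:, 0:7] > 0, axis=1)                  # heights
        ok &= np.all(draw[:, 13:19] > 0, axis=1)               # minor axes
        ok &= np.all(draw[:, 7:13] >= draw[:, 13:19], axis=1)  # R >= r
        ok &= np.all(np.abs(draw[:, 19:25]) <= 1, axis=1)      # bend cos
        ok &= np.all((draw[:, 25:37] >= 0)
                     & (draw[:, 25:37] <= np.pi), axis=1)      # colatitudes
        ok &= np.all((draw[:, 37:43] > -np.pi)
                     & (draw[:, 37:43] <= np.pi), axis=1)      # azimuths
        ok &= np.all(draw[:, 43:] > 0, axis=1)                 # ratios, volumes
        return ok

    X = np.empty((n_clusters * n_per_cluster, d))
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    for c in range(n_clusters):
        need = n_per_cluster
        rows = []
        while need > 0:
            draw = rng.multivariate_normal(means[c], covs[c], size=2 * need)
            kept = draw[rows_valid(draw)][:need]
            rows.append(kept)
            need -= len(kept)
        X[labels == c] = np.vstack(rows)
    model = MixtureModel(
        weights=np.full(n_clusters, 1.0 / n_clusters),
        means=means, covariances=covs, feature_names=feature_names(),
    )
    return X, labels, model


def template_feature_vector(profile: str, bend_angle: float = 0.5,
                            twist_angle: float = 1.2,
                            aspect: float = 1.2) -> FeatureVector:
    """Descriptor measured from a bent, elliptic-section template.

    The helical bend keeps link colatitudes well away from zero and the
    cross-section anisotropy (local R/r = ``aspect``) keeps ellipse axes
    well away from the circular R = r boundary, so a Gaussian centred on
    this descriptor stays inside the descriptor's validity region.
    """
    spec = default_spec(profile, bend_angle=bend_angle, twist_angle=twist_angle,
                        section_aspect=aspect)
    mesh, insertion, _ = make_synthetic_spine(spec)
    fv, _ = extract_features(mesh, insertion, spine_id=f"template_{profile}")
    return fv


# per-block draw sds for profile_feature_model: lengths and volumes get a
# relative sd; angle-like blocks get a small absolute sd, kept well below
# the margins the bent templates leave to the validity boundaries.
_BLOCK_REL = {"heights": 0.03, "axes": 0.03, "ratios": 0.03, "volumes": 0.03}
_BLOCK_ABS = {"bend_cos": 0.004, "colat": 0.010, "normal_colat": 0.010,
              "normal_az": 0.020}


def profile_feature_model(profiles=("stubby", "thin", "mushroom-like"),
                          sd_scale: float = 1.0) -> MixtureModel:
    """A Gaussian mixture whose means are measured profile descriptors.

    Each component is centred on the 54-feature descriptor extracted
    from one bent parametric profile, with independent per-feature sds
    (relative for lengths/volumes, absolute for angles, scaled by
    ``sd_scale``). Samples from this model are geometrically consistent,
    which makes it the reference population for simulation round-trip
    checks.
    """
    means, covs = [], []
    for p in profiles:
        m = template_feature_vector(p).to_array()
        sd = np.empty(54)
        sd[0:7] = _BLOCK_REL["heights"] * np.abs(m[0:7])
        sd[7:19] = _BLOCK_REL["axes"] * np.abs(m[7:19])
        sd[19:25] = _BLOCK_ABS["bend_cos"]
        sd[25:31] = _BLOCK_ABS["colat"]
        sd[31:37] = _BLOCK_ABS["normal_colat"]
        sd[37:43] = _BLOCK_ABS["normal_az"]
        sd[43:46] = _BLOCK_REL["ratios"] * np.abs(m[43:46])
        sd[46:54] = _BLOCK_REL["volumes"] * np.abs(m[46:54])
        sd = np.maximum(sd * sd_scale, 1e-6)
        means.append(m)
        covs.append(np.diag(sd ** 2))
    C = len(means)
    return MixtureModel(
        weights=np.full(C, 1.0 / C),
        means=np.array(means),
        covariances=np.array(covs),
        feature_names=feature_names(),
    )
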
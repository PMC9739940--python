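"""Synthetic single-view seedling scenes with ground-truth labels.

Emulates what a top-down depth camera sees of a melon-type seedling: a thin
vertical stem, one to three curved leaves with controllable top-view overlap,
a planar ground with a seedling tray beneath it, plus the two characteristic
depth-camera artefacts — *hover points* (chains of spurious returns strung
along the viewing ray at silhouette edges) and sparse uniform outliers.

Every leaf is an elliptical patch in parameter space bent by a quadratic bowl
``z = kappa (u^2 + v^2)`` and then rigidly posed, so its exact surface area is
available in closed form via first-fundamental-form quadrature; the areas are
attached to the cloud metadata and anchor the phenotyping tests.

The camera is orthographic along -z (the sensor looks straight down), so the
viewing axis is z everywhere below.  Because the scan is single-view, the stem
cylinder is sampled only on its camera-visible upper strip: surface elements
whose outward normal points more than ``STEM_VISIBLE_HALF_ANGLE`` away from
vertical return no depth samples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import Frame, LabeledCloud

__all__ = [
    "SeedlingSpec",
    "NoiseSpec",
    "generate_seedling",
    "add_scene_background",
    "add_sensor_noise",
    "leaf_patch_area",
]

#: z of the stem base above the ground datum (pot soil level), meters.
PLANT_BASE_Z = 0.10
#: minor/major axis ratio of the leaf ellipse.
LEAF_MINOR_RATIO = 0.6
#: lean of the stem (hypocotyl) axis from vertical, degrees.  Cucurbit
#: seedlings sprawl; a leaning stem is also what makes the stem surface
#: visible to a top-down camera at all.
STEM_TILT = 50.0
#: azimuthal half-width (degrees) of the camera-visible strip of the stem
#: cylinder, measured around its most upward-facing line.
STEM_STRIP_HALF_ANGLE = 25.0
#: Gaussian surface jitter emulating sensor depth noise, meters.
SURFACE_JITTER = 2e-4


@dataclass(frozen=True)
class SeedlingSpec:
    """Geometry of one synthetic seedling.

    Defaults model a 2-leaf-stage melon seedling: 4 cm leaves bowed by a
    gentle quadratic curvature (8 m^-1 gives a ~1.3 cm rise at the tip), an
    8 cm stem of 4 mm radius, and moderate top-view leaf overlap.
    """

    n_leaves: int = 2
    leaf_radius: float = 0.04  # semi-major axis, m
    leaf_curvature: float = 8.0  # kappa of z = kappa (u^2+v^2), 1/m
    stem_height: float = 0.08  # m
    stem_radius: float = 0.004  # m
    overlap_fraction: float = 0.3
    points_per_organ: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves not in (1, 2, 3):
            raise ValueError("n_leaves must be 1, 2 or 3 (the covered growth stages)")
        for name in ("leaf_radius", "stem_height", "stem_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1); full overlap is degenerate")
        if self.points_per_organ < 50:
            raise ValueError("points_per_organ must be >= 50")
        if self.leaf_curvature < 0:
            raise ValueError("leaf_curvature must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Depth-camera noise model parameters.

    ``hover_fraction`` of silhouette-edge points each spawn a chain of
    ``hover_chain_len`` points interpolated along the viewing ray toward the
    surface behind the edge; ``outlier_fraction`` of the cloud size is added
    as uniform points in the bounding box inflated by ``outlier_box_scale``.
    The densities are free parameters of the model, not calibrated claims.
    """

    hover_fraction: float = 0.3
    hover_chain_len: int = 6
    outlier_fraction: float = 0.02
    outlier_box_scale: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hover_fraction <= 1.0:
            raise ValueError("hover_fraction must lie in [0, 1]")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if self.hover_chain_len < 1:
            raise ValueError("hover_chain_len must be >= 1")


def _bend_factor(u: np.ndarray, v: np.ndarray, kappa: float) -> np.ndarray:
    """Area element sqrt(1 + |grad z|^2) of the bowl z = kappa (u^2+v^2)."""
    return np.sqrt(1.0 + 4.0 * kappa**2 * (u**2 + v**2))


def leaf_patch_area(a: float, b: float, kappa: float, order: int = 64) -> float:
    """Exact surface area of the bent elliptical leaf patch.

    The patch is the ellipse ``(u/a)^2 + (v/b)^2 <= 1`` lifted by
    ``z = kappa (u^2 + v^2)``; the area is the first-fundamental-form integral
    of :func:`_bend_factor`, evaluated by tensor-product Gauss-Legendre
    quadrature (exact to machine precision at the default order for the
    smooth integrand involved).
    """
    # map (r, phi) in [0,1] x [0,2pi] onto the ellipse; Jacobian = a b r
    xr, wr = np.polynomial.legendre.leggauss(order)
    r = 0.5 * (xr + 1.0)
    wr = 0.5 * wr
    xp, wp = np.polynomial.legendre.leggauss(order)
    phi = np.pi * (xp + 1.0)
    wp = np.pi * wp
    rr, pp = np.meshgrid(r, phi, indexing="ij")
    u = a * rr * np.cos(pp)
    v = b * rr * np.sin(pp)
    integrand = _bend_factor(u, v, kappa) * a * b * rr
    return float(np.einsum("i,j,ij->", wr, wp, integrand))


def _sample_leaf_patch(rng: np.random.Generator, n: int, a: float, b: float, kappa: float) -> np.ndarray:
    """Area-uniform sample of the bent patch, in its local (u, v, z) frame.

    Rejection sampling: draw uniformly over the flat ellipse, accept with
    probability proportional to the local area element so the accepted points
    are uniform with respect to *surface* area.
    """
    gmax = _bend_factor(np.array(a), np.array(0.0), kappa)
    pts = np.empty((0, 3))
    while len(pts) < n:
        m = max(2 * (n - len(pts)), 64)
        r = np.sqrt(rng.random(m))
        phi = rng.random(m) * 2 * np.pi
        u = a * r * np.cos(phi)
        v = b * r * np.sin(phi)
        keep = rng.random(m) * gmax <= _bend_factor(u, v, kappa)
        z = kappa * (u[keep] ** 2 + v[keep] ** 2)
        pts = np.vstack([pts, np.column_stack([u[keep], v[keep], z])])
    return pts[:n]


def _sample_stem(rng: np.random.Generator, n: int, radius: float, height: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the camera-visible upper strip of the leaning stem cylinder.

    The stem axis leans :data:`STEM_TILT` degrees from vertical in the x-z
    plane and climbs a vertical height ``height``; only the strip within
    :data:`STEM_STRIP_HALF_ANGLE` of the cylinder's most upward-facing line
    returns depth samples.  Returns ``(points, top_center)`` where
    ``top_center`` is the crown point the leaves attach to.
    """
    tilt = np.deg2rad(STEM_TILT)
    axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    # most upward-facing direction perpendicular to the axis, and its side
    up = np.array([0.0, 0.0, 1.0]) - axis[2] * axis
    up /= np.linalg.norm(up)
    side = np.cross(axis, up)
    length = height / np.cos(tilt)
    s = rng.uniform(0.0, length, n)
    beta = np.deg2rad(rng.uniform(-STEM_STRIP_HALF_ANGLE, STEM_STRIP_HALF_ANGLE, n))
    pts = (
        s[:, None] * axis
        + radius * np.cos(beta)[:, None] * up
        + radius * np.sin(beta)[:, None] * side
    )
    return pts, length * axis


def generate_seedling(spec: SeedlingSpec) -> LabeledCloud:
    """Generate one labeled seedling cloud in the sensor frame.

    Stem points carry semantic 0 / instance 0; leaf *i* carries semantic 1 /
    instance *i*.  The exact analytic area of every leaf patch is recorded in
    ``metadata["leaf_areas"]`` keyed by instance id.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    a = spec.leaf_radius
    b = LEAF_MINOR_RATIO * a
    kappa = spec.leaf_curvature

    parts, sems, insts = [], [], []

    stem, crown = _sample_stem(rng, spec.points_per_organ, spec.stem_radius, spec.stem_height)
    stem[:, 2] += PLANT_BASE_Z
    crown = crown + np.array([0.0, 0.0, PLANT_BASE_Z])
    parts.append(stem)
    sems.append(np.zeros(len(stem), dtype=np.int64))
    insts.append(np.zeros(len(stem), dtype=np.int64))

    span = 2 * np.pi / spec.n_leaves
    delta = span * (1.0 - spec.overlap_fraction) if spec.n_leaves > 1 else 0.0
    area = leaf_patch_area(a, b, kappa)
    leaf_areas = {}
    for i in range(spec.n_leaves):
        local = _sample_leaf_patch(rng, spec.points_per_organ, a, b, kappa)
        azim = i * delta
        c, s = np.cos(azim), np.sin(azim)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        # petiole offset: leaf center sits one semi-major axis out from the crown
        posed = local @ rot.T
        posed += crown + np.array([1.15 * a * c, 1.15 * a * s, 0.006 * (i + 1)])
        parts.append(posed)
        sems.append(np.ones(len(posed), dtype=np.int64))
        insts.append(np.full(len(posed), i + 1, dtype=np.int64))
        leaf_areas[i + 1] = area

    pts = np.vstack(parts)
    pts += rng.normal(0.0, SURFACE_JITTER, pts.shape)
    return LabeledCloud(
        points=pts,
        semantic=np.concatenate(sems),
        instance=np.concatenate(insts),
        noise_mask=np.zeros(len(pts), dtype=bool),
        frame=Frame.SENSOR,
        metadata={"leaf_areas": leaf_areas, "spec": asdict(spec)},
    )


def add_scene_background(
    cloud: LabeledCloud,
    ground_z: float = 0.0,
    tray_height: float = 0.12,
    seed: int = 0,
    ground_extent: float = 0.5,
    tray_extent: float = 0.3,
    density: float = 20000.0,
) -> LabeledCloud:
    """Append a planar ground and a box-like seedling tray beneath it.

    The ground is a ``ground_extent`` x ``ground_extent`` square at
    ``z = ground_z``; the tray is a ``tray_extent`` box whose walls and bottom
    span ``z`` in ``[ground_z - tray_height, ground_z]``.  Appended points
    carry the unlabeled sentinel (semantic -1) and ``noise_mask = False``, so
    preprocessing — not the labels — must remove them.  Point counts are
    ``round(density * area)`` per surface.
    """
    if ground_z >= cloud.points[:, 2].min():
        raise ValueError("ground_z must lie below the plant")
    rng = np.random.default_rng(seed)
    surfaces = []

    n_ground = round(density * ground_extent**2)
    g = np.column_stack([
        rng.uniform(-ground_extent / 2, ground_extent / 2, n_ground),
        rng.uniform(-ground_extent / 2, ground_extent / 2, n_ground),
        np.full(n_ground, ground_z),
    ])
    surfaces.append(g)

    # four tray walls
    h = tray_height
    for axis, sign in ((0, 1), (0, -1), (1, 1), (1, -1)):
        n_wall = round(density * tray_extent * h)
        wall = np.empty((n_wall, 3))
        wall[:, axis] = sign * tray_extent / 2
        wall[:, 1 - axis] = rng.uniform(-tray_extent / 2, tray_extent / 2, n_wall)
        wall[:, 2] = rng.uniform(ground_z - h, ground_z, n_wall)
        surfaces.append(wall)
    # tray bottom
    n_bot = round(density * tray_extent**2)
    bot = np.column_stack([
        rng.uniform(-tray_extent / 2, tray_extent / 2, n_bot),
        rng.uniform(-tray_extent / 2, tray_extent / 2, n_bot),
        np.full(n_bot, ground_z - h),
    ])
    surfaces.append(bot)

    bg = np.vstack(surfaces)
    bg += rng.normal(0.0, SURFACE_JITTER, bg.shape)
    n_bg = len(bg)

    sem = cloud.semantic if cloud.semantic is not None else np.full(len(cloud), -1, dtype=np.int64)
    inst = cloud.instance if cloud.instance is not None else np.full(len(cloud), -1, dtype=np.int64)
    mask = cloud.noise_mask if cloud.noise_mask is not None else np.zeros(len(cloud), dtype=bool)
    return LabeledCloud(
        points=np.vstack([cloud.points, bg]),
        semantic=np.concatenate([sem, np.full(n_bg, -1, dtype=np.int64)]),
        instance=np.concatenate([inst, np.full(n_bg, -1, dtype=np.int64)]),
        noise_mask=np.concatenate([mask, np.zeros(n_bg, dtype=bool)]),
        frame=cloud.frame,
        metadata=dict(cloud.metadata),
    )


def silhouette_edge_points(points: np.ndarray, k: int = 10, threshold: float = 0.6) -> np.ndarray:
    """Indices of points whose top-view (x, y) neighborhood is one-sided.

    A point is an edge point when the centroid of its k nearest top-view
    neighbors is displaced from it by more than ``threshold`` times the mean
    neighbor distance — the discrete analogue of lying on the silhouette
    boundary, where depth cameras generate mixed returns.
    """
    xy = points[:, :2]
    k = min(k, len(xy) - 1)
    tree = cKDTree(xy)
    dist, idx = tree.query(xy, k=k + 1)
    nbrs = xy[idx[:, 1:]]
    offset = np.linalg.norm(nbrs.mean(axis=1) - xy, axis=1)
    mean_d = dist[:, 1:].mean(axis=1)
    return np.flatnonzero(offset > threshold * mean_d)


def add_sensor_noise(cloud: LabeledCloud, noise: NoiseSpec) -> LabeledCloud:
    """Inject hover-point chains and uniform outliers; injected points get
    ``noise_mask = True`` and sentinel labels.

    Hover chains: for a sampled subset of plant silhouette-edge points, insert
    ``hover_chain_len`` points at exactly the same (x, y) — collinear with the
    viewing axis — with z interpolated strictly between the edge point and the
    first surface behind it along the ray (the ground if nothing intervenes).
    Exact injected count is
    ``floor(hover_fraction * n_edges) * chain_len + floor(outlier_fraction * N)``.
    """
    rng = np.random.default_rng(noise.seed)
    n_in = len(cloud)
    pts = cloud.points

    plant_idx = (
        np.flatnonzero(cloud.semantic >= 0) if cloud.semantic is not None else np.arange(n_in)
    )
    edges = plant_idx[silhouette_edge_points(pts[plant_idx])] if len(plant_idx) > 10 else np.array([], int)

    n_chains = int(np.floor(noise.hover_fraction * len(edges)))
    chains = []
    if n_chains > 0:
        chosen = rng.choice(edges, size=n_chains, replace=False)
        floor_z = pts[:, 2].min()
        xy_tree = cKDTree(pts[:, :2])
        for i in chosen:
            x, y, z = pts[i]
            near = xy_tree.query_ball_point([x, y], r=0.01)
            below = [j for j in near if pts[j, 2] < z - 0.01]
            z_behind = max(pts[j, 2] for j in below) if below else floor_z
            t = np.arange(1, noise.hover_chain_len + 1) / (noise.hover_chain_len + 1)
            chain = np.column_stack([
                np.full(noise.hover_chain_len, x),
                np.full(noise.hover_chain_len, y),
                z - t * (z - z_behind),
            ])
            chains.append(chain)

    n_out = int(np.floor(noise.outlier_fraction * n_in))
    injected = chains
    if n_out > 0:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        center, half = (lo + hi) / 2, (hi - lo) / 2 * noise.outlier_box_scale
        injected = injected + [rng.uniform(center - half, center + half, (n_out, 3))]

    if not injected:
        return cloud.select(np.arange(n_in))  # identity copy

    new = np.vstack(injected)
    m = len(new)
    sem = cloud.semantic if cloud.semantic is not None else np.full(n_in, -1, dtype=np.int64)
    inst = cloud.instance if cloud.instance is not None else np.full(n_in, -1, dtype=np.int64)
    mask = cloud.noise_mask if cloud.noise_mask is not None else np.zeros(n_in, dtype=bool)
    return LabeledCloud(
        points=np.vstack([pts, new]),
        semantic=np.concatenate([sem, np.full(m, -1, dtype=np.int64)]),
        instance=np.concatenate([inst, np.full(m, -1, dtype=np.int64)]),
        noise_mask=np.concatenate([mask, np.ones(m, dtype=bool)]),
        frame=cloud.frame,
        metadata=dict(cloud.metadata),
    )
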
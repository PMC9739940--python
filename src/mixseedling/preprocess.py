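"""Background removal, hover/outlier filtering, and sampling utilities.

The denoising pipeline for a raw top-view seedling scene is:

1. :func:`passthrough_filter` — axis-aligned crop box around the pot
   (defaults 0.5 m x 0.5 m x 0.7 m).
2. :func:`fit_plane_lsq` + :func:`remove_ground_and_tray` — total-least-squares
   ground plane, then cut away the ground and the seedling tray sitting in the
   band 0.11-0.13 m below it.
3. :func:`neighborhood_filter` — the neighborhood-space-constraint rule: a
   point is deleted when the mean distance ``D`` to its ``N`` nearest
   neighbors reaches ``d`` (sparse outliers) or when the angle ``W`` between
   its estimated surface normal and the viewing axis reaches ``c`` (hover
   points strung along the line of sight).  Defaults ``N = 12``,
   ``d = 0.0034`` m, ``c = 60`` degrees.

Also here: unit-cube normalization, iterative farthest-point sampling, and
curvature (surface-variation) key-point sampling used by the network encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import Frame, LabeledCloud, Plane

__all__ = [
    "FilterParams",
    "BoxLimits",
    "NormalizeTransform",
    "passthrough_filter",
    "fit_plane_lsq",
    "estimate_ground_plane",
    "remove_ground_and_tray",
    "estimate_normals",
    "neighborhood_filter",
    "normalize_unit",
    "fps_downsample",
    "curvature_sample",
]


@dataclass(frozen=True)
class FilterParams:
    """Neighborhood-space-constraint filter parameters (N, d, c)."""

    N: int = 12  # neighborhood size
    d: float = 0.0034  # mean-neighbor-distance threshold, meters
    c: float = 60.0  # normal-to-viewing-axis angle threshold, degrees

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("N must be >= 3")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not 0 < self.c <= 90:
            raise ValueError("c must lie in (0, 90] degrees")


@dataclass(frozen=True)
class BoxLimits:
    """Axis-aligned crop box centered on the camera axis (meters)."""

    length: float = 0.5
    width: float = 0.5
    height: float = 0.7

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("box dimensions must be positive")


@dataclass(frozen=True)
class NormalizeTransform:
    """Record of the centroid/scale map applied by :func:`normalize_unit`.

    ``normalized = (points - centroid) / scale``.  Areas measured in the
    normalized frame map back to physical units via ``area * scale**2``.
    """

    centroid: np.ndarray
    scale: float

    def inverse(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) * self.scale + self.centroid

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.centroid) / self.scale


def passthrough_filter(cloud: LabeledCloud, box: BoxLimits = BoxLimits()) -> LabeledCloud:
    """Keep exactly the points inside the closed crop box, preserving order."""
    p = cloud.points
    keep = (
        (np.abs(p[:, 0]) <= box.length / 2)
        & (np.abs(p[:, 1]) <= box.width / 2)
        & (np.abs(p[:, 2]) <= box.height / 2)
    )
    if not keep.any():
        raise ValueError("no plant in crop box")
    return cloud.select(keep)


def fit_plane_lsq(points: np.ndarray) -> Plane:
    """Total-least-squares plane (minimal orthogonal residuals).

    The plane passes through the centroid with normal the eigenvector of the
    smallest covariance eigenvalue; the normal is oriented so its z component
    is non-negative.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
        raise ValueError("need at least 3 points of shape (M, 3)")
    centroid = points.mean(axis=0)
    q = points - centroid
    cov = q.T @ q
    evals, evecs = np.linalg.eigh(cov)
    # rank-deficient: the two smallest eigenvalues vanish => collinear input
    if evals[1] <= 1e-12 * max(evals[2], 1e-30):
        raise ValueError("degenerate (collinear) input: plane is not unique")
    normal = evecs[:, 0]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return Plane(normal=normal / np.linalg.norm(normal), offset=-float(normal @ centroid))


def estimate_ground_plane(cloud: LabeledCloud, bin_width: float = 0.01, band: float = 0.015) -> Plane:
    """Fit the ground by a z-histogram mode.

    The ground is the dominant horizontal structure of a cropped scene, so the
    modal z bin locates it; the plane is then total-least-squares fit to all
    points within ``band`` of the mode.
    """
    z = cloud.points[:, 2]
    edges = np.arange(z.min(), z.max() + bin_width, bin_width)
    hist, _ = np.histogram(z, bins=edges)
    mode = edges[np.argmax(hist)] + bin_width / 2
    sel = np.abs(z - mode) < band
    if sel.sum() < 3:
        raise ValueError("not enough points near the modal height to fit a ground plane")
    return fit_plane_lsq(cloud.points[sel])


def remove_ground_and_tray(
    cloud: LabeledCloud,
    plane: Plane,
    cut_offset: float = 0.12,
    plane_tol: float = 0.005,
) -> LabeledCloud:
    """Remove the ground plane and the tray band beneath it.

    Deletes every point within ``plane_tol`` of the plane (the ground itself,
    jitter included) together with the band extending ``cut_offset`` below it
    (the tray).  Points clearly above the plane — the plant — survive.
    ``cut_offset`` outside the 0.11-0.13 m band triggers a warning only.
    """
    if not 0.11 <= cut_offset <= 0.13:
        warnings.warn(
            f"cut_offset {cut_offset} outside the calibrated 0.11-0.13 m tray band",
            stacklevel=2,
        )
    sd = plane.signed_distance(cloud.points)
    remove = (sd <= plane_tol) & (sd >= -cut_offset - plane_tol)
    if remove.all():
        raise ValueError("ground/tray removal deleted every point")
    return cloud.select(~remove)


def _knn_indices(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and indices of the k nearest neighbors of every point,
    excluding the point itself."""
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k + 1)
    return dist[:, 1:], idx[:, 1:]


def estimate_normals(cloud: LabeledCloud, N: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Per-point unit normals from local least-squares planes.

    The normal of point ``p`` is the normal of the total-least-squares plane
    through ``p`` and its ``N`` nearest neighbors, folded so that
    ``normal . z >= 0``.  Returns ``(normals, degenerate)`` where
    ``degenerate`` flags neighborhoods too collinear to define a plane; those
    normals are set to the z axis.
    """
    points = cloud.points
    if len(points) < N + 1:
        raise ValueError(f"cloud must have at least N+1 = {N + 1} points")
    _, idx = _knn_indices(points, N)
    nbhd = np.concatenate([points[:, None, :], points[idx]], axis=1)  # (n, N+1, 3)
    q = nbhd - nbhd.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", q, q)
    evals, evecs = np.linalg.eigh(cov)
    normals = evecs[:, :, 0]
    degenerate = evals[:, 1] <= 1e-18 + 1e-12 * evals[:, 2]
    normals[degenerate] = np.array([0.0, 0.0, 1.0])
    flip = normals[:, 2] < 0
    normals[flip] = -normals[flip]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return normals, degenerate


def neighborhood_filter(
    cloud: LabeledCloud, params: FilterParams = FilterParams()
) -> tuple[LabeledCloud, np.ndarray]:
    """Delete hover points and sparse outliers in a single full pass.

    For every point of the *input* cloud: ``D`` = mean Euclidean distance to
    its ``N`` nearest neighbors, ``W`` = angle (degrees, folded to [0, 90])
    between the local least-squares normal and the viewing axis.  A point is
    removed iff ``D >= d`` or ``W >= c``; all D and W are computed before any
    deletion, so the pass is order-independent.

    Returns ``(kept_cloud, removed_mask)`` with the mask aligned to the input.
    """
    points = cloud.points
    if len(points) < params.N + 1:
        raise ValueError(f"cloud must have at least N+1 = {params.N + 1} points")
    dist, _ = _knn_indices(points, params.N)
    D = dist.mean(axis=1)
    normals, _ = estimate_normals(cloud, N=params.N)
    cos_w = np.clip(np.abs(normals[:, 2]), 0.0, 1.0)
    W = np.degrees(np.arccos(cos_w))
    removed = (D >= params.d) | (W >= params.c)
    if removed.all():
        raise ValueError("neighborhood filter removed every point; check units of d")
    return cloud.select(~removed), removed


def normalize_unit(cloud: LabeledCloud) -> tuple[LabeledCloud, NormalizeTransform]:
    """Center at the centroid and isotropically scale so max |coordinate| = 1."""
    if len(cloud) < 2:
        raise ValueError("need at least 2 points to normalize")
    centroid = cloud.points.mean(axis=0)
    centered = cloud.points - centroid
    scale = float(np.abs(centered).max())
    if scale == 0.0:
        raise ValueError("zero-extent cloud cannot be normalized")
    out = cloud.with_(points=centered / scale, frame=Frame.NORMALIZED)
    return out, NormalizeTransform(centroid=centroid, scale=scale)


def _fps_indices(points: np.ndarray, n: int, start: int) -> np.ndarray:
    """Greedy farthest-point sampling indices starting from ``start``."""
    total = len(points)
    chosen = np.empty(n, dtype=np.int64)
    chosen[0] = start
    mind = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, n):
        nxt = int(np.argmax(mind))
        chosen[i] = nxt
        np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1), out=mind)
    return chosen


def fps_downsample(cloud: LabeledCloud, n: int, seed: int | None = None) -> LabeledCloud:
    """Iterative farthest-point sampling down to ``n`` points.

    The start point is chosen by ``seed`` (index drawn from a seeded RNG); by
    default it is the point farthest from the centroid, which makes the
    sampling fully deterministic without randomness.
    """
    if n > len(cloud):
        raise ValueError(f"cannot sample {n} points from a cloud of {len(cloud)}")
    if seed is None:
        start = int(np.argmax(np.linalg.norm(cloud.points - cloud.points.mean(axis=0), axis=1)))
    else:
        start = int(np.random.default_rng(seed).integers(len(cloud)))
    idx = _fps_indices(cloud.points, n, start)
    return cloud.select(idx)


def surface_variation(points: np.ndarray, k: int = 16) -> np.ndarray:
    """Surface variation s = lambda0 / (lambda0+lambda1+lambda2) per point,
    from the covariance eigenvalues of the k-nearest-neighbor patch."""
    k = min(k, len(points) - 1)
    _, idx = _knn_indices(points, k)
    nbhd = np.concatenate([points[:, None, :], points[idx]], axis=1)
    q = nbhd - nbhd.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", q, q)
    evals = np.linalg.eigvalsh(cov)
    total = evals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, evals[:, 0] / total, 0.0)
    return s


def curvature_sample(cloud: LabeledCloud, n: int, k: int = 16) -> np.ndarray:
    """Curvature key-point sampling: indices of ``n`` high-variation points.

    Points are visited in order of decreasing surface variation (ties broken
    by index) and accepted greedily unless within the suppression radius
    (bounding-box diagonal / sqrt(n)) of an already accepted point, which
    keeps spatial coverage.  If the greedy pass exhausts the cloud before
    selecting ``n`` points, the remainder is filled by farthest-point
    sampling relative to the accepted set.  Fully deterministic.
    """
    points = cloud.points
    total = len(points)
    if n > total:
        raise ValueError(f"cannot sample {n} key points from {total} points")
    if n == total:
        return np.arange(total)
    s = surface_variation(points, k=k)
    if s.max() - s.min() <= 1e-9 * max(s.max(), 1e-12):
        # all-tie case (e.g. a flat plane): fall back to plain FPS
        start = int(np.argmax(np.linalg.norm(points - points.mean(axis=0), axis=1)))
        return _fps_indices(points, n, start)
    bbox_diag = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    radius = bbox_diag / np.sqrt(n) if n > 0 else 0.0
    order = np.lexsort((np.arange(total), -s))
    accepted: list[int] = []
    acc_pts = np.empty((0, 3))
    for i in order:
        if len(accepted) == n:
            break
        if acc_pts.size and np.min(np.linalg.norm(acc_pts - points[i], axis=1)) < radius:
            continue
        accepted.append(int(i))
        acc_pts = np.vstack([acc_pts, points[i]])
    if len(accepted) < n:
        # farthest-point fill: maximize distance to everything accepted so far
        mind = np.min(
            np.linalg.norm(points[:, None, :] - acc_pts[None, :, :], axis=2), axis=1
        )
        mind[accepted] = -np.inf
        while len(accepted) < n:
            nxt = int(np.argmax(mind))
            accepted.append(nxt)
            mind = np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1))
            mind[nxt] = -np.inf
    return np.asarray(accepted, dtype=np.int64)
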
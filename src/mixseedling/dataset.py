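"""Self-supervised occlusion dataset machinery.

Training data for leaf completion is manufactured from intact leaves: 14
viewpoints are placed on a cube around each leaf (8 corners + 6 face centers)
and the fraction of points nearest a sampled viewpoint (15%, 25% or 50%) is
removed, mimicking the way a neighboring leaf occludes the part of a leaf
facing it.  Segmentation data is augmented fourfold by random per-axis
translation in [-0.2, 0.2] and anisotropic scaling in [0.67, 1.5] (normalized
units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cloud import LabeledCloud
from .preprocess import fps_downsample

__all__ = [
    "CompletionPair",
    "AugmentParams",
    "cube_viewpoints",
    "remove_nearest_fraction",
    "augment",
    "build_segmentation_dataset",
    "build_completion_dataset",
    "save_completion_pairs_h5",
    "load_completion_pairs_h5",
]

#: the degrees of missingness used to manufacture occlusion
DEFAULT_FRACTIONS = (0.15, 0.25, 0.50)


@dataclass
class CompletionPair:
    """(partial, removed, complete) training/eval unit for leaf completion."""

    partial: LabeledCloud
    removed: LabeledCloud
    complete: LabeledCloud
    viewpoint: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        n = len(self.complete)
        if len(self.partial) + len(self.removed) != n:
            raise ValueError("|partial| + |removed| must equal |complete|")
        if abs(self.fraction - len(self.removed) / n) > 1.0 / n:
            raise ValueError("fraction inconsistent with |removed| / |complete|")
        self.viewpoint = np.asarray(self.viewpoint, dtype=np.float64).reshape(3)


@dataclass(frozen=True)
class AugmentParams:
    """Random translation/scaling augmentation; ``copies_per_cloud`` counts
    the original, so the default 4 quadruples the dataset."""

    translation_range: tuple[float, float] = (-0.2, 0.2)
    scale_range: tuple[float, float] = (0.67, 1.5)
    copies_per_cloud: int = 4

    def __post_init__(self) -> None:
        if self.translation_range[0] > self.translation_range[1]:
            raise ValueError("translation_range must be ordered")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be ordered")
        if self.copies_per_cloud < 1:
            raise ValueError("copies_per_cloud must be >= 1")


def cube_viewpoints(center: np.ndarray = np.zeros(3), half_extent: float = 1.0) -> np.ndarray:
    """The 14 occlusion viewpoints: 8 cube corners then 6 face centers.

    Order is fixed: corners in lexicographic (-,-,-) ... (+,+,+) sign order,
    then face centers -x, +x, -y, +y, -z, +z.
    """
    if half_extent <= 0:
        raise ValueError("half_extent must be positive")
    center = np.asarray(center, dtype=np.float64).reshape(3)
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=np.float64)
    faces = np.array(
        [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]], dtype=np.float64
    )
    return center + half_extent * np.vstack([corners, faces])


def remove_nearest_fraction(complete: LabeledCloud, viewpoint, fraction: float) -> CompletionPair:
    """Remove the ``round(fraction * N)`` points nearest the viewpoint.

    Ties in distance are broken by input index (stable argsort), making the
    removal deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    viewpoint = np.asarray(viewpoint, dtype=np.float64).reshape(3)
    n = len(complete)
    k = int(round(fraction * n))
    if k == 0 or k == n:
        raise ValueError(f"fraction {fraction} removes {k} of {n} points; nothing to learn")
    dist = np.linalg.norm(complete.points - viewpoint, axis=1)
    order = np.argsort(dist, kind="stable")
    removed_idx = np.sort(order[:k])
    kept_idx = np.sort(order[k:])
    return CompletionPair(
        partial=complete.select(kept_idx),
        removed=complete.select(removed_idx),
        complete=complete,
        viewpoint=viewpoint,
        fraction=fraction,
    )


def augment(cloud: LabeledCloud, params: AugmentParams = AugmentParams(), seed: int = 0) -> list[LabeledCloud]:
    """The original plus ``copies_per_cloud - 1`` jittered clones.

    Each clone is scaled anisotropically (one uniform draw per axis in
    ``scale_range``) and translated (one uniform draw per axis in
    ``translation_range``); labels are copied verbatim.  Applied in the
    normalized frame.
    """
    rng = np.random.default_rng(seed)
    out = [cloud]
    lo_t, hi_t = params.translation_range
    lo_s, hi_s = params.scale_range
    for _ in range(params.copies_per_cloud - 1):
        scale = rng.uniform(lo_s, hi_s, 3)
        shift = rng.uniform(lo_t, hi_t, 3)
        out.append(cloud.with_(points=cloud.points * scale + shift))
    return out


def build_segmentation_dataset(
    clouds: Sequence[LabeledCloud],
    params: AugmentParams = AugmentParams(),
    n_points: int = 2048,
    train_count: Optional[int] = None,
    seed: int = 0,
) -> dict:
    """Assemble the stem/leaf segmentation dataset manifest.

    Each source cloud must carry semantic and instance labels; it is resampled
    to ``n_points`` by farthest-point sampling, then augmented
    ``copies_per_cloud``-fold.  The first ``train_count`` sources (default:
    all but the last ~13%, matching a 130/20 split at 150 sources) form the
    training split.  Returns a manifest dict with the entries and counts.
    """
    for i, c in enumerate(clouds):
        if c.semantic is None or c.instance is None:
            raise ValueError(f"cloud {i} lacks semantic/instance labels")
    if train_count is None:
        train_count = int(round(len(clouds) * 130 / 150))
    entries = {"train": [], "test": []}
    for i, c in enumerate(clouds):
        base = fps_downsample(c, min(n_points, len(c)))
        split = "train" if i < train_count else "test"
        for j, aug in enumerate(augment(base, params, seed=seed + i)):
            entries[split].append({"source": i, "copy": j, "cloud": aug})
    return {
        "n_sources_train": train_count,
        "n_sources_test": len(clouds) - train_count,
        "copies_per_cloud": params.copies_per_cloud,
        "n_train": len(entries["train"]),
        "n_test": len(entries["test"]),
        "train": entries["train"],
        "test": entries["test"],
    }


def build_completion_dataset(
    leaves: Sequence[LabeledCloud],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    copies_per_leaf: int = 1,
    viewpoint_scale: float = 1.5,
    seed: int = 0,
) -> list[CompletionPair]:
    """One completion pair per (leaf, copy): a viewpoint drawn uniformly from
    the 14 cube viewpoints (cube half-extent = ``viewpoint_scale`` times the
    leaf's bounding-box half-diagonal, so every viewpoint lies outside the
    leaf) and a degree of missingness drawn uniformly from ``fractions``."""
    rng = np.random.default_rng(seed)
    fractions = list(fractions)
    pairs = []
    for leaf in leaves:
        lo, hi = leaf.points.min(axis=0), leaf.points.max(axis=0)
        center = (lo + hi) / 2
        half = viewpoint_scale * float(np.linalg.norm(hi - lo)) / 2
        vps = cube_viewpoints(center, half)
        for _ in range(copies_per_leaf):
            vp = vps[rng.integers(len(vps))]
            frac = fractions[rng.integers(len(fractions))]
            pairs.append(remove_nearest_fraction(leaf, vp, frac))
    return pairs


def save_completion_pairs_h5(pairs: Sequence[CompletionPair], path) -> None:
    """Persist pairs as HDF5 groups {partial, removed, complete} (n x 3 float32)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, p in enumerate(pairs):
            g = fh.create_group(f"pair_{i:05d}")
            g.create_dataset("partial", data=p.partial.points.astype(np.float32))
            g.create_dataset("removed", data=p.removed.points.astype(np.float32))
            g.create_dataset("complete", data=p.complete.points.astype(np.float32))
            g.attrs["viewpoint"] = p.viewpoint
            g.attrs["fraction"] = p.fraction


def load_completion_pairs_h5(path) -> list[CompletionPair]:
    import h5py

    pairs = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            pairs.append(
                CompletionPair(
                    partial=LabeledCloud(points=g["partial"][()].astype(np.float64)),
                    removed=LabeledCloud(points=g["removed"][()].astype(np.float64)),
                    complete=LabeledCloud(points=g["complete"][()].astype(np.float64)),
                    viewpoint=np.asarray(g.attrs["viewpoint"]),
                    fraction=float(g.attrs["fraction"]),
                )
            )
    return pairs
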
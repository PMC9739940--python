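"""The point-mixer segmentation/completion network.

Architecture
------------
*Encoder*: four stages of neighborhood aggregation followed by point-mixer
blocks.  Stage ``s`` samples ``encoder_resolutions[s]`` key points by
curvature sampling, groups each with its ``encoder_k[s]`` nearest neighbors,
and aggregates ``max-pool_k LBR(concat(F_i - F_ik, repeat(F_i, k)))`` into
``encoder_dims[s]`` channels.  Resolutions shrink (2048 -> 256) while channel
widths grow (128 -> 1024): the coarsest stage is the widest, mirroring the
decoder's printed widths in reverse.

*Point-mixer block*: a residual two-sublayer unit on an ``S x D`` group/
channel matrix — channel mixing per group, then, through a transpose, group
mixing per channel:

    Fc = Fs + MLP(LayerNorm(Fs))
    Fo = Fc + T(MLP(T(LayerNorm(Fc))))

*Completion decoder*: progressive coarse-to-fine generation (256 -> 512 ->
1024 -> 2048 points).  Each stage interpolates the running features onto the
encoder's same-resolution point set (inverse-distance 3-NN feature
propagation — a deliberate, simpler stand-in for graph-convolution
up-sampling), fuses them with the encoder's skip features, mixes, and emits
per-point 3-D coordinates; each stage's predicted points carry the features
to the next stage.

*Heads*: classification (two LBR + dropout 0.5 stacks and a final linear),
per-point semantic segmentation (same stack, category vector concatenated),
a 5-D instance embedding (pointwise linear + LeakyReLU) clustered by
mean shift, and the completion coordinate MLPs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..cloud import LabeledCloud
from ..preprocess import curvature_sample
from .autodiff import Tensor, concat, leaky_relu, max_axis, sum_axis, take
from .layers import LBR, MLP2, Dropout, LayerNorm, Linear, Module

__all__ = [
    "StageConfig",
    "FeaturePyramid",
    "PointMixerBlock",
    "MixNet",
    "point_mixer_block",
    "upsample_interpolate",
    "mean_shift_cluster",
]


@dataclass(frozen=True)
class StageConfig:
    """Resolutions, neighborhood sizes and channel widths of the network.

    ``default()`` is the full-scale configuration; ``desk_scale()`` is a
    proportionally shrunk configuration for CPU-scale experiments (256-point
    clouds), with the same structure.
    """

    encoder_resolutions: tuple[int, ...] = (2048, 1024, 512, 256)
    encoder_k: tuple[int, ...] = (32, 16, 8, 4)
    encoder_dims: tuple[int, ...] = (128, 256, 512, 1024)  # width grows as resolution shrinks
    decoder_resolutions: tuple[int, ...] = (256, 512, 1024, 2048)
    decoder_dims: tuple[int, ...] = (1024, 512, 256, 128)
    mixer_layers_per_stage: int = 2
    n_classes: int = 1
    n_parts: int = 2
    instance_dim: int = 5
    dropout: float = 0.5

    def __post_init__(self) -> None:
        lists = (self.encoder_resolutions, self.encoder_k, self.encoder_dims,
                 self.decoder_resolutions, self.decoder_dims)
        if len({len(x) for x in lists}) != 1:
            raise ValueError("all per-stage lists must have the same length")
        if list(self.encoder_resolutions) != sorted(self.encoder_resolutions, reverse=True):
            raise ValueError("encoder resolutions must be strictly decreasing")
        if list(self.decoder_resolutions) != sorted(self.decoder_resolutions):
            raise ValueError("decoder resolutions must be strictly increasing")
        if self.instance_dim != 5:
            raise ValueError("the instance embedding is 5-dimensional")

    @classmethod
    def default(cls) -> "StageConfig":
        return cls()

    @classmethod
    def desk_scale(cls, n_classes: int = 1, n_parts: int = 2) -> "StageConfig":
        return cls(
            encoder_resolutions=(256, 128, 64, 32),
            encoder_k=(16, 8, 8, 4),
            encoder_dims=(32, 64, 96, 128),
            decoder_resolutions=(32, 64, 128, 256),
            decoder_dims=(128, 96, 64, 32),
            mixer_layers_per_stage=2,
            n_classes=n_classes,
            n_parts=n_parts,
        )

    @property
    def input_resolution(self) -> int:
        return self.encoder_resolutions[0]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "StageConfig":
        raw = json.loads(text)
        for key in ("encoder_resolutions", "encoder_k", "encoder_dims",
                    "decoder_resolutions", "decoder_dims"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class FeaturePyramid:
    """Per-stage (points, features) emitted by the encoder."""

    stages: list[tuple[np.ndarray, Tensor]] = field(default_factory=list)

    def resolutions(self) -> list[int]:
        return [len(p) for p, _ in self.stages]


# ---------------------------------------------------------------------------
# functional pieces
# ---------------------------------------------------------------------------

def knn_indices(query: np.ndarray, source: np.ndarray, k: int) -> np.ndarray:
    """Indices into ``source`` of the k nearest neighbors of each query point
    (the query point itself included when it belongs to the source)."""
    if k > len(source):
        raise ValueError(f"k={k} exceeds the {len(source)} source points")
    _, idx = cKDTree(source).query(query, k=k)
    if k == 1:
        idx = idx[:, None]
    return idx


def neighborhood_aggregate(
    points: np.ndarray,
    features: Tensor,
    n_out: int,
    k: int,
    lbr: LBR,
) -> tuple[np.ndarray, Tensor]:
    """One neighborhood-aggregation step.

    Curvature-samples ``n_out`` centers, groups each with its ``k`` nearest
    input points, and aggregates ``max-pool_k LBR(concat(F_i - F_ik,
    repeat(F_i, k)))``; the concat doubles the channel axis ahead of the
    linear map.
    """
    centers = curvature_sample(LabeledCloud(points=points), n_out)
    nbr = knn_indices(points[centers], points, k)  # (n_out, k)
    f_ik = take(features, nbr)  # (n_out, k, d)
    f_i = take(features, np.broadcast_to(centers[:, None], nbr.shape))  # repeated centers
    grouped = concat([f_i - f_ik, f_i], axis=-1)  # (n_out, k, 2d)
    out = max_axis(lbr(grouped), axis=1)  # (n_out, d_out)
    return points[centers], out


class PointMixerBlock(Module):
    """Residual channel-mixing + group-mixing unit on an ``S x D`` matrix."""

    def __init__(self, S: int, D: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(D)
        self.mlp_channel = MLP2(D, D, D, rng)
        self.ln2 = LayerNorm(D)
        self.mlp_group = MLP2(S, S, S, rng)

    def __call__(self, x: Tensor) -> Tensor:
        fc = x + self.mlp_channel(self.ln1(x))
        fo = fc + self.mlp_group(self.ln2(fc).T).T
        return fo


def point_mixer_block(x: Tensor, block: PointMixerBlock) -> Tensor:
    """Functional alias used by the tests."""
    return block(x)


def upsample_interpolate(
    points_lo: np.ndarray, feats_lo: Tensor, points_hi: np.ndarray, eps: float = 1e-8
) -> Tensor:
    """Inverse-distance-weighted 3-NN feature propagation.

    Each high-resolution point receives the weighted average of the features
    of its three nearest low-resolution points, weights proportional to
    ``1/(dist + eps)``.  A zero-distance neighbor therefore dominates, so
    features are copied exactly where the point sets coincide.  The weights
    are treated as constants (no gradient flows into the coordinates).
    """
    if len(points_lo) == 0 or len(points_hi) == 0:
        raise ValueError("cannot interpolate between empty point sets")
    k = min(3, len(points_lo))
    dist, idx = cKDTree(points_lo).query(points_hi, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    w = 1.0 / (dist + eps)
    w = w / w.sum(axis=1, keepdims=True)
    gathered = take(feats_lo, idx)  # (n_hi, k, d)
    return sum_axis(gathered * Tensor(w[:, :, None]), axis=1)


def mean_shift_cluster(embedding: np.ndarray, bandwidth: float = 0.2) -> np.ndarray:
    """Flat-kernel mean-shift instance labels.

    Labels are contiguous from 0 and ordered by cluster size descending.
    The default bandwidth is twice the instance-loss margin, linking the
    clustering scale to the embedding geometry the loss enforces.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    embedding = np.asarray(embedding, dtype=np.float64)
    if len(embedding) == 1:
        return np.zeros(1, dtype=np.int64)
    from sklearn.cluster import MeanShift

    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False, cluster_all=True)
    raw = ms.fit_predict(embedding)
    # enforce the contract: contiguous ids ordered by cluster size descending,
    # ties broken by first appearance
    ids, counts = np.unique(raw, return_counts=True)
    first_seen = np.array([np.argmax(raw == i) for i in ids])
    order = np.lexsort((first_seen, -counts))
    remap = {int(ids[o]): rank for rank, o in enumerate(order)}
    return np.array([remap[int(r)] for r in raw], dtype=np.int64)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _EncoderStage(Module):
    def __init__(self, d_in: int, d_out: int, S: int, layers: int, rng: np.random.Generator):
        self.lbr = LBR(2 * d_in, d_out, rng)
        self.mixers = [PointMixerBlock(S, d_out, rng) for _ in range(layers)]


class _FuseStage(Module):
    """Skip fusion used by the feature-propagation (segmentation) decoder."""

    def __init__(self, d_in: int, d_skip: int, d_out: int, rng: np.random.Generator):
        self.fuse = LBR(d_in + d_skip, d_out, rng)


class _DecoderStage(Module):
    def __init__(self, d_in: int, d_skip: int, d_out: int, S: int, layers: int,
                 rng: np.random.Generator):
        self.fuse = LBR(d_in + d_skip, d_out, rng)
        self.mixers = [PointMixerBlock(S, d_out, rng) for _ in range(layers)]
        self.coord = MLP2(d_out, max(d_out // 2, 8), 3, rng)


class _HeadStack(Module):
    """Two LBR + dropout stages and a final linear layer."""

    def __init__(self, d_in: int, n_out: int, dropout: float, rng: np.random.Generator):
        self.lbr1 = LBR(d_in, max(d_in // 2, 16), rng)
        self.drop1 = Dropout(dropout)
        self.lbr2 = LBR(max(d_in // 2, 16), max(d_in // 4, 16), rng)
        self.drop2 = Dropout(dropout)
        self.out = Linear(max(d_in // 4, 16), n_out, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = self.drop1(self.lbr1(x), rng)
        x = self.drop2(self.lbr2(x), rng)
        return self.out(x)


class MixNet(Module):
    """Shared encoder with segmentation, instance, classification and
    completion branches.

    All weights are initialized from ``seed``; forward passes in eval mode
    are deterministic, and training-mode dropout draws its masks from an
    explicit RNG passed by the training loop.
    """

    def __init__(self, config: StageConfig = StageConfig(), seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config

        d_prev = 3
        self.encoder_stages = []
        for s in range(len(c.encoder_resolutions)):
            self.encoder_stages.append(
                _EncoderStage(d_prev, c.encoder_dims[s], c.encoder_resolutions[s],
                              c.mixer_layers_per_stage, rng)
            )
            d_prev = c.encoder_dims[s]

        # segmentation decoder: coarse -> fine over the encoder stages
        self.seg_stages = []
        enc_dims_rev = list(reversed(c.encoder_dims[:-1]))  # skip dims for stages 2..0
        d_run = c.encoder_dims[-1]
        for d_skip in enc_dims_rev:
            self.seg_stages.append(_FuseStage(d_run, d_skip, d_skip, rng))
            d_run = d_skip
        self.seg_head = _HeadStack(d_run + c.n_classes, c.n_parts, c.dropout, rng)
        self.inst_head_linear = Linear(d_run, c.instance_dim, rng)
        self.cls_head = _HeadStack(c.encoder_dims[-1], c.n_classes, c.dropout, rng)

        # completion decoder: progressive generation
        self.completion_stages = []
        d_run = c.encoder_dims[-1]
        for t, (res, dim) in enumerate(zip(c.decoder_resolutions, c.decoder_dims)):
            d_skip = c.encoder_dims[len(c.encoder_dims) - 1 - t]
            self.completion_stages.append(
                _DecoderStage(d_run, d_skip, dim, res, c.mixer_layers_per_stage, rng)
            )
            d_run = dim

    # -- encoder ------------------------------------------------------------

    def encode(self, points: np.ndarray) -> FeaturePyramid:
        """Run the four aggregation + mixer stages; returns every stage for
        skip fusion."""
        c = self.config
        if len(points) != c.input_resolution:
            raise ValueError(
                f"encoder expects {c.input_resolution} points, got {len(points)}"
            )
        pyramid = FeaturePyramid()
        pts = np.asarray(points, dtype=np.float64)
        feats = Tensor(pts)
        for s, stage in enumerate(self.encoder_stages):
            pts, feats = neighborhood_aggregate(
                pts, feats, c.encoder_resolutions[s], c.encoder_k[s], stage.lbr
            )
            for mixer in stage.mixers:
                feats = mixer(feats)
            pyramid.stages.append((pts, feats))
        return pyramid

    # -- heads --------------------------------------------------------------

    def global_feature(self, pyramid: FeaturePyramid) -> Tensor:
        """Channel-wise max-pool over the coarsest stage."""
        _, feats = pyramid.stages[-1]
        return max_axis(feats, axis=0)

    def classify(self, pyramid: FeaturePyramid, rng: np.random.Generator | None = None) -> Tensor:
        """Category scores (Nc,); the predicted label is the argmax."""
        g = self.global_feature(pyramid)
        return self.cls_head(g.reshape(1, -1), rng).reshape(-1)

    def per_point_features(self, pyramid: FeaturePyramid) -> Tensor:
        """Feature-propagation decoder: coarse-to-fine interpolation with skip
        fusion, ending at the full encoder resolution."""
        pts_run, feats_run = pyramid.stages[-1]
        for stage, (pts_skip, feats_skip) in zip(
            self.seg_stages, reversed(pyramid.stages[:-1])
        ):
            interp = upsample_interpolate(pts_run, feats_run, pts_skip)
            feats_run = stage.fuse(concat([interp, feats_skip], axis=-1))
            pts_run = pts_skip
        return feats_run

    def segment(
        self,
        per_point: Tensor,
        category: int = 0,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Per-point part scores (N, Ns) with the category one-hot appended."""
        c = self.config
        if not 0 <= category < c.n_classes:
            raise ValueError(f"category {category} out of range [0, {c.n_classes})")
        onehot = np.zeros((per_point.shape[0], c.n_classes))
        onehot[:, category] = 1.0
        x = concat([per_point, Tensor(onehot)], axis=-1)
        return self.seg_head(x, rng)

    def instance_embed(self, per_point: Tensor) -> Tensor:
        """Pointwise (kernel-size-1) projection to the 5-D embedding."""
        return leaky_relu(self.inst_head_linear(per_point), 0.01)

    # -- completion ---------------------------------------------------------

    def decode_completion(self, pyramid: FeaturePyramid) -> list[Tensor]:
        """Progressive stage outputs [Y1..Y4] at the decoder resolutions.

        Stage t interpolates the running features onto the encoder points of
        matching resolution, fuses the encoder skip features, mixes, and maps
        each point to 3-D coordinates; the predicted coordinates carry the
        features into the next stage.
        """
        c = self.config
        if pyramid.resolutions() != list(c.encoder_resolutions):
            raise ValueError(
                f"pyramid resolutions {pyramid.resolutions()} do not match config"
            )
        outputs: list[Tensor] = []
        pts_run, feats_run = pyramid.stages[-1]
        for t, stage in enumerate(self.completion_stages):
            enc_pts, enc_feats = pyramid.stages[len(pyramid.stages) - 1 - t]
            interp = upsample_interpolate(pts_run, feats_run, enc_pts)
            fused = stage.fuse(concat([interp, enc_feats], axis=-1))
            for mixer in stage.mixers:
                fused = mixer(fused)
            y = stage.coord(fused)
            outputs.append(y)
            pts_run, feats_run = y.data, fused
        return outputs
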
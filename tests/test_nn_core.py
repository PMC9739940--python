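"""Autodiff engine and network blocks: gradient checks against finite
differences, oracle equivalence for aggregation/interpolation, head
contracts, and mean-shift clustering."""

import numpy as np
import pytest

from mixseedling.cloud import LabeledCloud
from mixseedling.nn import autodiff as ad
from mixseedling.nn.autodiff import Tensor
from mixseedling.nn.layers import LBR, MLP2, Dropout, LayerNorm, Linear
from mixseedling.nn.model import (
    MixNet,
    PointMixerBlock,
    StageConfig,
    mean_shift_cluster,
    neighborhood_aggregate,
    upsample_interpolate,
)


def numeric_grad(f, xs, h=1e-6):
    """Central finite differences of sum(f(xs)) wrt each tensor in xs."""
    grads = []
    for x in xs:
        g = np.zeros_like(x.data)
        it = np.nditer(x.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = x.data[i]
            x.data[i] = orig + h
            fp = f(*xs).data.sum()
            x.data[i] = orig - h
            fm = f(*xs).data.sum()
            x.data[i] = orig
            g[i] = (fp - fm) / (2 * h)
        grads.append(g)
    return grads


class TestAutodiff:
    @pytest.mark.parametrize("name,f,shapes", [
        ("matmul_lrelu", lambda a, b: ad.sum_axis(ad.leaky_relu(a @ b)), [(3, 4), (4, 2)]),
        ("max_pool", lambda a: ad.sum_axis(ad.max_axis(a, axis=1)), [(3, 5)]),
        ("sqrt_chain", lambda a: ad.sum_axis(ad.sqrt(a * a + 1.0)), [(4,)]),
        ("gather", lambda a: ad.sum_axis(ad.take(a, np.array([[0, 1], [2, 0]])) * 2.0), [(3, 2)]),
        ("div_concat", lambda a, b: ad.sum_axis(ad.concat([a, b], axis=-1) / 2.0), [(2, 2), (2, 3)]),
        ("mean_keepdims", lambda a: ad.sum_axis(ad.mean_axis(a * a, axis=-1, keepdims=True) + a), [(3, 4)]),
    ])
    def test_gradients_match_finite_differences(self, rng, name, f, shapes):
        xs = [Tensor(rng.standard_normal(s), requires_grad=True) for s in shapes]
        f(*xs).backward()
        for x, num in zip(xs, numeric_grad(f, xs)):
            np.testing.assert_allclose(x.grad, num, atol=1e-5)

    def test_log_softmax_gradient(self, rng):
        w = Tensor(rng.standard_normal((3, 4)))
        f = lambda a: ad.sum_axis(ad.log_softmax(a) * w)
        x = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
        f(x).backward()
        np.testing.assert_allclose(x.grad, numeric_grad(f, [x])[0], atol=1e-5)

    def test_repeated_parent_accumulates(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        (x * x + x).backward()
        np.testing.assert_allclose(x.grad, [5.0])  # 2x + 1 at x=2

    def test_layernorm_gradient(self, rng):
        ln = LayerNorm(4)
        w = Tensor(rng.standard_normal((5, 4)))
        f = lambda x: ad.sum_axis(ln(x) * w)
        x = Tensor(rng.standard_normal((5, 4)), requires_grad=True)
        f(x).backward()
        np.testing.assert_allclose(x.grad, numeric_grad(f, [x])[0], atol=1e-5)

    def test_lbr_train_mode_gradient(self, rng):
        lbr = LBR(4, 6, np.random.default_rng(0))
        lbr.train(True)
        w = Tensor(rng.standard_normal((5, 6)))
        f = lambda x: ad.sum_axis(lbr(x) * w)
        x = Tensor(rng.standard_normal((5, 4)), requires_grad=True)
        f(x).backward()
        np.testing.assert_allclose(x.grad, numeric_grad(f, [x])[0], atol=1e-4)


class TestPointMixerBlock:
    def test_zero_weight_mlps_give_residual_identity(self, rng):
        block = PointMixerBlock(4, 6, np.random.default_rng(0))
        for mlp in (block.mlp_channel, block.mlp_group):
            for lin in (mlp.fc1, mlp.fc2):
                lin.weight.data[:] = 0.0
                lin.bias.data[:] = 0.0
        x = Tensor(rng.standard_normal((4, 6)))
        np.testing.assert_allclose(block(x).data, x.data)

    def test_two_by_two_hand_computation(self):
        block = PointMixerBlock(2, 2, np.random.default_rng(0))
        for mlp in (block.mlp_channel, block.mlp_group):
            mlp.fc1.weight.data[:] = np.eye(2)
            mlp.fc1.bias.data[:] = 0.0
            mlp.fc2.weight.data[:] = np.eye(2)
            mlp.fc2.bias.data[:] = 0.0
        x = np.array([[1.0, 3.0], [2.0, 0.0]])

        def lnorm(v):  # LayerNorm with unit gamma, zero beta
            mu, var = v.mean(-1, keepdims=True), v.var(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + 1e-5)

        def mlp_id(v):  # identity fc weights: fc2(lrelu(fc1 v)) = lrelu(v)
            return np.where(v > 0, v, 0.01 * v)

        fc = x + mlp_id(lnorm(x))
        fo = fc + mlp_id(lnorm(fc).T).T
        np.testing.assert_allclose(block(Tensor(x)).data, fo, atol=1e-12)

    @pytest.mark.parametrize("S,D", [(1, 8), (64, 128)])
    def test_shape_preserved(self, rng, S, D):
        block = PointMixerBlock(S, D, np.random.default_rng(1))
        assert block(Tensor(rng.standard_normal((S, D)))).shape == (S, D)


class TestNeighborhoodAggregate:
    def test_self_neighbor_identity_k1(self, rng):
        """k=1 with centers covering all points: F_i - F_ik = 0, so the output
        is exactly LBR(concat(0, F_i)) max-pooled over the single neighbor."""
        pts = rng.standard_normal((16, 3))
        feats = Tensor(rng.standard_normal((16, 4)))
        lbr = LBR(8, 6, np.random.default_rng(2))
        lbr.eval()
        out_pts, out = neighborhood_aggregate(pts, feats, 16, 1, lbr)
        order = [int(np.flatnonzero((pts == p).all(axis=1))[0]) for p in out_pts]
        direct = lbr(ad.concat([Tensor(np.zeros((16, 4))), ad.take(feats, np.array(order))], axis=-1))
        np.testing.assert_allclose(out.data, direct.data, atol=1e-12)

    def test_shape_contract(self, rng):
        pts = rng.standard_normal((8, 3))
        feats = Tensor(rng.standard_normal((8, 3)))
        lbr = LBR(6, 16, np.random.default_rng(3))
        lbr.eval()
        out_pts, out = neighborhood_aggregate(pts, feats, 4, 2, lbr)
        assert out_pts.shape == (4, 3) and out.shape == (4, 16)

    def test_matches_per_center_loop_oracle(self, rng):
        pts = rng.standard_normal((32, 3))
        feats = rng.standard_normal((32, 5))
        lbr = LBR(10, 7, np.random.default_rng(4))
        lbr.eval()
        out_pts, out = neighborhood_aggregate(pts, Tensor(feats), 8, 4, lbr)
        from scipy.spatial import cKDTree
        tree = cKDTree(pts)
        for row, center_pt in zip(out.data, out_pts):
            ci = int(np.flatnonzero((pts == center_pt).all(axis=1))[0])
            _, nbr = tree.query(pts[ci], k=4)
            rows = []
            for j in np.atleast_1d(nbr):
                rows.append(np.concatenate([feats[ci] - feats[j], feats[ci]]))
            expect = lbr(Tensor(np.array(rows))).data.max(axis=0)
            np.testing.assert_allclose(row, expect, atol=1e-5)

    def test_k_exceeding_cloud_errors(self, rng):
        pts = rng.standard_normal((4, 3))
        lbr = LBR(6, 4, np.random.default_rng(5))
        with pytest.raises(ValueError):
            neighborhood_aggregate(pts, Tensor(pts), 2, 10, lbr)


class TestUpsampleInterpolate:
    def test_coincident_points_copy_features(self, rng):
        lo = rng.standard_normal((10, 3))
        feats = rng.standard_normal((10, 4))
        out = upsample_interpolate(lo, Tensor(feats), lo[:6])
        np.testing.assert_allclose(out.data, feats[:6], atol=1e-6)

    def test_midpoint_averages_two_neighbors(self):
        lo = np.array([[0.0, 0, 0], [1.0, 0, 0], [100.0, 0, 0]])
        feats = np.array([[1.0, 0], [3.0, 0], [5.0, 0]])
        hi = np.array([[0.5, 0, 0]])
        out = upsample_interpolate(lo, Tensor(feats), hi)
        # far third neighbor has ~0.25% weight; midpoint is the two-point mean
        assert out.data[0, 0] == pytest.approx(2.0, abs=0.02)

    def test_matches_explicit_3nn_loop(self, rng):
        lo = rng.standard_normal((20, 3))
        feats = rng.standard_normal((20, 6))
        hi = rng.standard_normal((15, 3))
        out = upsample_interpolate(lo, Tensor(feats), hi)
        for i, q in enumerate(hi):
            d = np.linalg.norm(lo - q, axis=1)
            nbr = np.argsort(d)[:3]
            w = 1.0 / (d[nbr] + 1e-8)
            w /= w.sum()
            np.testing.assert_allclose(out.data[i], w @ feats[nbr], atol=1e-6)


@pytest.fixture(scope="module")
def model():
    return MixNet(StageConfig.desk_scale(), seed=0).eval()


@pytest.fixture(scope="module")
def pyramid(model):
    return model.encode(np.random.default_rng(0).standard_normal((256, 3)))


class TestHeads:

    def test_classify_deterministic_in_eval(self, model, pyramid):
        a = model.classify(pyramid).data
        b = model.classify(pyramid).data
        np.testing.assert_array_equal(a, b)
        assert a.shape == (1,)

    def test_dropout_mask_reproducible_with_seeded_rng(self, model, pyramid):
        model.train(True)
        try:
            a = model.classify(pyramid, np.random.default_rng(42)).data
            b = model.classify(pyramid, np.random.default_rng(42)).data
        finally:
            model.eval()
        np.testing.assert_array_equal(a, b)

    def test_segment_shape_and_category_sensitivity(self, rng):
        model = MixNet(StageConfig.desk_scale(n_classes=3), seed=1).eval()
        pyramid = model.encode(rng.standard_normal((256, 3)))
        pp = model.per_point_features(pyramid)
        s0 = model.segment(pp, 0)
        s1 = model.segment(pp, 1)
        assert s0.shape == (256, 2)
        assert not np.allclose(s0.data, s1.data)
        with pytest.raises(ValueError):
            model.segment(pp, 5)

    def test_instance_head_five_dims_and_equivariance(self, model, rng):
        feats = rng.standard_normal((30, 32))
        out = model.instance_embed(Tensor(feats)).data
        assert out.shape == (30, 5)
        perm = rng.permutation(30)
        out_p = model.instance_embed(Tensor(feats[perm])).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)
        # pointwise affine + LeakyReLU oracle
        w, b = model.inst_head_linear.weight.data, model.inst_head_linear.bias.data
        pre = feats @ w + b
        np.testing.assert_allclose(out, np.where(pre > 0, pre, 0.01 * pre), atol=1e-12)

    def test_dropout_requires_rng_in_train_mode(self):
        d = Dropout(0.5)
        d.train(True)
        with pytest.raises(ValueError):
            d(Tensor(np.zeros((2, 2))))


class TestMeanShift:
    def test_identical_points_one_cluster(self):
        emb = np.zeros((20, 5))
        labels = mean_shift_cluster(emb, bandwidth=0.2)
        assert set(labels) == {0}

    def test_two_separated_blobs(self, rng):
        sigma = 0.05
        a = rng.normal(0, sigma, (40, 5))
        b = rng.normal(0, sigma, (25, 5)) + 10 * sigma * np.sqrt(5)
        labels = mean_shift_cluster(np.vstack([a, b]), bandwidth=3 * sigma)
        assert set(labels) == {0, 1}
        # larger blob gets label 0; zero misassignments
        assert (labels[:40] == 0).all() and (labels[40:] == 1).all()

    def test_single_point(self):
        assert mean_shift_cluster(np.zeros((1, 5))).tolist() == [0]


class TestEncoderDecoderContracts:
    def test_desk_scale_shapes(self, rng):
        model = MixNet(StageConfig.desk_scale(), seed=0).eval()
        pyramid = model.encode(rng.standard_normal((256, 3)))
        cfg = model.config
        for (pts, feats), r, d in zip(pyramid.stages, cfg.encoder_resolutions, cfg.encoder_dims):
            assert pts.shape == (r, 3) and feats.shape == (r, d)
        outs = model.decode_completion(pyramid)
        assert [len(o.data) for o in outs] == list(cfg.decoder_resolutions)
        assert all(np.isfinite(o.data).all() for o in outs)

    def test_forward_deterministic_in_eval(self, rng):
        model = MixNet(StageConfig.desk_scale(), seed=0).eval()
        pts = rng.standard_normal((256, 3))
        a = model.decode_completion(model.encode(pts))[-1].data
        b = model.decode_completion(model.encode(pts))[-1].data
        np.testing.assert_array_equal(a, b)

    def test_wrong_input_size_errors(self, rng):
        model = MixNet(StageConfig.desk_scale(), seed=0)
        with pytest.raises(ValueError):
            model.encode(rng.standard_normal((100, 3)))
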
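"""Object-contextual-attention pipeline vs an independent loop oracle."""
import numpy as np
import pytest

from mtloca.backbone import PixelRepresentations
from mtloca.nn.tensor import Tensor
from mtloca.oca import OCAConfig, OCAModule, predict_mask


def identity_module(channels=6, seed=0):
    cfg = OCAConfig(identity_transforms=True)
    return OCAModule(channels, cfg, np.random.default_rng(seed))


def reps_from(arr):
    return PixelRepresentations(features=Tensor(np.asarray(arr, dtype=np.float64)))


def oracle_pipeline(x, soft_logits):
    """Brute-force loops: soft-region weights -> f -> w -> y (identity
    transforms, plain dot-product compatibility)."""
    c, h, w = x.shape
    k = soft_logits.shape[0]
    hw = h * w
    xf = x.reshape(c, hw)
    logits = soft_logits.reshape(k, hw)
    d = np.zeros((k, hw))
    for kk in range(k):
        e = np.exp(logits[kk] - logits[kk].max())
        d[kk] = e / e.sum()
    f = np.zeros((k, c))
    for kk in range(k):
        for i in range(hw):
            f[kk] += d[kk, i] * xf[:, i]
    wrel = np.zeros((hw, k))
    for i in range(hw):
        scores = np.array([xf[:, i] @ f[kk] for kk in range(k)])
        e = np.exp(scores - scores.max())
        wrel[i] = e / e.sum()
    y = np.zeros((c, hw))
    for i in range(hw):
        for kk in range(k):
            y[:, i] += wrel[i, kk] * f[kk]
    return d, f, wrel, y


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pipeline_matches_loops(self, seed):
        rng = np.random.default_rng(seed)
        c, h, w = 6, 8, 8
        mod = identity_module(channels=c, seed=seed)
        x = rng.normal(size=(1, c, h, w))
        reps = reps_from(x)
        d = mod.soft_regions(reps)
        f = mod.region_representations(reps, d)
        wrel = mod.pixel_region_relation(reps, f)
        ctx = mod.contextual_representation(wrel, f)
        soft_np = d.logits.data[0]
        d_o, f_o, w_o, y_o = oracle_pipeline(x[0], soft_np)
        np.testing.assert_allclose(d.weights.data[0], d_o, atol=1e-6)
        np.testing.assert_allclose(f.f.data[0], f_o, atol=1e-6)
        np.testing.assert_allclose(wrel.w.data[0], w_o, atol=1e-6)
        np.testing.assert_allclose(ctx.data[0], y_o, atol=1e-6)


class TestSoftRegions:
    def test_uniform_weights_for_constant_logits(self):
        mod = identity_module(channels=4)
        # zero features -> zero conv output -> constant logits
        reps = reps_from(np.zeros((1, 4, 5, 5)))
        d = mod.soft_regions(reps)
        np.testing.assert_allclose(d.weights.data, 1.0 / 25, atol=1e-12)

    def test_weights_sum_to_one_per_region(self):
        mod = identity_module(channels=4, seed=3)
        reps = reps_from(np.random.default_rng(1).normal(size=(2, 4, 6, 6)))
        d = mod.soft_regions(reps)
        np.testing.assert_allclose(d.weights.data.sum(axis=2), 1.0, atol=1e-6)

    def test_mass_norm_weights_are_region_averages(self):
        cfg = OCAConfig(identity_transforms=True, region_weight_norm="mass")
        mod = OCAModule(4, cfg, np.random.default_rng(2))
        reps = reps_from(np.random.default_rng(5).normal(size=(1, 4, 6, 6)))
        d = mod.soft_regions(reps)
        # unit mass per region, and every weight positive
        np.testing.assert_allclose(d.weights.data.sum(axis=2), 1.0, atol=1e-6)
        assert (d.weights.data > 0).all()
        # f_k lies inside the convex hull of pixel features -> bounded by
        # per-channel min/max
        f = mod.region_representations(reps, d)
        feats = reps.features.data[0].reshape(4, -1)
        assert (f.f.data[0] <= feats.max(axis=1) + 1e-9).all()
        assert (f.f.data[0] >= feats.min(axis=1) - 1e-9).all()

    def test_spatial_alignment(self):
        mod = identity_module(channels=4)
        reps = reps_from(np.random.default_rng(0).normal(size=(1, 4, 7, 9)))
        d = mod.soft_regions(reps)
        assert d.logits.shape == (1, 2, 7, 9)


class TestRegionRepresentations:
    def test_one_hot_weights_give_plain_sums(self):
        from mtloca.oca import SoftObjectRegions
        mod = identity_module(channels=3)
        x = np.random.default_rng(0).normal(size=(1, 3, 2, 2))
        reps = reps_from(x)
        onehot = np.zeros((1, 2, 4))
        onehot[0, 0, :2] = 1.0   # region 0 owns pixels 0,1
        onehot[0, 1, 2:] = 1.0   # region 1 owns pixels 2,3
        d = SoftObjectRegions(logits=Tensor(np.zeros((1, 2, 2, 2))),
                              weights=Tensor(onehot))
        f = mod.region_representations(reps, d)
        xf = x.reshape(3, 4)
        np.testing.assert_allclose(f.f.data[0, 0], xf[:, :2].sum(axis=1), atol=1e-12)
        np.testing.assert_allclose(f.f.data[0, 1], xf[:, 2:].sum(axis=1), atol=1e-12)

    def test_two_pixel_hand_example(self):
        from mtloca.oca import SoftObjectRegions
        mod = identity_module(channels=2)
        x = np.array([[1.0, 0.0], [0.0, 1.0]]).reshape(1, 2, 1, 2)
        d = SoftObjectRegions(logits=Tensor(np.zeros((1, 2, 1, 2))),
                              weights=Tensor(np.array([[[0.5, 0.5], [0.5, 0.5]]])))
        f = mod.region_representations(reps_from(x), d)
        np.testing.assert_allclose(f.f.data[0, 0], [0.5, 0.5], atol=1e-12)

    def test_shape_mismatch_raises(self):
        from mtloca.oca import SoftObjectRegions
        mod = identity_module(channels=3)
        d = SoftObjectRegions(logits=Tensor(np.zeros((1, 2, 3, 3))),
                              weights=Tensor(np.zeros((1, 2, 9))))
        with pytest.raises(ValueError, match="do not match"):
            mod.region_representations(reps_from(np.zeros((1, 3, 4, 4))), d)


class TestPixelRegionRelation:
    def test_rows_sum_to_one(self):
        mod = identity_module(channels=5, seed=2)
        reps = reps_from(np.random.default_rng(4).normal(size=(2, 5, 6, 6)))
        d = mod.soft_regions(reps)
        f = mod.region_representations(reps, d)
        w = mod.pixel_region_relation(reps, f)
        np.testing.assert_allclose(w.w.data.sum(axis=2), 1.0, atol=1e-6)
        assert (w.w.data > 0).all() and (w.w.data < 1).all()

    def test_equal_scores_give_half_half(self):
        mod = identity_module(channels=3)
        # identical pixels -> identical region representations -> equal scores
        reps = reps_from(np.full((1, 3, 4, 4), 0.7))
        d = mod.soft_regions(reps)
        f = mod.region_representations(reps, d)
        w = mod.pixel_region_relation(reps, f)
        np.testing.assert_allclose(w.w.data, 0.5, atol=1e-9)

    def test_nonfinite_scores_raise(self):
        mod = identity_module(channels=3)
        reps = reps_from(np.full((1, 3, 2, 2), 1e300))
        d = mod.soft_regions(reps)
        from mtloca.oca import ObjectRegionRepresentations
        f = ObjectRegionRepresentations(f=Tensor(np.full((1, 2, 3), 1e300)))
        with np.errstate(over="ignore"), \
                pytest.raises(FloatingPointError, match="non-finite"):
            mod.pixel_region_relation(reps, f)


class TestContextualRepresentation:
    def test_identical_relation_rows_give_identical_context(self):
        mod = identity_module(channels=4, seed=1)
        x = np.random.default_rng(2).normal(size=(1, 4, 2, 2))
        x[0, :, 1, 1] = x[0, :, 0, 0]  # duplicate one pixel
        reps = reps_from(x)
        d = mod.soft_regions(reps)
        f = mod.region_representations(reps, d)
        w = mod.pixel_region_relation(reps, f)
        ctx = mod.contextual_representation(w, f).data[0]  # (C, HW)
        np.testing.assert_allclose(ctx[:, 0], ctx[:, 3], atol=1e-12)

    def test_one_hot_relation_returns_region_vector(self):
        from mtloca.oca import ObjectRegionRepresentations, PixelRegionRelation
        mod = identity_module(channels=3)
        f = ObjectRegionRepresentations(
            f=Tensor(np.array([[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]])))
        w = PixelRegionRelation(w=Tensor(np.array([[[1.0, 0.0], [0.0, 1.0]]])))
        ctx = mod.contextual_representation(w, f).data[0]
        np.testing.assert_allclose(ctx[:, 0], [1.0, 2.0, 3.0], atol=1e-12)
        np.testing.assert_allclose(ctx[:, 1], [4.0, 5.0, 6.0], atol=1e-12)


class TestAugmentedSegmentation:
    def test_concat_channel_count(self):
        mod = identity_module(channels=4, seed=5)
        reps = reps_from(np.random.default_rng(0).normal(size=(1, 4, 4, 4)))
        d, f, w, aug = mod(reps)
        assert aug.features.shape[1] == 4 + mod.context_channels
        assert aug.seg_logits.shape == (1, 2, 4, 4)

    def test_argmax_and_tie_break(self):
        logits = np.zeros((1, 2, 2, 2))
        logits[0, 0, 0, 0], logits[0, 1, 0, 0] = 2.0, -1.0   # clear class 0
        logits[0, 1, 0, 1] = 3.0                             # clear class 1
        # (1,0) and (1,1) tied at zero -> background
        masks = predict_mask(logits)
        assert masks[0, 0, 0] == 0
        assert masks[0, 0, 1] == 1
        assert masks[0, 1, 0] == 0 and masks[0, 1, 1] == 0

    def test_region_permutation_equivariance(self):
        """Swapping the two region channels in the learned projections must
        swap d/f and the relation columns and the final logits."""
        mod = identity_module(channels=4, seed=7)
        x = np.random.default_rng(3).normal(size=(1, 4, 5, 5))
        reps = reps_from(x)
        d1, f1, w1, aug1 = mod(reps)
        # permute region index in both region-indexed parameter blocks
        mod.soft_conv.weight.data = mod.soft_conv.weight.data[::-1].copy()
        mod.soft_conv.bias.data = mod.soft_conv.bias.data[::-1].copy()
        mod.aug_conv.weight.data = mod.aug_conv.weight.data[::-1].copy()
        mod.aug_conv.bias.data = mod.aug_conv.bias.data[::-1].copy()
        d2, f2, w2, aug2 = mod(reps)
        np.testing.assert_allclose(d2.weights.data, d1.weights.data[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(f2.f.data, f1.f.data[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(w2.w.data, w1.w.data[:, :, ::-1], atol=1e-12)
        np.testing.assert_allclose(aug2.seg_logits.data,
                                   aug1.seg_logits.data[:, ::-1], atol=1e-10)


class TestConfig:
    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="two object regions"):
            OCAConfig(num_regions=1)

    def test_bad_norm_rejected(self):
        with pytest.raises(ValueError, match="region_weight_norm"):
            OCAConfig(region_weight_norm="rows")

    def test_general_k(self):
        cfg = OCAConfig(num_regions=3, identity_transforms=True)
        mod = OCAModule(4, cfg, np.random.default_rng(0))
        reps = reps_from(np.random.default_rng(1).normal(size=(1, 4, 4, 4)))
        d, f, w, aug = mod(reps)
        assert f.f.shape == (1, 3, 4)
        np.testing.assert_allclose(w.w.data.sum(axis=2), 1.0, atol=1e-6)
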
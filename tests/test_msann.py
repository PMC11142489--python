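"""Attention branch: CAM/SAM/block arithmetic against hand-unrolled
scalar oracles, structural contracts, and a training smoke run."""

import math

import numpy as np
import pytest

from gliopipe.msann import (
    ChannelAttention3d,
    MsaBlock,
    MsaBlockConfig,
    MsannConfig,
    SpatialAttention3d,
    build_msann,
    channel_attention,
    msa_block,
    spatial_attention,
    train_msann,
)
from gliopipe.nn import Tensor


def sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def conv3d_oracle(x, w, b, pad):
    """Plain-loop 3D cross-correlation, stride 1."""
    C, D, H, W = x.shape
    O, _, k, _, _ = w.shape
    out = np.zeros((O, D, H, W))
    for o in range(O):
        for z in range(D):
            for yy in range(H):
                for xx in range(W):
                    acc = b[o]
                    for c in range(C):
                        for kz in range(k):
                            for ky in range(k):
                                for kx in range(k):
                                    z2, y2, x2 = z + kz - pad, yy + ky - pad, xx + kx - pad
                                    if 0 <= z2 < D and 0 <= y2 < H and 0 <= x2 < W:
                                        acc += x[c, z2, y2, x2] * w[o, c, kz, ky, kx]
                    out[o, z, yy, xx] = acc
    return out


@pytest.fixture()
def pinned_cam():
    cam = ChannelAttention3d(channels=2, reduction=2)
    cam.fc1.weight.data = np.array([[0.5], [-0.3]])
    cam.fc1.bias.data = np.array([0.1])
    cam.fc2.weight.data = np.array([[0.7, -0.2]])
    cam.fc2.bias.data = np.array([0.05, -0.1])
    return cam


class TestChannelAttention:
    def test_matches_scalar_recomputation(self, pinned_cam, rng):
        x = rng.standard_normal((1, 2, 2, 2, 2))
        got = channel_attention(x, pinned_cam)

        def mlp(v):
            h = max(0.0, v[0] * 0.5 + v[1] * (-0.3) + 0.1)
            return np.array([h * 0.7 + 0.05, h * (-0.2) - 0.1])

        mx = x[0].reshape(2, -1).max(axis=1)
        av = x[0].reshape(2, -1).mean(axis=1)
        expected = np.array([sigmoid(v) for v in mlp(mx) + mlp(av)])
        np.testing.assert_allclose(got[0], expected, rtol=1e-12)

    def test_identical_channels_tied_parameters_give_equal_weights(self, rng):
        cam = ChannelAttention3d(channels=2, reduction=2)
        cam.fc1.weight.data = np.array([[0.4], [0.4]])  # exchange-symmetric
        cam.fc1.bias.data = np.array([0.2])
        cam.fc2.weight.data = np.array([[0.6, 0.6]])
        cam.fc2.bias.data = np.array([0.1, 0.1])
        chan = rng.standard_normal((1, 1, 2, 2, 2))
        x = np.concatenate([chan, chan], axis=1)
        w = channel_attention(x, cam)
        assert w[0, 0] == pytest.approx(w[0, 1], rel=1e-14)

    def test_weights_in_open_unit_interval(self, rng):
        cam = ChannelAttention3d(channels=4, reduction=2, rng=rng)
        w = channel_attention(rng.standard_normal((3, 4, 3, 3, 3)) * 10, cam)
        assert np.all((w > 0) & (w < 1))


class TestSpatialAttention:
    def test_matches_scalar_recomputation(self, rng):
        sam = SpatialAttention3d(kernel=3, rng=rng)
        x = rng.standard_normal((1, 3, 2, 2, 2))
        got = spatial_attention(x, sam)
        desc = np.stack([x[0].max(axis=0), x[0].mean(axis=0)])
        pre = conv3d_oracle(desc, sam.conv.weight.data, sam.conv.bias.data, pad=1)
        expected = 1.0 / (1.0 + np.exp(-pre))
        np.testing.assert_allclose(got[0], expected, rtol=1e-10)

    def test_constant_input_constant_weights(self, rng):
        # kernel 1 keeps exact translation symmetry (no boundary padding)
        sam = SpatialAttention3d(kernel=1, rng=rng)
        x = np.full((1, 2, 3, 3, 3), 1.7)
        w = spatial_attention(x, sam)
        assert np.ptp(w) == 0.0

    def test_output_shape_and_range(self, rng):
        sam = SpatialAttention3d(rng=rng)
        x = rng.standard_normal((2, 5, 4, 4, 4))
        w = spatial_attention(x, sam)
        assert w.shape == (2, 1, 4, 4, 4)
        assert np.all((w > 0) & (w < 1))


class TestMsaBlock:
    def test_output_channel_doubling(self, rng):
        block = MsaBlock(MsaBlockConfig(3, 8, reduction=2, stride=2), rng=rng)
        out = msa_block(rng.standard_normal((1, 3, 8, 8, 8)), block)
        assert out.shape == (1, 16, 4, 4, 4)
        assert block.out_channels == 16

    def test_identity_attention_duplicates_conv(self, rng):
        block = MsaBlock(MsaBlockConfig(2, 4, reduction=2, stride=1), rng=rng)
        x = rng.standard_normal((1, 2, 4, 4, 4))
        out = msa_block(x, block, identity_attention=True)
        conv = block.conv(Tensor(x)).relu().data
        np.testing.assert_array_equal(out[:, :4], conv)
        np.testing.assert_array_equal(out[:, 4:], conv)

    def test_without_attention_halves_channels(self, rng):
        block = MsaBlock(MsaBlockConfig(2, 4, stride=1), rng=rng, use_attention=False)
        out = msa_block(rng.standard_normal((1, 2, 4, 4, 4)), block)
        assert out.shape[1] == 4 and block.out_channels == 4

    def test_full_block_matches_unrolled_oracle(self, rng):
        """F = Conv(x) || [CAM-weighted Conv (*) SAM weights], all
        recomputed with plain loops and scalar arithmetic."""
        block = MsaBlock(MsaBlockConfig(1, 2, reduction=2, stride=1), rng=rng)
        x = rng.standard_normal((1, 1, 2, 2, 2))
        got = msa_block(x, block)

        y = conv3d_oracle(x[0], block.conv.weight.data, block.conv.bias.data, pad=1)
        y = np.maximum(y, 0)  # trunk activation
        # channel weights
        w1, b1 = block.cam.fc1.weight.data, block.cam.fc1.bias.data
        w2, b2 = block.cam.fc2.weight.data, block.cam.fc2.bias.data

        def mlp(v):
            h = np.maximum(v @ w1 + b1, 0)
            return h @ w2 + b2

        mx = y.reshape(2, -1).max(axis=1)
        av = y.reshape(2, -1).mean(axis=1)
        cw = 1.0 / (1.0 + np.exp(-(mlp(mx) + mlp(av))))
        yc = y * cw[:, None, None, None]
        desc = np.stack([yc.max(axis=0), yc.mean(axis=0)])
        sw = 1.0 / (1.0 + np.exp(-conv3d_oracle(desc, block.sam.conv.weight.data, block.sam.conv.bias.data, pad=1)))
        expected = np.concatenate([y, yc * sw[0]], axis=0)
        np.testing.assert_allclose(got[0], expected, rtol=1e-9)

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError, match="divide"):
            MsaBlockConfig(3, 6, reduction=4)


class TestTrainMsann:
    def test_smoke_train_scores_and_determinism(self, cohort_small):
        cohort = cohort_small[:4] + cohort_small[10:14]
        cfg = MsannConfig(pool_in=2, epochs=6, seed=0, test_fraction=0.25)
        a = train_msann(cohort, cfg)
        assert all(0.0 <= s <= 1.0 for s in a.scores.values())
        assert a.losses[-1] < a.losses[0]
        b = train_msann(cohort, cfg)
        assert a.scores == b.scores

    def test_unlabeled_study_rejected(self, cohort_small):
        bad = cohort_small[0].study
        bad = type(bad)(bad.study_id, bad.sequences, labels=bad.labels, grade=None)
        with pytest.raises(ValueError, match="unlabeled"):
            train_msann([bad] + [c.study for c in cohort_small[1:4]], MsannConfig(epochs=1))

    def test_ablation_halves_trunk_width(self):
        full = build_msann(MsannConfig(channels=(4, 8), seed=0))
        thin = build_msann(MsannConfig(channels=(4, 8), use_attention=False, seed=0))
        assert full.blocks[-1].out_channels == 2 * thin.blocks[-1].out_channels
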
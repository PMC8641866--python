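"""Architecture contracts: pyramid, residual encoder, RCAM, decoder, RSAM."""

import numpy as np
import pytest

from rfarn import nn
from rfarn.model import (
    RCAM,
    RFARN,
    RSAM,
    DecoderBlock,
    NetworkConfig,
    ResidualEncoderBlock,
    build_side_pyramid,
    channel_affinity,
    reverse_weight,
    rfarn_forward,
)
from rfarn.nn import Tensor
from rfarn.train import bce_loss


class TestSidePyramid:
    def test_sizes(self, reduced_net):
        patch = np.zeros((48, 48))
        levels = build_side_pyramid(patch, reduced_net)
        assert [l.shape[0] for l in levels] == [48, 24, 12, 6]

    def test_constant_preserved(self, reduced_net):
        levels = build_side_pyramid(np.full((48, 48), 3.25), reduced_net)
        for l in levels:
            assert np.allclose(l, 3.25)

    def test_checkerboard_averages_to_half(self, reduced_net):
        # every 2x2 cell holds two 0s and two 1s, so cell means are 0.5
        board = np.indices((48, 48)).sum(axis=0) % 2
        levels = build_side_pyramid(board, reduced_net)
        assert np.allclose(levels[1], 0.5)

    def test_size_mismatch_rejected(self, reduced_net):
        with pytest.raises(ValueError):
            build_side_pyramid(np.zeros((32, 32)), reduced_net)


class TestReverseWeight:
    def test_zero_logit_gives_half(self):
        assert reverse_weight(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_complement_identity(self, rng):
        phi = rng.standard_normal((1, 5, 5)) * 10
        s = 1.0 / (1.0 + np.exp(-phi))
        assert np.allclose(reverse_weight(phi) + s, 1.0, atol=1e-12)

    def test_saturation_suppresses_confident_regions(self):
        assert reverse_weight(np.array([20.0]))[0] < 1e-8
        out = reverse_weight(np.array([-30.0, 30.0]))
        assert (out > 0).all() and (out < 1).all()


class TestChannelAffinity:
    def test_zeros_give_uniform(self):
        m = channel_affinity(np.zeros(4), np.zeros(4))
        assert np.allclose(m, 0.25)

    def test_columns_sum_to_one(self, rng):
        m = channel_affinity(rng.standard_normal(6), rng.standard_normal(6))
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-6)

    def test_two_channel_hand_softmax(self):
        m = channel_affinity(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        e = np.exp(1.0)
        assert m[0, 0] == pytest.approx(e / (e + 1), abs=1e-4)   # 0.7311
        assert m[1, 0] == pytest.approx(1 / (e + 1), abs=1e-4)   # 0.2689

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            channel_affinity(np.zeros(3), np.zeros(4))


class TestResidualEncoderBlock:
    def test_shapes(self, rng):
        block = ResidualEncoderBlock(3, 8, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, 3, 12, 12)).astype(np.float32))
        features, pooled = block(x)
        assert features.shape == (2, 8, 12, 12)
        assert pooled.shape == (2, 8, 6, 6)

    def test_zero_convs_identity_shortcut(self, rng):
        block = ResidualEncoderBlock(4, 4, np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0
            conv.bias.data[...] = 0
        assert block.project is None
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        features, _ = block(x)
        assert np.allclose(features.data, x.data, atol=1e-6)


class TestRCAM:
    def test_output_shape(self, rng):
        rcam = RCAM(8, 4, np.random.default_rng(0))
        deep = Tensor(rng.standard_normal((2, 8, 3, 3)).astype(np.float32))
        shallow = Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
        out = rcam(deep, shallow)
        assert out.shape == shallow.shape
        assert np.isfinite(out.data).all()

    def test_zero_logits_halve_the_shallow_features(self, rng):
        rcam = RCAM(8, 4, np.random.default_rng(0))
        rcam.squeeze.weight.data[...] = 0
        rcam.squeeze.bias.data[...] = 0
        rcam.up.weight.data[...] = 0
        rcam.up.bias.data[...] = 0
        deep = Tensor(rng.standard_normal((1, 8, 3, 3)).astype(np.float32))
        shallow = Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32))
        _, state = rcam(deep, shallow, return_state=True)
        assert np.allclose(state["reverse_weights"], 0.5)
        assert np.allclose(state["edge_features"], 0.5 * shallow.data, atol=1e-7)

    def test_matches_manual_scalar_trace(self, rng):
        """Step-by-step scalar trace of the reverse-channel-attention
        pipeline at C=2 with hand-set weights."""
        rcam = RCAM(2, 2, np.random.default_rng(0))
        wsq = np.array([0.7, -0.3])
        wup = np.array([[0.5, -0.2], [0.1, 0.4]])
        rho = np.array([1.5, 0.8])
        rcam.squeeze.weight.data = wsq.reshape(1, 2, 1, 1).astype(np.float64)
        rcam.squeeze.bias.data = np.array([0.1])
        rcam.up.weight.data = wup.reshape(1, 1, 2, 2).astype(np.float64)
        rcam.up.bias.data = np.array([-0.05])
        rcam.rho.data = rho.astype(np.float64)

        deep = rng.standard_normal((1, 2, 1, 1))
        shallow = rng.standard_normal((1, 2, 2, 2))
        out = rcam(Tensor(deep), Tensor(shallow))

        # independent trace with plain scalar numpy
        logit = float((wsq * deep[0, :, 0, 0]).sum() + 0.1)
        up = logit * wup - 0.05                       # (2,2) map
        rw = 1.0 - 1.0 / (1.0 + np.exp(-up))
        bhat = rw[None] * shallow[0]                  # (2,2,2)
        avg = bhat.mean(axis=(1, 2))
        mx = bhat.max(axis=(1, 2))
        outer = np.outer(avg, mx)
        e = np.exp(outer - outer.max(axis=0, keepdims=True))
        cb = e / e.sum(axis=0, keepdims=True)
        ab = (1.0 / (1.0 + np.exp(-cb))) * rho[None, :]
        mixed = np.einsum("ij,ihw->jhw", ab, bhat)
        want = mixed + shallow[0]
        assert np.allclose(out.data[0], want, atol=1e-10)

    def test_scale_mismatch_rejected(self, rng):
        rcam = RCAM(8, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            rcam(Tensor(np.zeros((1, 8, 3, 3), dtype=np.float32)),
                 Tensor(np.zeros((1, 4, 7, 7), dtype=np.float32)))


class TestDecoderBlock:
    def test_output_doubles_and_is_nonnegative(self, rng):
        dec = DecoderBlock(8, 4, 4, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
        skip = Tensor(rng.standard_normal((2, 4, 12, 12)).astype(np.float32))
        out = dec(x, skip)
        assert out.shape == (2, 4, 12, 12)
        assert (out.data >= 0).all()

    def test_concatenation_arithmetic(self):
        dec = DecoderBlock(8, 5, 4, np.random.default_rng(0))
        # first conv consumes deconv channels + skip channels
        assert dec.conv1.weight.shape[1] == 4 + 5

    def test_size_mismatch_rejected(self, rng):
        dec = DecoderBlock(8, 4, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            dec(Tensor(np.zeros((1, 8, 6, 6), dtype=np.float32)),
                Tensor(np.zeros((1, 4, 11, 11), dtype=np.float32)))


class TestRSAM:
    def test_output_shape_and_affinity_normalization(self, rng):
        rsam = RSAM(8, 4, np.random.default_rng(0))
        enc = Tensor(rng.standard_normal((2, 8, 3, 3)).astype(np.float32))
        dec = Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
        out, state = rsam(enc, dec, return_state=True)
        assert out.shape == dec.shape
        sums = state["spatial_affinity"].sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_zero_weights_give_half_mask(self, rng):
        rsam = RSAM(8, 4, np.random.default_rng(0))
        for conv in (rsam.squeeze, rsam.up, rsam.mask_conv):
            conv.weight.data[...] = 0
            conv.bias.data[...] = 0
        enc = Tensor(rng.standard_normal((1, 8, 3, 3)).astype(np.float32))
        dec = Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32))
        _, state = rsam(enc, dec, return_state=True)
        assert np.allclose(state["mask"], 0.5)


class TestFullNetwork:
    def test_forward_contract(self, reduced_net, rng):
        x = rng.random((2, 48, 48)).astype(np.float32)
        out = rfarn_forward(x, reduced_net)
        assert out.shape == (2, 48, 48)
        assert (out > 0).all() and (out < 1).all()

    def test_wrong_patch_size_rejected(self, reduced_net):
        with pytest.raises(ValueError):
            rfarn_forward(np.zeros((1, 32, 32), dtype=np.float32), reduced_net)

    def test_inference_is_deterministic(self, reduced_net, rng):
        model = RFARN(reduced_net)
        x = rng.random((2, 48, 48)).astype(np.float32)
        a = rfarn_forward(x, model=model)
        b = rfarn_forward(x, model=model)
        assert np.array_equal(a, b)

    def test_seeded_init_is_reproducible(self, reduced_net):
        a = RFARN(reduced_net).state_dict()
        b = RFARN(reduced_net).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_every_parameter_receives_gradient(self, rng):
        cfg = NetworkConfig(base_channels=4, seed=2)
        model = RFARN(cfg)
        x = rng.random((2, 48, 48)).astype(np.float32)
        y = (rng.random((2, 1, 48, 48)) > 0.8).astype(np.float32)
        loss = bce_loss(model(x), y)
        loss.backward()
        for name, p in model.named_parameters().items():
            assert p.grad is not None, f"{name} got no gradient"
            assert np.linalg.norm(p.grad) > 0, f"{name} gradient is zero"
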
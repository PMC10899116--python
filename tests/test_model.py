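"""Architecture contracts: shapes, parameter budget, ablations, and the
attention / pyramid-pooling operators against straight-line oracles."""

import numpy as np
import pytest
from scipy import signal

from anorak import nn
from anorak.config import NetworkConfig
from anorak.model import (build_network, count_parameters,
                          first_order_attention, make_stream_inputs,
                          predict_patch, second_order_attention)
from anorak.nn import functional as F


TINY = NetworkConfig(width_multiplier=0.25)


# ---------------------------------------------------------------------------
# stream inputs
# ---------------------------------------------------------------------------

class TestStreamInputs:
    def test_shapes_for_768_patch(self):
        patch = np.zeros((768, 768, 3), np.uint8)
        fine, inter, coarse = make_stream_inputs(patch)
        assert fine.shape[:2] == (384, 384)
        assert inter.shape[:2] == (192, 192)
        assert coarse.shape[:2] == (96, 96)

    def test_constant_patch_gives_constant_rasters(self):
        patch = np.full((64, 64, 3), 123, np.uint8)
        for raster in make_stream_inputs(patch):
            np.testing.assert_allclose(raster, 123.0)

    def test_checkerboard_fine_raster_is_block_mean(self, rng):
        patch = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        fine = make_stream_inputs(patch)[0]
        # independent brute-force 2x2 block averaging
        ref = np.zeros((32, 32, 3))
        for i in range(32):
            for j in range(32):
                ref[i, j] = patch[2 * i:2 * i + 2, 2 * j:2 * j + 2].mean(axis=(0, 1))
        np.testing.assert_allclose(fine, ref)

    def test_rejects_size_not_divisible_by_8(self):
        with pytest.raises(ValueError):
            make_stream_inputs(np.zeros((68, 68, 3)))


# ---------------------------------------------------------------------------
# parameter counting and ablation wiring
# ---------------------------------------------------------------------------

class TestParameters:
    def test_single_1x1_conv_has_28_parameters(self):
        conv = nn.Conv2d(3, 7, 1, bias=True)
        assert sum(p.data.size for p in conv.parameters()) == 28

    def test_reference_configuration_is_4_10_million(self):
        net = build_network(NetworkConfig())
        n = count_parameters(net)
        assert abs(n - 4.10e6) <= 0.005e6
        assert round(n / 1e6, 2) == 4.10

    def test_count_increases_with_width(self):
        n1 = count_parameters(build_network(NetworkConfig(width_multiplier=0.25)))
        n2 = count_parameters(build_network(NetworkConfig(width_multiplier=0.5)))
        assert n2 > n1

    def test_single_stream_has_no_attention_parameters(self):
        net = build_network(NetworkConfig(n_streams=1, fusion="add",
                                          width_multiplier=0.25))
        names = [k for k, _ in net.named_parameters()]
        assert not any(k.startswith(("fo_", "so.")) for k in names)

    def test_toggles_change_only_their_own_submodules(self):
        base = dict(build_network(NetworkConfig(fusion="add", width_multiplier=0.25),
                                  seed=0).named_parameters())
        fo = dict(build_network(NetworkConfig(fusion="fo", width_multiplier=0.25),
                                seed=0).named_parameters())
        so = dict(build_network(NetworkConfig(fusion="so", width_multiplier=0.25),
                                seed=0).named_parameters())
        extra_fo = set(fo) - set(base)
        extra_so = set(so) - set(base)
        assert extra_fo and all(k.startswith("fo_") for k in extra_fo)
        assert extra_so and all(k.startswith("so.") for k in extra_so)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_streams=2)
        with pytest.raises(ValueError):
            NetworkConfig(fusion="concat")
        with pytest.raises(ValueError):
            NetworkConfig(ppm_bins=())


# ---------------------------------------------------------------------------
# forward contracts
# ---------------------------------------------------------------------------

class TestForward:
    def test_probmap_shape_simplex_and_argmax_on_768(self):
        net = build_network(TINY, seed=0)
        patch = np.random.default_rng(0).integers(0, 256, (768, 768, 3)).astype(np.uint8)
        probs, labels = predict_patch(net, patch)
        assert probs.shape == (768, 768, 7)
        assert labels.shape == (768, 768)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-5)
        assert probs.min() >= 0
        np.testing.assert_array_equal(labels, probs.argmax(axis=2))

    def test_simplex_across_configurations(self, rng):
        patch = rng.integers(0, 256, (128, 128, 3)).astype(np.uint8)
        for fusion in ("add", "fo", "so", "fo+so"):
            net = build_network(NetworkConfig(fusion=fusion, width_multiplier=0.25))
            probs, _ = predict_patch(net, patch)
            np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-5)

    def test_add_fusion_never_invokes_attention(self, rng):
        net = build_network(NetworkConfig(fusion="add", width_multiplier=0.25))
        patch = rng.integers(0, 256, (128, 128, 3)).astype(np.uint8)
        predict_patch(net, patch)
        assert net.op_calls["fo"] == 0
        assert net.op_calls["so"] == 0
        assert net.op_calls["ppm"] == 1

    def test_rejects_patch_not_divisible_by_64(self):
        net = build_network(TINY)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 96, 96, 3), np.uint8))


# ---------------------------------------------------------------------------
# first-order attention
# ---------------------------------------------------------------------------

class TestFirstOrderAttention:
    def test_zero_preactivation_halves_fine_features(self, rng):
        fine = nn.Tensor(rng.normal(size=(1, 8, 4, 4)))
        coarse = nn.Tensor(rng.normal(size=(1, 8, 2, 2)))
        w1 = np.zeros((8, 2)); b1 = np.zeros(2)
        w2 = np.zeros((2, 8)); b2 = np.zeros(8)
        out = first_order_attention(coarse, fine, w1, b1, w2, b2)
        np.testing.assert_allclose(out.numpy(), 0.5 * fine.numpy(), rtol=1e-6)

    def test_saturated_gate_approaches_identity(self, rng):
        fine = nn.Tensor(rng.normal(size=(1, 4, 4, 4)))
        coarse = nn.Tensor(np.ones((1, 4, 2, 2)))
        w1 = np.ones((4, 2)); b1 = np.zeros(2)
        w2 = np.ones((2, 4)) * 50.0; b2 = np.full(4, 50.0)
        out = first_order_attention(coarse, fine, w1, b1, w2, b2)
        np.testing.assert_allclose(out.numpy(), fine.numpy(), rtol=1e-5)

    def test_matches_straight_line_recomputation(self, rng):
        c, cf = 6, 8
        coarse = rng.normal(size=(2, c, 4, 4))
        fine = rng.normal(size=(2, cf, 4, 4))
        w1 = rng.normal(size=(c, 3)); b1 = rng.normal(size=3)
        w2 = rng.normal(size=(3, cf)); b2 = rng.normal(size=cf)
        out = first_order_attention(nn.Tensor(coarse), nn.Tensor(fine),
                                    w1, b1, w2, b2).numpy()
        z = coarse.mean(axis=(2, 3))
        h = np.maximum(z @ w1 + b1, 0.0)
        gate = 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))
        ref = fine * gate[:, :, None, None]
        np.testing.assert_allclose(out, ref, rtol=1e-5, atol=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        fine = nn.Tensor(rng.normal(size=(1, 8, 4, 4)))
        coarse = nn.Tensor(rng.normal(size=(1, 6, 2, 2)))
        with pytest.raises(ValueError):
            first_order_attention(coarse, fine, np.zeros((6, 2)), np.zeros(2),
                                  np.zeros((2, 7)), np.zeros(7))


# ---------------------------------------------------------------------------
# second-order attention
# ---------------------------------------------------------------------------

class TestSecondOrderAttention:
    def test_matches_bruteforce_gram_softmax_mix(self, rng):
        a = rng.normal(size=(1, 4, 8, 8))
        b = rng.normal(size=(1, 4, 8, 8))
        out = second_order_attention([nn.Tensor(a), nn.Tensor(b)]).numpy()

        def soft(m):
            e = np.exp(m - m.max(axis=-1, keepdims=True))
            return e / e.sum(axis=-1, keepdims=True)

        fa = a.reshape(1, 4, 64)
        fb = b.reshape(1, 4, 64)
        scale = 1 / np.sqrt(64)
        ref = np.zeros_like(fa)
        for fi, fj in ((fa, fb), (fb, fa)):
            gram = soft(fi @ fj.transpose(0, 2, 1) * scale)
            ref = ref + gram @ fj
        np.testing.assert_allclose(out, ref.reshape(1, 4, 8, 8), rtol=1e-4,
                                   atol=1e-5)

    def test_identical_constant_maps_mix_uniformly(self):
        const = np.full((1, 3, 2, 2), 0.7)
        out = second_order_attention([nn.Tensor(const), nn.Tensor(const)]).numpy()
        # all Gram entries equal -> uniform softmax rows -> each reweighted
        # stream equals the channel mean; two ordered pairs sum
        np.testing.assert_allclose(out, np.full_like(const, 2 * 0.7), rtol=1e-6)

    def test_single_stream_bypassed(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 4, 4, 4)))
        out = second_order_attention([x])
        np.testing.assert_array_equal(out.numpy(), x.numpy())

    def test_mismatched_grids_rejected(self, rng):
        a = nn.Tensor(rng.normal(size=(1, 4, 8, 8)))
        b = nn.Tensor(rng.normal(size=(1, 4, 4, 4)))
        with pytest.raises(ValueError):
            second_order_attention([a, b])


# ---------------------------------------------------------------------------
# pyramid pooling
# ---------------------------------------------------------------------------

class TestPyramidPool:
    def test_constant_input_gives_constant_branches(self):
        """Pooled branches of a constant map are constant with its value;
        the fused map is constant away from the zero-padded border."""
        from anorak.model import PyramidPool

        ppm = PyramidPool(8, (1, 2), rng=np.random.default_rng(0))
        x = nn.Tensor(np.full((1, 8, 6, 6), 0.7))
        for b in (1, 2):
            pooled = F.adaptive_avg_pool2d(x, (b, b)).numpy()
            np.testing.assert_allclose(pooled, 0.7)
            up = F.upsample_bilinear(nn.Tensor(pooled), (6, 6)).numpy()
            np.testing.assert_allclose(up, 0.7)
        out = ppm(x).numpy()
        interior = out[:, :, 1:-1, 1:-1]
        spread = interior.max(axis=(2, 3)) - interior.min(axis=(2, 3))
        assert float(spread.max()) < 1e-5

    def test_matches_straight_line_recomputation(self, rng):
        from anorak.model import PyramidPool
        from anorak.nn.functional import _interp_matrix, _pool_bins

        ppm = PyramidPool(16, (1, 2, 3, 6), rng=np.random.default_rng(3))
        x = rng.normal(size=(1, 16, 12, 12))
        out = ppm(nn.Tensor(x)).numpy()

        branches = [x]
        for i, b in enumerate((1, 2, 3, 6)):
            hs, he = _pool_bins(12, b)
            pooled = np.stack([
                np.stack([x[0, :, hs[p]:he[p], hs[q]:he[q]].mean(axis=(1, 2))
                          for q in range(b)], axis=1)
                for p in range(b)], axis=1)[None]        # (1, C, b, b)
            conv = getattr(ppm, f"red{i}")
            red = np.einsum("oc,nchw->nohw", conv.weight.data[:, :, 0, 0], pooled)
            red = np.maximum(red + conv.bias.data[None, :, None, None], 0.0)
            m = _interp_matrix(12, b)
            up = np.einsum("ij,ncjk,lk->ncil", m, red, m)
            branches.append(up)
        cat = np.concatenate(branches, axis=1)
        w, bias = ppm.fuse.weight.data, ppm.fuse.bias.data
        fused = np.stack([
            sum(signal.correlate2d(cat[0, ci], w[co, ci], mode="same")
                for ci in range(cat.shape[1])) + bias[co]
            for co in range(16)])[None]
        ref = np.maximum(fused, 0.0)
        np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-4)

    def test_bin_larger_than_grid_rejected(self, rng):
        from anorak.model import PyramidPool

        ppm = PyramidPool(4, (1, 6), rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            ppm(nn.Tensor(rng.normal(size=(1, 4, 4, 4))))
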
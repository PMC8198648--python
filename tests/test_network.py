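"""Feature extractor: attention gates, residual identity, SPP, size invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grainkit.network import (
    BackboneConfig,
    Tensor,
    UndersizeError,
    channel_attention,
    channel_gate,
    forward_extract,
    init_params,
    pyramid_bins,
    residual_block,
    spatial_attention,
    spatial_gate,
    spp_pool,
)
from grainkit.network.autodiff import conv2d, maxpool2d


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------- pyramid bins

class TestPyramidBins:
    def test_unit_bins(self):
        assert pyramid_bins(4, 4) == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_global_bin(self):
        assert pyramid_bins(5, 1) == [(0, 5)]

    def test_uneven_extent_overlapping_bins(self):
        assert pyramid_bins(7, 4) == [(0, 2), (1, 4), (3, 6), (5, 7)]

    @settings(derandomize=True, max_examples=200)
    @given(extent=st.integers(1, 64), n_bins=st.sampled_from([1, 2, 4]))
    def test_bins_cover_extent_with_no_empty_bin(self, extent, n_bins):
        bins = pyramid_bins(extent, n_bins)
        covered = set()
        for lo, hi in bins:
            assert hi > lo  # non-empty
            covered |= set(range(lo, hi))
        assert covered == set(range(extent))

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            pyramid_bins(5, 0)
        with pytest.raises(ValueError):
            pyramid_bins(0, 2)


# ------------------------------------------------------------------------ SPP

def _brute_force_spp(f, levels=(4, 2, 1)):
    rows = []
    for n in levels:
        for r0, r1 in pyramid_bins(f.shape[0], n):
            for c0, c1 in pyramid_bins(f.shape[1], n):
                rows.append(
                    np.array([
                        max(f[r, c, ch] for r in range(r0, r1) for c in range(c0, c1))
                        for ch in range(f.shape[2])
                    ])
                )
    return np.stack(rows)


class TestSppPool:
    def test_descriptor_geometry_is_21_rows(self, rng):
        f = rng.normal(size=(13, 13, 1024))
        d = spp_pool(f)
        assert d.blocks.shape == (21, 1024)
        assert d.flat.shape == (21 * 1024,)

    def test_constant_map_gives_constant_descriptor(self):
        d = spp_pool(np.full((6, 9, 3), 2.5))
        assert np.all(d.blocks == 2.5)

    def test_matches_exhaustive_bin_oracle_on_all_small_maps(self, rng):
        for n in range(4, 10):
            for m in range(4, 10):
                f = rng.normal(size=(n, m, 3))
                assert np.allclose(spp_pool(f).blocks, _brute_force_spp(f))

    def test_flatten_order_is_blocks_outer_channels_inner(self, rng):
        f = rng.normal(size=(5, 7, 2))
        d = spp_pool(f)
        assert np.array_equal(d.flat[:2], d.blocks[0])
        assert np.array_equal(d.flat[2:4], d.blocks[1])

    def test_undersize_map_names_minimum(self):
        with pytest.raises(ValueError, match=">= 4"):
            spp_pool(np.zeros((3, 10, 2)))


# ------------------------------------------------------------------ attention

class TestChannelAttention:
    def test_closed_form_on_spatially_constant_input(self, rng):
        # constant-per-channel map: avg pool == max pool, gate = sigmoid(2(Wv+b))
        v = np.array([0.3, -1.2, 2.0])
        f = np.broadcast_to(v, (4, 6, 3)).copy()
        w = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        expected_gate = _sigmoid(2.0 * (w @ v + b))
        assert np.allclose(channel_gate(f, {"w": w, "b": b}), expected_gate)
        out = channel_attention(f, {"w": w, "b": b})
        assert np.allclose(out, f * expected_gate)

    def test_zero_input_identity_weights_gives_half_gate(self):
        f = np.zeros((5, 5, 4))
        w = np.eye(4)
        out = channel_attention(f, {"w": w, "b": np.zeros(4)})
        assert np.allclose(channel_gate(f, {"w": w, "b": np.zeros(4)}), 0.5)
        assert np.allclose(out, 0.0)

    def test_gate_in_unit_interval_and_shape_preserved(self, rng):
        for _ in range(5):
            f = rng.normal(scale=10, size=(3, 8, 6))
            w = rng.normal(size=(6, 6))
            gate = channel_gate(f, {"w": w, "b": rng.normal(size=6)})
            assert np.all((gate > 0) & (gate < 1))
            out = channel_attention(f, {"w": w, "b": np.zeros(6)})
            assert out.shape == f.shape

    def test_weight_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_attention(rng.normal(size=(4, 4, 3)), {"w": np.eye(5), "b": np.zeros(5)})


class TestSpatialAttention:
    def test_single_channel_hand_convolution_oracle(self, rng):
        # with C=1, mean map == max map == the channel itself
        f = rng.normal(size=(3, 3, 1))
        w = rng.normal(size=(1, 2, 3, 3))
        b = rng.normal(size=1)
        padded = np.pad(f[:, :, 0], 1)
        conv = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                window = padded[i : i + 3, j : j + 3]
                conv[i, j] = (window * w[0, 0]).sum() + (window * w[0, 1]).sum() + b[0]
        expected_mask = _sigmoid(conv)
        assert np.allclose(spatial_gate(f, {"w": w, "b": b}), expected_mask)
        assert np.allclose(
            spatial_attention(f, {"w": w, "b": b}), f * expected_mask[:, :, None]
        )

    def test_zero_weights_force_half_gate(self, rng):
        f = rng.normal(size=(6, 9, 4))
        w = {"w": np.zeros((1, 2, 7, 7)), "b": np.zeros(1)}
        assert np.allclose(spatial_attention(f, w), f / 2.0)

    def test_mask_in_unit_interval(self, rng):
        f = rng.normal(scale=5, size=(7, 5, 3))
        mask = spatial_gate(f, {"w": rng.normal(size=(1, 2, 3, 3)), "b": rng.normal(size=1)})
        assert mask.shape == (7, 5)
        assert np.all((mask > 0) & (mask < 1))

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial_attention(rng.normal(size=(4, 4, 2)),
                              {"w": np.zeros((1, 2, 4, 4)), "b": np.zeros(1)}, kernel=4)


# ------------------------------------------------------------------- residual

class TestResidualBlock:
    def test_zero_branch_is_identity(self, rng):
        x = rng.normal(size=(4, 5, 3))
        assert np.array_equal(residual_block(x, lambda v: np.zeros_like(v)), x)

    def test_zero_input_passes_branch_output(self):
        x = np.zeros((3, 3, 2))
        out = residual_block(x, lambda v: v + 1.0)
        assert np.allclose(out, 1.0)

    def test_linear_branch_matches_elementwise_sum(self, rng):
        x = rng.normal(scale=0.1, size=(4, 4, 2))
        branch = lambda v: 3.0 * v - 0.5
        assert np.allclose(residual_block(x, branch), branch(x) + x)

    def test_shape_mismatch_without_projection_rejected(self, rng):
        x = rng.normal(size=(4, 4, 2))
        with pytest.raises(ValueError, match="projection"):
            residual_block(x, lambda v: v[:2])


# ------------------------------------------------------------- whole extractor

class TestForwardExtract:
    def test_descriptor_shape_invariant_over_random_sizes(self, tiny_config, tiny_params, rng):
        shapes = set()
        for _ in range(10):
            h = int(rng.integers(64, 129))
            w = int(rng.integers(64, 257))
            img = rng.integers(0, 255, (h, w, 3), dtype=np.uint8)
            d = forward_extract(img, tiny_config, tiny_params)
            shapes.add(d.blocks.shape)
            assert np.isfinite(d.flat).all()
        assert shapes == {(21, tiny_config.out_channels)}

    def test_undersized_image_errors_before_weights(self, tiny_config, tiny_params):
        with pytest.raises(UndersizeError, match=str(tiny_config.min_input_size)):
            forward_extract(np.zeros((32, 500, 3), dtype=np.uint8), tiny_config, tiny_params)

    def test_zero_attention_weights_quarter_scale_trunk(self, rng):
        """Zero gate convolutions force both sigmoid gates to 0.5, so the
        descriptor equals the attention-free descriptor scaled by 1/4
        (single-stage trunk, zero biases, positive post-ReLU map)."""
        cfg_att = BackboneConfig(stage_block_counts=(1,), stage_channels=(8,), stem_channels=8)
        cfg_plain = BackboneConfig(stage_block_counts=(1,), stage_channels=(8,),
                                   stem_channels=8, use_attention=False)
        params = init_params(cfg_att, seed=3)
        for name in ("stage0.ca.w", "stage0.ca.b", "stage0.sa.w", "stage0.sa.b"):
            params[name] = np.zeros_like(params[name])
        img = rng.integers(0, 255, (64, 96, 3), dtype=np.uint8)
        gated = forward_extract(img, cfg_att, params)
        plain = forward_extract(img, cfg_plain, params)
        assert np.allclose(gated.blocks, 0.25 * plain.blocks)

    def test_tiny_config_smoke_on_minimum_size(self, tiny_config, tiny_params):
        img = np.random.default_rng(0).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        d = forward_extract(img, tiny_config, tiny_params)
        assert d.blocks.shape == (21, 32)
        assert np.isfinite(d.flat).all()


# ----------------------------------------------------------- autodiff engine

class TestAutodiffGradients:
    def test_conv_maxpool_gradient_matches_finite_differences(self, rng):
        x0 = rng.normal(size=(2, 8, 9))
        w0 = rng.normal(size=(3, 2, 3, 3)) * 0.5
        b0 = rng.normal(size=3)

        def run(xv, wv, bv):
            x, w, b = Tensor(xv, True), Tensor(wv, True), Tensor(bv, True)
            out = maxpool2d(conv2d(x, w, b, stride=1, pad=1).relu(), 2, 2)
            loss = (out * out).sum()
            return x, w, b, loss

        x, w, b, loss = run(x0, w0, b0)
        loss.backward()
        eps = 1e-6
        for val, tensor in ((x0, x), (w0, w), (b0, b)):
            idx = np.unravel_index(np.argmax(np.abs(tensor.grad)), val.shape)
            pert = val.copy()
            pert[idx] += eps
            lp = run(*(pert if v is val else v for v in (x0, w0, b0)))[3].data
            pert[idx] -= 2 * eps
            lm = run(*(pert if v is val else v for v in (x0, w0, b0)))[3].data
            numeric = (lp - lm) / (2 * eps)
            assert np.isclose(numeric, tensor.grad[idx], rtol=1e-4), idx
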
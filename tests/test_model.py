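"""Backbone geometry, attention oracle equivalence, and analytic accounting."""

import numpy as np
import pytest
from scipy.special import erf

from conftest import micro_config, tiny_config
from swinpoly.model import (SwinClassifier, SwinConfig, complexity_msa,
                            complexity_wmsa, count_parameters,
                            load_checkpoint, model_mac_count, save_checkpoint,
                            summarize, PatchMerging, SwinBlock,
                            _relative_position_index)
from swinpoly.nn import Tensor


def _softmax(a, axis=-1):
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class TestConfig:
    def test_odd_depth_rejected(self):
        with pytest.raises(ValueError, match="even"):
            tiny_config(depths=(3, 2), num_heads=(2, 4))

    def test_head_not_dividing_dim_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            tiny_config(num_heads=(5, 4))

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            SwinConfig(input_size=225)

    def test_stage_geometry(self):
        cfg = SwinConfig()
        assert cfg.stage_resolutions() == (56, 28, 14, 7)
        assert cfg.stage_dims() == (96, 192, 384, 768)


class TestPatchEmbed:
    def test_default_token_grid(self):
        # only geometry: a full-size embed layer on one image is still fast
        model = SwinClassifier(tiny_config(input_size=224), rng=0)
        x = np.zeros((1, 224, 224, 1), dtype=np.float32)
        tokens = model.patch_embed(Tensor(x))
        assert tokens.shape == (1, 56, 56, 24)

    def test_small_shape_arithmetic(self):
        model = SwinClassifier(micro_config(input_size=8, embed_dim=5,
                                            num_heads=(1,), window_size=2),
                               rng=0)
        tokens = model.patch_embed(Tensor(np.zeros((2, 8, 8, 1), np.float32)))
        assert tokens.shape == (2, 2, 2, 5)

    def test_zero_image_gives_projection_bias(self, micro_model):
        out = micro_model.patch_embed.proj(
            Tensor(np.zeros((1, 4, 4, 16), np.float32)))
        np.testing.assert_allclose(
            out.data, np.broadcast_to(micro_model.patch_embed.proj.bias.data,
                                      out.shape), atol=1e-7)


class TestSwinBlock:
    def test_zeroed_projections_give_identity(self, rng):
        blk = SwinBlock(dim=8, resolution=4, num_heads=2, window_size=4,
                        shifted=False, mlp_ratio=2.0,
                        rng=np.random.default_rng(0))
        blk.attn.proj.weight.data[:] = 0
        blk.mlp.fc2.weight.data[:] = 0
        x = rng.standard_normal((2, 4, 4, 8)).astype(np.float32)
        np.testing.assert_allclose(blk(Tensor(x)).data, x, atol=1e-7)

    def test_degenerate_window_covers_whole_map(self):
        # window size >= side: the shifted block must not shift or mask
        blk = SwinBlock(dim=8, resolution=7, num_heads=2, window_size=7,
                        shifted=True, mlp_ratio=2.0,
                        rng=np.random.default_rng(0))
        assert blk.shift == (0, 0)
        assert blk.attn_mask is None

    def test_matches_dense_per_window_oracle(self):
        """Unshifted block attention equals a loop-based dense softmax
        attention computed per window with the same weights."""
        rng = np.random.default_rng(5)
        dim, m, heads, res = 16, 4, 2, 8
        blk = SwinBlock(dim=dim, resolution=res, num_heads=heads,
                        window_size=m, shifted=False, mlp_ratio=2.0, rng=rng)
        blk.attn.relative_position_bias_table.data[:] = \
            rng.standard_normal(blk.attn.relative_position_bias_table.shape) \
            .astype(np.float32)
        x = rng.standard_normal((1, res, res, dim)).astype(np.float32)
        got = blk(Tensor(x)).data[0]

        # oracle: replicate pre-norm, windowed multi-head attention, MLP
        def layer_norm(a, w, b):
            mu = a.mean(-1, keepdims=True)
            var = a.var(-1, keepdims=True)
            return (a - mu) / np.sqrt(var + 1e-5) * w + b

        xn = layer_norm(x[0], blk.norm1.weight.data, blk.norm1.bias.data)
        hd = dim // heads
        wq = blk.attn.qkv.weight.data
        bq = blk.attn.qkv.bias.data
        bias_tab = blk.attn.relative_position_bias_table.data
        rel = _relative_position_index(m)
        attn_out = np.zeros_like(xn)
        for r0 in range(0, res, m):
            for c0 in range(0, res, m):
                t = xn[r0:r0 + m, c0:c0 + m].reshape(m * m, dim)
                qkv = t @ wq + bq
                q, k, v = np.split(qkv, 3, axis=-1)
                heads_out = []
                for h in range(heads):
                    qs = q[:, h * hd:(h + 1) * hd] / np.sqrt(hd)
                    ks = k[:, h * hd:(h + 1) * hd]
                    vs = v[:, h * hd:(h + 1) * hd]
                    logits = qs @ ks.T + bias_tab[rel, h]
                    heads_out.append(_softmax(logits) @ vs)
                out = np.concatenate(heads_out, axis=-1)
                out = out @ blk.attn.proj.weight.data + blk.attn.proj.bias.data
                attn_out[r0:r0 + m, c0:c0 + m] = out.reshape(m, m, dim)
        z = x[0] + attn_out
        zn = layer_norm(z, blk.norm2.weight.data, blk.norm2.bias.data)
        h1 = zn @ blk.mlp.fc1.weight.data + blk.mlp.fc1.bias.data
        h1 = h1 * 0.5 * (1.0 + erf(h1 / np.sqrt(2)))
        expected = z + h1 @ blk.mlp.fc2.weight.data + blk.mlp.fc2.bias.data
        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestPatchMerging:
    def test_shape_halves_resolution_doubles_channels(self, rng):
        pm = PatchMerging(dim=3, rng=np.random.default_rng(0))
        out = pm(Tensor(rng.standard_normal((2, 6, 4, 3)).astype(np.float32)))
        assert out.shape == (2, 3, 2, 6)

    def test_minimal_grid(self, rng):
        pm = PatchMerging(dim=1, rng=np.random.default_rng(0))
        out = pm(Tensor(rng.standard_normal((1, 2, 2, 1)).astype(np.float32)))
        assert out.shape == (1, 1, 1, 2)

    def test_odd_dims_rejected(self):
        pm = PatchMerging(dim=2, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="even"):
            pm(Tensor(np.zeros((1, 3, 4, 2), np.float32)))

    def test_neighborhood_gather_order(self, rng):
        """The pre-projection gather is exactly the 2x2 concatenation."""
        pm = PatchMerging(dim=2, rng=np.random.default_rng(0))
        x = rng.standard_normal((1, 4, 4, 2)).astype(np.float32)
        concat = np.concatenate([x[:, 0::2, 0::2], x[:, 1::2, 0::2],
                                 x[:, 0::2, 1::2], x[:, 1::2, 1::2]], axis=-1)
        mu = concat.mean(-1, keepdims=True)
        var = concat.var(-1, keepdims=True)
        normed = (concat - mu) / np.sqrt(var + 1e-5) \
            * pm.norm.weight.data + pm.norm.bias.data
        expected = normed @ pm.reduction.weight.data
        np.testing.assert_allclose(pm(Tensor(x)).data, expected, atol=1e-6)


class TestForward:
    def test_batch_logit_shape(self, tiny_model, rng):
        x = rng.random((2, 32, 32, 1)).astype(np.float32)
        assert tiny_model(x).shape == (2, 4)

    def test_identical_images_identical_logits(self, tiny_model, rng):
        img = rng.random((32, 32, 1)).astype(np.float32)
        logits = tiny_model(np.stack([img, img])).data
        np.testing.assert_array_equal(logits[0], logits[1])

    def test_forward_is_pure(self, tiny_model, rng):
        x = rng.random((1, 32, 32, 1)).astype(np.float32)
        np.testing.assert_array_equal(tiny_model(x).data, tiny_model(x).data)

    def test_stagewise_token_and_channel_scaling(self, tiny_model, rng):
        capture = {}
        tiny_model(rng.random((1, 32, 32, 1)).astype(np.float32), capture=capture)
        s0 = capture["stage0.block0.norm1"]
        s1 = capture["stage1.block0.norm1"]
        assert s0.shape[1] * s0.shape[2] == 4 * s1.shape[1] * s1.shape[2]
        assert s1.shape[3] == 2 * s0.shape[3]

    def test_head_permutation_equivariance(self, rng):
        model = SwinClassifier(micro_config(), rng=3)
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        base = model(x).data.copy()
        perm = np.array([2, 0, 3, 1])
        model.head.weight.data = model.head.weight.data[:, perm]
        model.head.bias.data = model.head.bias.data[perm]
        np.testing.assert_allclose(model(x).data, base[:, perm], atol=1e-6)


class TestComplexity:
    def test_formulas(self):
        h = w = 56
        c, m = 96, 7
        assert complexity_msa(h, w, c) == 4 * h * w * c**2 + 2 * (h * w)**2 * c
        assert complexity_wmsa(h, w, c, m) == 145_108_992

    def test_coincide_when_window_covers_grid(self):
        assert complexity_msa(7, 7, 32) == complexity_wmsa(7, 7, 32, 7)

    def test_wmsa_never_more_expensive(self):
        for h, w, c, m in [(56, 56, 96, 7), (28, 28, 192, 7), (8, 8, 16, 4)]:
            gap = complexity_msa(h, w, c) - complexity_wmsa(h, w, c, m)
            assert gap == 2 * h * w * c * (h * w - m * m)
            assert gap >= 0


class TestAccounting:
    def test_default_parameter_count(self):
        assert round(count_parameters(SwinConfig(num_classes=4)) / 1e6, 1) == 27.5

    def test_default_mac_count(self):
        assert round(model_mac_count(SwinConfig(num_classes=4)) / 1e9, 1) == 4.5

    def test_head_growth_algebra(self):
        base = count_parameters(tiny_config(num_classes=4))
        grown = count_parameters(tiny_config(num_classes=8))
        final_dim = tiny_config().stage_dims()[-1]
        assert grown - base == (final_dim + 1) * 4

    def test_summary_is_consistent(self):
        s = summarize(SwinConfig(num_classes=4)).to_dict()
        assert s["parameters_millions"] == 27.5
        assert s["macs_giga"] == 4.5


class TestCheckpoint:
    def test_roundtrip_preserves_forward(self, tmp_path, rng):
        model = SwinClassifier(micro_config(), rng=7)
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        before = model(x).data
        path = tmp_path / "model.npz"
        save_checkpoint(path, model, ["A", "B", "C", "D"])
        loaded, classes = load_checkpoint(path)
        assert classes == ["A", "B", "C", "D"]
        np.testing.assert_array_equal(loaded(x).data, before)

    def test_bad_format_rejected(self, tmp_path):
        import json
        path = tmp_path / "bad.npz"
        np.savez(path, __meta__=np.frombuffer(
            json.dumps({"format": "other"}).encode(), dtype=np.uint8))
        with pytest.raises(ValueError, match="format"):
            load_checkpoint(path)
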
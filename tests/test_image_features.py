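"""Patch embedding, self-attention, FFN and the stacked ViT encoder."""

import numpy as np
import pytest

from apocvit import nn
from apocvit.image_features import (EncoderConfig, ImageEncoder,
                                    PatchGridSpec, add_positional,
                                    encode_image, extract_patches, ffn,
                                    patchify_embed, self_attention)


class TestPatchify:
    def test_64px_image_16px_patches_give_16_tokens(self, rng):
        spec = PatchGridSpec((64, 64), (16, 16), 32)
        W = rng.normal(0, 1, (spec.patch_dim, 32))
        tokens = patchify_embed(rng.normal(0, 1, (64, 64)), spec, W,
                                np.zeros(32))
        assert tokens.shape == (16, 32)

    def test_224px_16px_patch_count_is_196(self):
        assert PatchGridSpec((224, 224), (16, 16), 64).num_patches == 196

    def test_zero_image_zero_bias_gives_zero_tokens(self, rng):
        spec = PatchGridSpec((32, 32), (8, 8), 16)
        W = rng.normal(0, 1, (spec.patch_dim, 16))
        tokens = patchify_embed(np.zeros((32, 32)), spec, W, np.zeros(16))
        assert np.all(tokens == 0.0)

    def test_non_divisible_patch_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            PatchGridSpec((30, 30), (8, 8), 16)

    def test_patch_rows_are_row_major_blocks(self):
        img = np.arange(16.0).reshape(4, 4)
        spec = PatchGridSpec((4, 4), (2, 2), 4)
        patches = extract_patches(img, spec)
        assert np.array_equal(patches[0], [0, 1, 4, 5])
        assert np.array_equal(patches[3], [10, 11, 14, 15])


class TestPositional:
    def test_zero_table_is_identity(self, rng):
        tokens = rng.normal(0, 1, (9, 8))
        assert np.array_equal(add_positional(tokens, np.zeros((9, 8))), tokens)

    def test_joint_permutation_equivariance(self, rng):
        tokens = rng.normal(0, 1, (9, 8))
        pos = rng.normal(0, 1, (9, 8))
        perm = rng.permutation(9)
        assert np.allclose(add_positional(tokens, pos)[perm],
                           add_positional(tokens[perm], pos[perm]))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            add_positional(rng.normal(0, 1, (9, 8)), np.zeros((8, 8)))

    def test_encoder_is_position_sensitive(self, rng):
        # with a nonzero positional table, permuting patches changes output
        spec = PatchGridSpec((16, 16), (8, 8), 8)
        enc = ImageEncoder(spec, EncoderConfig(depth=1, num_heads=2,
                                               ffn_hidden=16), rng)
        img = rng.normal(0, 1, (16, 16))
        permuted = img.copy()
        permuted[:8], permuted[8:] = img[8:].copy(), img[:8].copy()
        a = enc(img[None])
        b = enc(permuted[None])
        assert not np.allclose(a.data, b.data)


class TestSelfAttention:
    def test_single_token_returns_value_exactly(self, rng):
        Q = rng.normal(0, 1, (1, 4))
        K = rng.normal(0, 1, (1, 4))
        V = rng.normal(0, 1, (1, 6))
        assert np.allclose(self_attention(Q, K, V, 4), V)

    def test_identical_keys_give_uniform_average(self, rng):
        K = np.tile(rng.normal(0, 1, (1, 4)), (5, 1))
        Q = rng.normal(0, 1, (5, 4))
        V = rng.normal(0, 1, (5, 3))
        out, A = self_attention(Q, K, V, 4, return_weights=True)
        assert np.allclose(A, 1.0 / 5)
        assert np.allclose(out, np.tile(V.mean(axis=0), (5, 1)))

    def test_rows_sum_to_one(self, rng):
        Q, K = rng.normal(0, 1, (2, 7, 4))
        V = rng.normal(0, 1, (7, 5))
        _, A = self_attention(Q, K, V, 4, return_weights=True)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-9)

    def test_output_in_convex_hull_of_values(self, rng):
        Q, K = rng.normal(0, 1, (2, 6, 4))
        V = rng.normal(0, 1, (6, 3))
        out = self_attention(Q, K, V, 4)
        assert np.all(out <= V.max(axis=0) + 1e-12)
        assert np.all(out >= V.min(axis=0) - 1e-12)

    def test_nonpositive_dk_rejected(self, rng):
        with pytest.raises(ValueError):
            self_attention(np.eye(2), np.eye(2), np.eye(2), 0)


class TestFFN:
    def test_zero_input_closed_form(self, rng):
        W1, b1 = rng.normal(0, 1, (4, 6)), rng.normal(0, 1, 6)
        W2, b2 = rng.normal(0, 1, (6, 4)), rng.normal(0, 1, 4)
        expected = np.maximum(b1, 0) @ W2 + b2
        assert np.allclose(ffn(np.zeros(4), W1, b1, W2, b2), expected)

    def test_identity_weights_pass_nonnegative_input(self):
        x = np.array([0.5, 2.0, 0.0])
        I = np.eye(3)
        z = np.zeros(3)
        assert np.allclose(ffn(x, I, z, I, z), x)

    def test_relu_stage_is_nonnegative(self, rng):
        x = rng.normal(0, 1, 5)
        W1, b1 = rng.normal(0, 1, (5, 7)), rng.normal(0, 1, 7)
        assert np.all(np.maximum(x @ W1 + b1, 0.0) >= 0.0)


class TestEncoder:
    def test_output_dim_matches_embed_dim(self, rng):
        spec = PatchGridSpec((32, 32), (8, 8), 24)
        enc = ImageEncoder(spec, EncoderConfig(depth=2, num_heads=3,
                                               ffn_hidden=32), rng)
        feat = encode_image(rng.normal(0, 1, (32, 32)), enc)
        assert feat.dim == 24 and feat.modality == "image"

    def test_deterministic_under_fixed_weights(self, rng):
        spec = PatchGridSpec((16, 16), (8, 8), 8)
        enc = ImageEncoder(spec, EncoderConfig(depth=1, num_heads=1,
                                               ffn_hidden=8), rng)
        img = rng.normal(0, 1, (16, 16))
        assert np.array_equal(enc(img[None]).data, enc(img[None]).data)

    def test_single_patch_change_changes_feature(self, rng):
        spec = PatchGridSpec((32, 32), (8, 8), 16)
        enc = ImageEncoder(spec, EncoderConfig(depth=2, num_heads=2,
                                               ffn_hidden=16), rng)
        img = rng.normal(0, 1, (32, 32))
        other = img.copy()
        other[:8, :8] += 1.0   # perturb exactly one patch
        assert not np.allclose(enc(img[None]).data, enc(other[None]).data)

    def test_zeroed_sublayers_make_each_layer_identity(self, rng):
        # residual wiring: with attention proj and FFN second map zeroed,
        # every encoder layer must return its input untouched
        spec = PatchGridSpec((16, 16), (8, 8), 8)
        enc = ImageEncoder(spec, EncoderConfig(depth=2, num_heads=2,
                                               ffn_hidden=8), rng)
        for layer in enc.layers:
            layer.attn.proj.W.data[:] = 0.0
            layer.attn.proj.b.data[:] = 0.0
            layer.fc2.W.data[:] = 0.0
            layer.fc2.b.data[:] = 0.0
        x = enc.tokens(rng.normal(0, 1, (1, 16, 16)))
        y = x
        for layer in enc.layers:
            y = layer(y)
        assert np.array_equal(y.data, x.data)

    def test_gradients_flow_to_patch_embedding(self, rng):
        spec = PatchGridSpec((16, 16), (8, 8), 8)
        enc = ImageEncoder(spec, EncoderConfig(depth=1, num_heads=2,
                                               ffn_hidden=8), rng)
        out = enc(rng.normal(0, 1, (2, 16, 16)))
        loss = (out * out).sum()
        loss.backward()
        assert enc.embed.W.grad is not None
        assert np.any(enc.embed.W.grad != 0.0)
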
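"""Backbone oracles: window attention vs dense attention, patch ops, shapes."""

import numpy as np
import pytest

from snagdet.backbone import (FeatureMap, PatchExpand, PatchMerge, SwinBackbone,
                              SwinBlock, SwinConfig, WindowAttention,
                              patch_partition, shift_attention_mask, wmsa_cost)
from snagdet.nn import Tensor


def dense_attention_oracle(x, Wqkv, bqkv, Wproj, bproj, bias_table, rel_index,
                           heads, allowed=None):
    """Brute-force multi-head attention over a token set (numpy loops)."""
    n, c = x.shape
    d = c // heads
    qkv = x @ Wqkv + bqkv
    q, k, v = qkv[:, :c], qkv[:, c:2 * c], qkv[:, 2 * c:]
    out = np.zeros((n, c))
    for h in range(heads):
        qh = q[:, h * d:(h + 1) * d]
        kh = k[:, h * d:(h + 1) * d]
        vh = v[:, h * d:(h + 1) * d]
        for i in range(n):
            logits = np.full(n, -np.inf)
            for j in range(n):
                if allowed is not None and not allowed[i, j]:
                    continue
                logits[j] = qh[i] @ kh[j] / np.sqrt(d) + bias_table[rel_index[i, j], h]
            w = np.exp(logits - logits.max())
            w = w / w.sum()
            out[i, h * d:(h + 1) * d] = sum(w[j] * vh[j] for j in range(n) if w[j] > 0)
    return out @ Wproj + bproj


class TestWindowAttention:
    def test_single_window_equals_dense_attention(self, rng):
        M, c, heads = 4, 8, 2
        attn = WindowAttention(c, heads, M, np.random.default_rng(3))
        x = rng.normal(size=(M, M, c))
        wins = Tensor(x.reshape(1, M * M, c))
        got = attn(wins).numpy()[0]
        want = dense_attention_oracle(
            x.reshape(M * M, c), attn.qkv.weight.data, attn.qkv.bias.data,
            attn.proj.weight.data, attn.proj.bias.data,
            attn.rel_bias.data, attn._rel_index, heads)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_uniform_attention_when_logits_flat(self, rng):
        """Zero Q,K weights and zero bias → every token gets the window mean."""
        M, c = 2, 4
        attn = WindowAttention(c, 1, M, np.random.default_rng(0))
        attn.qkv.weight.data[:, :2 * c] = 0.0   # Q and K projections
        attn.qkv.bias.data[:2 * c] = 0.0
        attn.rel_bias.data[:] = 0.0
        x = rng.normal(size=(1, M * M, c))
        got = attn(Tensor(x)).numpy()[0]
        v = x[0] @ attn.qkv.weight.data[:, 2 * c:] + attn.qkv.bias.data[2 * c:]
        want = np.repeat(v.mean(axis=0, keepdims=True), M * M, axis=0)
        want = want @ attn.proj.weight.data + attn.proj.bias.data
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_attention_rows_are_probability_vectors(self, rng):
        """Row-stochasticity, checked under extreme logits for stability."""
        M, c = 4, 4
        attn = WindowAttention(c, 1, M, np.random.default_rng(1))
        x = Tensor(rng.normal(size=(2, M * M, c)) * 1e4)
        qkv = attn.qkv(x).reshape(2, M * M, 3, 1, c).transpose(2, 0, 3, 1, 4)
        logits = (qkv[0] @ qkv[1].transpose(0, 1, 3, 2)) * (1 / np.sqrt(c))
        rows = logits.softmax(axis=-1).numpy()
        assert np.isfinite(rows).all()
        np.testing.assert_allclose(rows.sum(axis=-1), 1.0, atol=1e-12)


class TestShiftedWindows:
    @pytest.mark.parametrize("M", [2, 4])
    def test_mask_allows_exactly_preshift_contiguous_pairs(self, M):
        """Combinatorial check of the shift mask against a region oracle."""
        h = w = 2 * M
        shift = M // 2
        mask = shift_attention_mask(h, w, M, shift)
        # oracle: recompute region ids from first principles
        region = np.zeros((h, w), int)
        bounds = [(0, h - M), (h - M, h - shift), (h - shift, h)]
        for a, (r0, r1) in enumerate(bounds):
            for b, (c0, c1) in enumerate(bounds):
                region[r0:r1, c0:c1] = 3 * a + b
        rolled = np.roll(region, (-shift, -shift), (0, 1))
        wins = rolled.reshape(h // M, M, w // M, M).transpose(0, 2, 1, 3).reshape(-1, M * M)
        for wi in range(wins.shape[0]):
            for i in range(M * M):
                for j in range(M * M):
                    allowed = wins[wi, i] == wins[wi, j]
                    assert (mask[wi, i, j] == 0) == allowed

    def test_shift_zero_matches_plain_window_attention(self, rng):
        M, c = 2, 4
        blk = SwinBlock(c, 1, M, 2.0, np.random.default_rng(5), shift=0)
        blk2 = SwinBlock(c, 1, M, 2.0, np.random.default_rng(5), shift=0)
        x = Tensor(rng.normal(size=(2 * M, 2 * M, c)))
        np.testing.assert_allclose(blk(x).numpy(), blk2(x).numpy())

    def test_cyclic_shift_roundtrip_restores_input(self, rng):
        x = Tensor(rng.normal(size=(8, 8, 3)))
        back = x.roll((-2, -2), (0, 1)).roll((2, 2), (0, 1))
        np.testing.assert_array_equal(back.numpy(), x.numpy())

    def test_shifted_attention_equals_region_restricted_dense_oracle(self, rng):
        """Each token's SW-MSA output equals dense attention over the tokens
        sharing both its shifted window and its pre-shift region."""
        M, c, heads = 4, 8, 2
        h = w = 2 * M
        shift = M // 2
        blk = SwinBlock(c, heads, M, 2.0, np.random.default_rng(7), shift=shift)
        x = rng.normal(size=(h, w, c))
        got = blk._attention(Tensor(x)).numpy()

        attn = blk.attn
        region = np.zeros((h, w), int)
        bounds = [(0, h - M), (h - M, h - shift), (h - shift, h)]
        for a, (r0, r1) in enumerate(bounds):
            for b, (c0, c1) in enumerate(bounds):
                region[r0:r1, c0:c1] = 3 * a + b
        rolled_region = np.roll(region, (-shift, -shift), (0, 1))
        xs = np.roll(x, (-shift, -shift), (0, 1))
        out_rolled = np.zeros_like(xs)
        for wy in range(h // M):
            for wx in range(w // M):
                sl = (slice(wy * M, wy * M + M), slice(wx * M, wx * M + M))
                tokens = xs[sl].reshape(M * M, c)
                regs = rolled_region[sl].reshape(M * M)
                allowed = regs[:, None] == regs[None, :]
                res = dense_attention_oracle(
                    tokens, attn.qkv.weight.data, attn.qkv.bias.data,
                    attn.proj.weight.data, attn.proj.bias.data,
                    attn.rel_bias.data, attn._rel_index, heads, allowed=allowed)
                out_rolled[sl] = res.reshape(M, M, c)
        want = np.roll(out_rolled, (shift, shift), (0, 1))
        np.testing.assert_allclose(got, want, atol=1e-5)


class TestPatchOps:
    @pytest.mark.parametrize("hw,expect", [((512, 512), (128, 128, 48)),
                                           ((8, 8), (2, 2, 48))])
    def test_partition_shapes(self, hw, expect):
        fm = patch_partition(np.zeros((*hw, 3)), 4)
        assert fm.shape == expect

    def test_partition_constant_image_gives_identical_tokens(self):
        fm = patch_partition(np.full((16, 16, 3), 7.0), 4).numpy()
        assert np.ptp(fm) == 0.0 and fm.flat[0] == 7.0

    def test_partition_rejects_wrong_channels(self):
        with pytest.raises(ValueError):
            patch_partition(np.zeros((16, 16, 1)), 4)

    def test_merge_shape_law(self, rng):
        pm = PatchMerge(8, np.random.default_rng(0))
        out = pm(Tensor(rng.normal(size=(4, 4, 8))))
        assert out.shape == (2, 2, 16)

    def test_merge_matches_gather_concat_multiply_oracle(self):
        """2×2×1 toy with a fixed known reduction matrix, LN bypassed."""
        pm = PatchMerge(1, np.random.default_rng(0))
        W = np.arange(8, dtype=float).reshape(4, 2)
        pm.reduce.weight.data = W
        pm.norm.gamma.data[:] = 1.0
        pm.norm.beta.data[:] = 0.0
        x = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])
        got = pm(Tensor(x)).numpy()
        gathered = np.array([1.0, 3.0, 2.0, 4.0])  # (r0c0, r1c0, r0c1, r1c1)
        normed = (gathered - gathered.mean()) / np.sqrt(gathered.var() + 1e-5)
        np.testing.assert_allclose(got[0, 0], normed @ W, atol=1e-12)

    def test_two_merges_reach_stride_16(self, rng):
        x = Tensor(rng.normal(size=(8, 8, 4)))
        m1 = PatchMerge(4, np.random.default_rng(0))
        m2 = PatchMerge(8, np.random.default_rng(1))
        assert m2(m1(x)).shape == (2, 2, 16)

    def test_expand_shape_law(self, rng):
        pe = PatchExpand(16, np.random.default_rng(0))
        assert pe(Tensor(rng.normal(size=(2, 2, 16)))).shape == (4, 4, 8)

    def test_expand_then_merge_preserves_spatial_dims(self, rng):
        x = Tensor(rng.normal(size=(2, 2, 8)))
        pe = PatchExpand(8, np.random.default_rng(0))
        pm = PatchMerge(4, np.random.default_rng(1))
        assert pm(pe(x)).shape[:2] == (2, 2)

    def test_expand_rearrangement_order_matches_index_oracle(self):
        """1×1×4 toy: place the 2c vector as a row-major 2×2×(c/2) block."""
        pe = PatchExpand(4, np.random.default_rng(0))
        pe.expand.weight.data = np.eye(4, 8)  # output = first 4 dims then 0s
        x = Tensor(np.array([[[10.0, 11.0, 12.0, 13.0]]]))
        got = pe(x).numpy()  # (2, 2, 2)
        v = np.array([10.0, 11.0, 12.0, 13.0]) @ np.eye(4, 8)
        want = np.zeros((2, 2, 2))
        for a in range(2):
            for b in range(2):
                for ch in range(2):
                    want[a, b, ch] = v[a * 4 + b * 2 + ch]
        np.testing.assert_allclose(got, want)

    def test_expand_rejects_odd_channels(self):
        with pytest.raises(ValueError):
            PatchExpand(3, np.random.default_rng(0))


class TestBlocksAndBackbone:
    def test_block_is_identity_with_zeroed_output_projections(self, rng):
        blk = SwinBlock(4, 1, 2, 2.0, np.random.default_rng(0))
        blk.attn.proj.weight.data[:] = 0.0
        blk.attn.proj.bias.data[:] = 0.0
        blk.mlp.fc2.weight.data[:] = 0.0
        blk.mlp.fc2.bias.data[:] = 0.0
        x = rng.normal(size=(4, 4, 4))
        np.testing.assert_allclose(blk(Tensor(x)).numpy(), x, atol=1e-12)

    @pytest.mark.parametrize("hw", [(8, 8), (12, 8), (6, 10)])
    def test_block_preserves_shape(self, hw, rng):
        blk = SwinBlock(4, 1, 4, 2.0, np.random.default_rng(0), shift=2)
        x = Tensor(rng.normal(size=(*hw, 4)))
        assert blk(x).shape == x.shape

    def test_block_pair_equals_sequential_composition(self, rng):
        """A W-MSA block followed by an SW-MSA block equals applying the two
        blocks independently in sequence."""
        r = np.random.default_rng(9)
        b1 = SwinBlock(4, 1, 2, 2.0, r, shift=0)
        b2 = SwinBlock(4, 1, 2, 2.0, r, shift=1)
        x = Tensor(rng.normal(size=(4, 4, 4)))
        np.testing.assert_allclose(b2(b1(x)).numpy(),
                                   b2.forward(b1.forward(x)).numpy())

    @pytest.mark.parametrize("size,C,shapes", [
        (64, 8, [(16, 16, 8), (8, 8, 16), (4, 4, 32), (2, 2, 64)]),
    ])
    def test_backbone_stage_shape_law(self, size, C, shapes):
        cfg = SwinConfig(base_channels=C, depths=(1, 1, 1, 1), window_size=2,
                         heads=(1, 1, 1, 1), mlp_ratio=1.0)
        U = SwinBackbone(cfg)(np.zeros((size, size, 3)))
        assert [U[f"U{i+1}"].shape for i in range(4)] == shapes
        assert [U[f"U{i+1}"].stride for i in range(4)] == [4, 8, 16, 32]

    def test_backbone_deterministic(self, tiny_swin_config, rng):
        img = rng.normal(size=(64, 64, 3))
        bb = SwinBackbone(tiny_swin_config)
        u1 = bb(img)["U4"].numpy()
        u2 = bb(img)["U4"].numpy()
        np.testing.assert_array_equal(u1, u2)

    def test_parameter_count_is_reproducible_function_of_config(self):
        n1 = SwinBackbone(SwinConfig.tiny_test(seed=0)).n_parameters()
        n2 = SwinBackbone(SwinConfig.tiny_test(seed=99)).n_parameters()
        assert n1 == n2 > 0


class TestCostFormula:
    def test_direct_evaluation(self):
        assert wmsa_cost(8, 8, 2, 4) == 5120

    def test_linear_in_spatial_size(self):
        assert wmsa_cost(16, 16, 4, 2) == 4 * wmsa_cost(8, 8, 4, 2)

    def test_quadratic_window_dependence_of_attention_term(self):
        def attn_term(M):
            return wmsa_cost(M, M, 4, M) - 4 * M * M * 16
        assert attn_term(8) / attn_term(4) == (8 / 4) ** 4  # M² window × M² area
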
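"""Attention fusion layer: hand oracles, masking, gradients."""

import numpy as np
import pytest

from gdafusion.encoders import TokenEmbeddingSequence
from gdafusion.fusion import (
    ModalityProjections,
    ProjectionSet,
    fuse,
    fuse_backward,
    fuse_forward,
    mha_backward,
    mha_forward,
    multi_head_attention,
)


from oracles import naive_mha


def tes(emb, mask=None):
    emb = np.asarray(emb, dtype=float)
    mask = np.ones(len(emb), bool) if mask is None else np.asarray(mask, bool)
    return TokenEmbeddingSequence(emb, mask)


class TestMultiHeadAttention:
    def test_hand_computed_softmax_single_head(self):
        # query [1,0] vs keys [1,0],[0,1]: scores [1/sqrt(2), 0] ->
        # weights softmax([0.7071, 0]) = [0.6698, 0.3302]
        query = tes([[1.0, 0.0]])
        kv = tes([[1.0, 0.0], [0.0, 1.0]])
        eye = np.eye(2)
        out, weights = multi_head_attention(
            query, kv, eye, (eye, eye), n_heads=1, return_weights=True
        )
        np.testing.assert_allclose(weights[0, 0], [0.6698, 0.3302], atol=5e-4)
        np.testing.assert_allclose(out[0], [0.6698, 0.3302], atol=5e-4)

    def test_single_valid_key_returns_its_value(self, rng):
        w = {k: rng.standard_normal((4, 4)) for k in "qkv"}
        kv = tes(rng.standard_normal((3, 4)), [False, True, False])
        query = tes(rng.standard_normal((2, 4)))
        out = multi_head_attention(query, kv, w["q"], (w["k"], w["v"]), n_heads=2)
        expected = kv.embeddings[1] @ w["v"]
        for row in out:
            np.testing.assert_allclose(row, expected, atol=1e-10)

    def test_attention_rows_sum_to_one_over_valid_keys(self, rng):
        query = tes(rng.standard_normal((3, 4)))
        kv = tes(rng.standard_normal((5, 4)), [True, True, False, True, False])
        eye = np.eye(4)
        _, weights = multi_head_attention(
            query, kv, eye, (eye, eye), n_heads=2, return_weights=True
        )
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-12)
        assert (weights[..., [2, 4]] == 0).all()

    def test_all_keys_padded_errors(self, rng):
        emb = rng.standard_normal((2, 4))
        with pytest.raises(ValueError, match="valid"):
            mha_forward(
                emb[None], emb[None], np.zeros((1, 2), bool),
                np.eye(4), np.eye(4), np.eye(4), np.eye(4), 1,
            )

    @pytest.mark.parametrize("n_heads", [1, 2, 4])
    def test_matches_naive_oracle(self, rng, n_heads):
        for _ in range(20):
            tq, tk, h = rng.integers(1, 5), rng.integers(1, 5), 8
            xq, xkv = rng.standard_normal((tq, h)), rng.standard_normal((tk, h))
            mask = rng.random(tk) < 0.7
            if not mask.any():
                mask[0] = True
            ws = [rng.standard_normal((h, h)) for _ in range(4)]
            out = multi_head_attention(
                tes(xq), tes(xkv, mask), ws[0], (ws[1], ws[2]), n_heads, w_o=ws[3]
            )
            expected = naive_mha(xq, xkv, mask, *ws, n_heads)
            np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_permuting_keys_leaves_output_unchanged(self, rng):
        import itertools

        h = 4
        xq = rng.standard_normal((2, h))
        xkv = rng.standard_normal((4, h))
        mask = np.array([True, True, True, False])
        ws = [rng.standard_normal((h, h)) for _ in range(4)]
        base = multi_head_attention(
            tes(xq), tes(xkv, mask), ws[0], (ws[1], ws[2]), 2, w_o=ws[3]
        )
        for perm in itertools.permutations(range(4)):
            out = multi_head_attention(
                tes(xq), tes(xkv[list(perm)], mask[list(perm)]),
                ws[0], (ws[1], ws[2]), 2, w_o=ws[3],
            )
            np.testing.assert_allclose(out, base, atol=1e-10)

    def test_constant_values_dominate_any_query(self, rng):
        # if all value projections are equal the attention mixture is moot
        h = 6
        xkv = np.tile(rng.standard_normal(h), (4, 1))
        xq = rng.standard_normal((3, h))
        ws = [rng.standard_normal((h, h)) for _ in range(4)]
        out = multi_head_attention(
            tes(xq), tes(xkv), ws[0], (ws[1], ws[2]), 3, w_o=ws[3]
        )
        expected = (xkv[0] @ ws[2]) @ ws[3]
        for row in out:
            np.testing.assert_allclose(row, expected, atol=1e-9)


def random_projection_set(rng, h, n_heads=2):
    def mp():
        return ModalityProjections(*(rng.standard_normal((h, h)) for _ in range(4)))

    return ProjectionSet(protein=mp(), text=mp(), n_heads=n_heads)


class TestFuse:
    def test_identical_inputs_shared_projections_collapse(self, rng):
        h = 4
        mp = ModalityProjections(*(rng.standard_normal((h, h)) for _ in range(4)))
        shared = ProjectionSet(
            protein=mp,
            text=ModalityProjections(mp.w_q, mp.w_k, mp.w_v, mp.w_o),
            n_heads=2,
        )
        g = tes(rng.standard_normal((3, h)))
        d = tes(g.embeddings.copy())
        fp = fuse(g, d, shared)
        self_attn = multi_head_attention(
            g, g, mp.w_q, (mp.w_k, mp.w_v), 2, w_o=mp.w_o
        )
        np.testing.assert_allclose(fp.g_star.embeddings, self_attn, atol=1e-10)
        np.testing.assert_allclose(fp.d_star.embeddings, self_attn, atol=1e-10)

    def test_token_counts_preserved(self, rng):
        proj = random_projection_set(rng, 6, 2)
        g, d = tes(rng.standard_normal((3, 6))), tes(rng.standard_normal((5, 6)))
        fp = fuse(g, d, proj)
        assert fp.g_star.n_tokens == 3
        assert fp.d_star.n_tokens == 5

    def test_matches_term_by_term_oracle(self, rng):
        # G* = (self + cross)/2 with the naive loop oracle for each term
        h = 6
        proj = random_projection_set(rng, h, 2)
        s, t = proj.protein, proj.text
        xg, xd = rng.standard_normal((3, h)), rng.standard_normal((4, h))
        gm = np.array([True, True, False])
        dm = np.array([True, False, True, True])
        g_star, d_star, _ = fuse_forward(xg[None], xd[None], gm[None], dm[None], proj)
        g_expect = 0.5 * (
            naive_mha(xg, xg, gm, s.w_q, s.w_k, s.w_v, s.w_o, 2)
            + naive_mha(xg, xd, dm, s.w_q, t.w_k, t.w_v, s.w_o, 2)
        )
        g_expect[~gm] = 0.0
        d_expect = 0.5 * (
            naive_mha(xd, xd, dm, t.w_q, t.w_k, t.w_v, t.w_o, 2)
            + naive_mha(xd, xg, gm, t.w_q, s.w_k, s.w_v, t.w_o, 2)
        )
        d_expect[~dm] = 0.0
        np.testing.assert_allclose(g_star[0], g_expect, atol=1e-6)
        np.testing.assert_allclose(d_star[0], d_expect, atol=1e-6)

    def test_eight_heads_match_per_head_slices(self, rng):
        # multi-head output = per-head single-head attention on slices,
        # concatenated, then output-projected
        h, n_heads = 16, 8
        xq, xkv = rng.standard_normal((3, h)), rng.standard_normal((4, h))
        mask = np.ones(4, bool)
        ws = [rng.standard_normal((h, h)) for _ in range(4)]
        out = multi_head_attention(
            tes(xq), tes(xkv, mask), ws[0], (ws[1], ws[2]), n_heads, w_o=ws[3]
        )
        expected = naive_mha(xq, xkv, mask, *ws, n_heads)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_padded_rows_do_not_influence_valid_outputs(self, rng):
        h = 6
        proj = random_projection_set(rng, h, 2)
        xg = rng.standard_normal((4, h))
        xd = rng.standard_normal((3, h))
        gm = np.array([True, True, True, False])
        dm = np.array([True, True, False])
        g1, d1, _ = fuse_forward(xg[None], xd[None], gm[None], dm[None], proj)
        xg2, xd2 = xg.copy(), xd.copy()
        xg2[~gm] = 1e6  # garbage in padded rows
        xd2[~dm] = -1e6
        g2, d2, _ = fuse_forward(xg2[None], xd2[None], gm[None], dm[None], proj)
        np.testing.assert_allclose(g1, g2, atol=1e-9)
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestGradients:
    def test_mha_backward_matches_finite_differences(self, rng):
        h, n_heads = 4, 2
        xq = rng.standard_normal((2, 3, h))
        xkv = rng.standard_normal((2, 4, h))
        kv_mask = np.array([[True, True, True, False], [True, False, True, True]])
        weights = {k: rng.standard_normal((h, h)) * 0.5
                   for k in ("w_q", "w_k", "w_v", "w_o")}
        target = rng.standard_normal((2, 3, h))

        def loss_of(ws, q, kv):
            out, _ = mha_forward(q, kv, kv_mask, ws["w_q"], ws["w_k"],
                                 ws["w_v"], ws["w_o"], n_heads)
            return 0.5 * np.sum((out - target) ** 2)

        out, cache = mha_forward(xq, xkv, kv_mask, weights["w_q"], weights["w_k"],
                                 weights["w_v"], weights["w_o"], n_heads)
        d_xq, d_xkv, grads = mha_backward(out - target, cache)
        eps = 1e-6
        for name in weights:
            w = weights[name]
            for idx in [(0, 0), (1, 2), (3, 3)]:
                orig = w[idx]
                w[idx] = orig + eps
                up = loss_of(weights, xq, xkv)
                w[idx] = orig - eps
                down = loss_of(weights, xq, xkv)
                w[idx] = orig
                np.testing.assert_allclose(
                    grads[name][idx], (up - down) / (2 * eps), rtol=1e-4, atol=1e-7
                )
        for arr, grad in ((xq, d_xq), (xkv, d_xkv)):
            idx = (0, 1, 2)
            orig = arr[idx]
            arr[idx] = orig + eps
            up = loss_of(weights, xq, xkv)
            arr[idx] = orig - eps
            down = loss_of(weights, xq, xkv)
            arr[idx] = orig
            np.testing.assert_allclose(
                grad[idx], (up - down) / (2 * eps), rtol=1e-4, atol=1e-7
            )

    def test_fuse_backward_matches_finite_differences(self, rng):
        h = 4
        proj = random_projection_set(rng, h, 2)
        xg = rng.standard_normal((2, 3, h))
        xd = rng.standard_normal((2, 2, h))
        gm = np.ones((2, 3), bool)
        dm = np.ones((2, 2), bool)
        tg = rng.standard_normal((2, 3, h))
        td = rng.standard_normal((2, 2, h))

        def loss():
            gs, ds, _ = fuse_forward(xg, xd, gm, dm, proj)
            return 0.5 * (np.sum((gs - tg) ** 2) + np.sum((ds - td) ** 2))

        gs, ds, cache = fuse_forward(xg, xd, gm, dm, proj)
        _, _, grads = fuse_backward(gs - tg, ds - td, cache)
        eps = 1e-6
        for key, w in (("protein.w_q", proj.protein.w_q),
                       ("text.w_v", proj.text.w_v),
                       ("protein.w_o", proj.protein.w_o)):
            for idx in [(0, 1), (2, 3)]:
                orig = w[idx]
                w[idx] = orig + eps
                up = loss()
                w[idx] = orig - eps
                down = loss()
                w[idx] = orig
                np.testing.assert_allclose(
                    grads[key][idx], (up - down) / (2 * eps), rtol=1e-4, atol=1e-7
                )
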
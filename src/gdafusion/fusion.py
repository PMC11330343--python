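"""Bimodal attention fusion layer.

A single fusion layer updates each modality's token matrix as the average of
its self-attention and its cross-attention onto the other modality::

    G* = 1/2 [ MHA(Q_s, K_s, V_s) + MHA(Q_s, K_t, V_t) ]
    D* = 1/2 [ MHA(Q_t, K_t, V_t) + MHA(Q_t, K_s, V_s) ]

where Q/K/V are linear projections of the protein (s) and text (t) token
matrices and MHA is standard multi-head scaled dot-product attention
(scores QK'/sqrt(d_head), softmax over valid key positions, heads
concatenated, one output map per modality shared by both terms). The layer
output is exactly this average — no residual, layer norm or feed-forward
sublayer — and exactly one layer is applied, to constrain capacity.

Everything here is plain numpy. Forward passes return caches from which
:func:`mha_backward` / :func:`fuse_backward` compute exact analytic
gradients with respect to inputs and all projection weights; the contrastive
pre-training loop is built on these.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .encoders import TokenEmbeddingSequence

PROTEIN, TEXT = "protein", "text"


@dataclass
class ModalityProjections:
    """Query/key/value/output maps of one modality, each H_fusion x H_fusion."""

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray

    def validate(self, h: int) -> None:
        for name in ("w_q", "w_k", "w_v", "w_o"):
            w = getattr(self, name)
            if w.shape != (h, h):
                raise ValueError(f"{name} has shape {w.shape}, expected ({h}, {h})")
            if not np.isfinite(w).all():
                raise ValueError(f"{name} contains non-finite entries")


@dataclass
class ProjectionSet:
    """Two distinct sets of projection matrices, one per modality."""

    protein: ModalityProjections
    text: ModalityProjections
    n_heads: int = 8

    def __post_init__(self) -> None:
        h = self.protein.w_q.shape[0]
        if h % self.n_heads != 0:
            raise ValueError(
                f"H_fusion={h} not divisible by n_heads={self.n_heads}"
            )
        self.protein.validate(h)
        self.text.validate(h)

    @property
    def h_fusion(self) -> int:
        return int(self.protein.w_q.shape[0])

    @classmethod
    def initialize(
        cls, h_fusion: int, n_heads: int = 8, seed: int = 0
    ) -> "ProjectionSet":
        """Seeded uniform init in +-sqrt(1/H_fusion)."""
        rng = np.random.default_rng(seed)
        bound = np.sqrt(1.0 / h_fusion)

        def w() -> np.ndarray:
            return rng.uniform(-bound, bound, size=(h_fusion, h_fusion))

        return cls(
            protein=ModalityProjections(w(), w(), w(), w()),
            text=ModalityProjections(w(), w(), w(), w()),
            n_heads=n_heads,
        )


@dataclass
class FusedPair:
    """Fused token matrices for one (gene, disease) pair."""

    g_star: TokenEmbeddingSequence
    d_star: TokenEmbeddingSequence


# ---------------------------------------------------------------------------
# batched multi-head attention, forward and backward
# ---------------------------------------------------------------------------

def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    b, t, h = x.shape
    return x.reshape(b, t, n_heads, h // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    b, nh, t, d = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, nh * d)


def mha_forward(
    xq: np.ndarray,
    xkv: np.ndarray,
    kv_mask: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
    w_o: np.ndarray,
    n_heads: int,
    q_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, dict]:
    """Masked multi-head attention on batched token matrices.

    Parameters are batched as (B, T, H); masks as boolean (B, T). Padded key
    positions are excluded from the softmax (score -inf); padded query rows
    emit zero vectors. Returns (output, cache) where cache feeds
    :func:`mha_backward`.
    """
    xq = np.asarray(xq, dtype=float)
    xkv = np.asarray(xkv, dtype=float)
    kv_mask = np.asarray(kv_mask, dtype=bool)
    if not kv_mask.any(axis=1).all():
        raise ValueError("every batch element needs >= 1 valid key position")
    b, tq, h = xq.shape
    d_head = h // n_heads
    q = _split_heads(xq @ w_q, n_heads)
    k = _split_heads(xkv @ w_k, n_heads)
    v = _split_heads(xkv @ w_v, n_heads)
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(d_head)
    neg = np.finfo(float).min
    scores = np.where(kv_mask[:, None, None, :], scores, neg)
    scores -= scores.max(axis=-1, keepdims=True)
    attn = np.exp(scores)
    attn = np.where(kv_mask[:, None, None, :], attn, 0.0)
    attn /= attn.sum(axis=-1, keepdims=True)
    o_heads = attn @ v
    o = _merge_heads(o_heads)
    out = o @ w_o
    if q_mask is not None:
        out = out * np.asarray(q_mask, dtype=float)[:, :, None]
    cache = {
        "xq": xq, "xkv": xkv, "q": q, "k": k, "v": v, "attn": attn, "o": o,
        "w_q": w_q, "w_k": w_k, "w_v": w_v, "w_o": w_o,
        "n_heads": n_heads, "d_head": d_head, "q_mask": q_mask,
    }
    return out, cache


def mha_backward(
    d_out: np.ndarray, cache: dict
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Gradients of masked MHA w.r.t. query input, kv input, and weights."""
    n_heads, d_head = cache["n_heads"], cache["d_head"]
    q_mask = cache["q_mask"]
    d_out = np.asarray(d_out, dtype=float)
    if q_mask is not None:
        d_out = d_out * np.asarray(q_mask, dtype=float)[:, :, None]
    o, attn, q, k, v = cache["o"], cache["attn"], cache["q"], cache["k"], cache["v"]
    d_wo = np.einsum("bth,btp->hp", o, d_out)
    d_o = d_out @ cache["w_o"].T
    d_o_heads = _split_heads(d_o, n_heads)
    d_attn = d_o_heads @ v.transpose(0, 1, 3, 2)
    d_v = attn.transpose(0, 1, 3, 2) @ d_o_heads
    d_scores = attn * (d_attn - (d_attn * attn).sum(axis=-1, keepdims=True))
    d_scores /= np.sqrt(d_head)
    d_q = d_scores @ k
    d_k = d_scores.transpose(0, 1, 3, 2) @ q
    d_q_flat = _merge_heads(d_q)
    d_k_flat = _merge_heads(d_k)
    d_v_flat = _merge_heads(d_v)
    xq, xkv = cache["xq"], cache["xkv"]
    grads = {
        "w_q": np.einsum("bti,bto->io", xq, d_q_flat),
        "w_k": np.einsum("bti,bto->io", xkv, d_k_flat),
        "w_v": np.einsum("bti,bto->io", xkv, d_v_flat),
        "w_o": d_wo,
    }
    d_xq = d_q_flat @ cache["w_q"].T
    d_xkv = d_k_flat @ cache["w_k"].T + d_v_flat @ cache["w_v"].T
    return d_xq, d_xkv, grads


def multi_head_attention(
    query_src: TokenEmbeddingSequence,
    kv_src: TokenEmbeddingSequence,
    proj_q: np.ndarray,
    proj_kv: tuple[np.ndarray, np.ndarray],
    n_heads: int,
    w_o: Optional[np.ndarray] = None,
    return_weights: bool = False,
):
    """Single-instance masked MHA over token-embedding sequences.

    ``proj_q`` is the query map, ``proj_kv`` the (key, value) maps; ``w_o``
    defaults to the identity. Returns the updated token matrix (and,
    optionally, the per-head attention weight tensor).
    """
    w_k, w_v = proj_kv
    h = query_src.hidden_size
    if w_o is None:
        w_o = np.eye(h)
    if not kv_src.mask.any():
        raise ValueError("kv_src has no valid tokens")
    out, cache = mha_forward(
        query_src.embeddings[None],
        kv_src.embeddings[None],
        kv_src.mask[None],
        proj_q, w_k, w_v, w_o,
        n_heads,
        q_mask=query_src.mask[None],
    )
    if return_weights:
        return out[0], cache["attn"][0]
    return out[0]


# ---------------------------------------------------------------------------
# the fusion layer
# ---------------------------------------------------------------------------

def fuse_forward(
    xg: np.ndarray,
    xd: np.ndarray,
    g_mask: np.ndarray,
    d_mask: np.ndarray,
    proj: ProjectionSet,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Batched fusion layer on projected token matrices.

    Returns (g_star, d_star, cache); g_star/d_star have the same token
    counts as the inputs, with padded rows zeroed.
    """
    s, t, nh = proj.protein, proj.text, proj.n_heads
    o_ss, c_ss = mha_forward(xg, xg, g_mask, s.w_q, s.w_k, s.w_v, s.w_o, nh, g_mask)
    o_st, c_st = mha_forward(xg, xd, d_mask, s.w_q, t.w_k, t.w_v, s.w_o, nh, g_mask)
    o_tt, c_tt = mha_forward(xd, xd, d_mask, t.w_q, t.w_k, t.w_v, t.w_o, nh, d_mask)
    o_ts, c_ts = mha_forward(xd, xg, g_mask, t.w_q, s.w_k, s.w_v, t.w_o, nh, d_mask)
    g_star = 0.5 * (o_ss + o_st)
    d_star = 0.5 * (o_tt + o_ts)
    cache = {"ss": c_ss, "st": c_st, "tt": c_tt, "ts": c_ts}
    return g_star, d_star, cache


def fuse_backward(
    d_gstar: np.ndarray, d_dstar: np.ndarray, cache: dict
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Gradients of the fusion layer w.r.t. both inputs and all projections.

    Weight gradients are keyed ``"protein.w_q"`` ... ``"text.w_o"``.
    """
    gxq1, gxkv1, g1 = mha_backward(0.5 * d_gstar, cache["ss"])
    gxq2, gxkv2, g2 = mha_backward(0.5 * d_gstar, cache["st"])
    gxq3, gxkv3, g3 = mha_backward(0.5 * d_dstar, cache["tt"])
    gxq4, gxkv4, g4 = mha_backward(0.5 * d_dstar, cache["ts"])
    d_xg = gxq1 + gxkv1 + gxq2 + gxkv4
    d_xd = gxkv2 + gxq3 + gxkv3 + gxq4
    grads = {
        "protein.w_q": g1["w_q"] + g2["w_q"],
        "protein.w_k": g1["w_k"] + g4["w_k"],
        "protein.w_v": g1["w_v"] + g4["w_v"],
        "protein.w_o": g1["w_o"] + g2["w_o"],
        "text.w_q": g3["w_q"] + g4["w_q"],
        "text.w_k": g2["w_k"] + g3["w_k"],
        "text.w_v": g2["w_v"] + g3["w_v"],
        "text.w_o": g3["w_o"] + g4["w_o"],
    }
    return d_xg, d_xd, grads


def fuse(
    g: TokenEmbeddingSequence,
    d: TokenEmbeddingSequence,
    proj: ProjectionSet,
) -> FusedPair:
    """Apply the single fusion layer to one (gene, disease) token pair."""
    if g.hidden_size != proj.h_fusion or d.hidden_size != proj.h_fusion:
        raise ValueError(
            f"inputs must be projected to the fusion dimension {proj.h_fusion}"
        )
    g_star, d_star, _ = fuse_forward(
        g.embeddings[None], d.embeddings[None], g.mask[None], d.mask[None], proj
    )
    return FusedPair(
        g_star=TokenEmbeddingSequence(g_star[0], g.mask.copy(), g.source_id),
        d_star=TokenEmbeddingSequence(d_star[0], d.mask.copy(), d.source_id),
    )


__all__ = [
    "ModalityProjections",
    "ProjectionSet",
    "FusedPair",
    "mha_forward",
    "mha_backward",
    "multi_head_attention",
    "fuse_forward",
    "fuse_backward",
    "fuse",
]
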
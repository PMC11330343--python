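"""Pooling of fused token matrices into per-entity vectors.

Two strategies: ``cls`` takes the begin token (index 0) of each side;
``pooling`` takes the mean of the token embeddings. The mean is taken over
valid (unpadded) tokens only — padding is an artifact of batching, not of
the method, so it must not dilute the pooled vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import FusedPair

STRATEGIES = ("cls", "pooling")


@dataclass
class PooledPair:
    """Pooled gene/disease vectors with the strategy that produced them."""

    g_vec: np.ndarray
    d_vec: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g_vec).all() and np.isfinite(self.d_vec).all()):
            raise ValueError("pooled vectors must be finite")


def pool_tokens(
    tokens: np.ndarray, mask: np.ndarray, strategy: str
) -> np.ndarray:
    """Pool a (B, T, H) token batch to (B, H) under a strategy."""
    if strategy == "cls":
        return tokens[:, 0, :]
    if strategy == "pooling":
        m = np.asarray(mask, dtype=float)
        return (tokens * m[:, :, None]).sum(axis=1) / m.sum(axis=1)[:, None]
    raise ValueError(f"unknown aggregation strategy {strategy!r}")


def pool_backward(
    d_vec: np.ndarray, mask: np.ndarray, n_tokens: int, strategy: str
) -> np.ndarray:
    """Distribute a (B, H) pooled gradient back over (B, T, H) tokens."""
    b, h = d_vec.shape
    out = np.zeros((b, n_tokens, h))
    if strategy == "cls":
        out[:, 0, :] = d_vec
        return out
    if strategy == "pooling":
        m = np.asarray(mask, dtype=float)
        out += d_vec[:, None, :] * (m / m.sum(axis=1)[:, None])[:, :, None]
        return out
    raise ValueError(f"unknown aggregation strategy {strategy!r}")


def aggregate(fp: FusedPair, strategy: str = "pooling") -> PooledPair:
    """Compress a fused pair into one vector per side."""
    if strategy not in STRATEGIES:
        raise ValueError(
            f"unknown aggregation strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    g = pool_tokens(fp.g_star.embeddings[None], fp.g_star.mask[None], strategy)[0]
    d = pool_tokens(fp.d_star.embeddings[None], fp.d_star.mask[None], strategy)[0]
    return PooledPair(g_vec=g, d_vec=d, strategy=strategy)


__all__ = ["STRATEGIES", "PooledPair", "pool_tokens", "pool_backward", "aggregate"]
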
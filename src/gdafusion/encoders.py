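"""Token encoders: the contract, a deterministic toy encoder, and projections.

The fusion layer consumes per-token embedding matrices from two unimodal
encoders — one for protein sequences (one token per residue) and one for
disease descriptions (one token per word). In production those encoders are
large pre-trained language models loaded through :class:`ExternalEncoderAdapter`;
for fully offline work the :class:`ToyEncoder` produces deterministic
hash-seeded embeddings in which a token's vector depends only on its local
k-mer context, so planted sequence motifs and description keywords map to
reproducible, nearly orthogonal directions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .records import PROTEIN_ALPHABET

BEGIN_TOKEN = "<s>"


@dataclass(frozen=True)
class EncoderSpec:
    """Declares an encoder's modality, width and token budget.

    ``trainable`` records whether encoder weights receive gradients during
    pre-training; the toy encoder is always frozen, external adapters default
    to trainable.
    """

    modality: str  # "protein" | "text"
    hidden_size: int = 64
    max_tokens: int = 128
    trainable: bool = False

    def __post_init__(self) -> None:
        if self.modality not in ("protein", "text"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.max_tokens < 2:
            raise ValueError("max_tokens must be >= 2")


@dataclass
class TokenEmbeddingSequence:
    """A T x H matrix of token embeddings with a validity mask.

    Padded positions carry zero vectors; at least one token must be valid.
    """

    embeddings: np.ndarray
    mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be a T x H matrix")
        if self.mask.shape != (self.embeddings.shape[0],):
            raise ValueError("mask length must equal token count")
        if self.embeddings.shape[0] < 1 or not self.mask.any():
            raise ValueError("at least one valid token required")
        if not np.isfinite(self.embeddings).all():
            raise ValueError("embeddings must be finite")

    @property
    def n_tokens(self) -> int:
        return int(self.embeddings.shape[0])

    @property
    def hidden_size(self) -> int:
        return int(self.embeddings.shape[1])


def _stable_seed(modality: str, kmer: str, vocab_seed: int) -> int:
    digest = hashlib.blake2b(
        f"{modality}|{kmer}|{vocab_seed}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") % (2**63)


@lru_cache(maxsize=1_000_000)
def _toy_vector(modality: str, kmer: str, vocab_seed: int, hidden_size: int):
    rng = np.random.default_rng(_stable_seed(modality, kmer, vocab_seed))
    v = rng.standard_normal(hidden_size)
    v /= np.linalg.norm(v)
    v.setflags(write=False)
    return v


def toy_embed_token(
    modality: str, kmer: str, vocab_seed: int, hidden_size: int
) -> np.ndarray:
    """Deterministic unit-norm embedding of a k-mer (or word) token.

    The vector is drawn from a unit normal seeded with a stable hash of
    (modality, k-mer, vocab_seed) and scaled to unit norm, so identical
    tokens always map to identical vectors and distinct tokens are nearly
    orthogonal in expectation at realistic widths.
    """
    if modality == "protein" and kmer != BEGIN_TOKEN:
        bad = set(kmer) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"k-mer {kmer!r} outside the protein alphabet: {bad}")
    return _toy_vector(modality, kmer, int(vocab_seed), int(hidden_size))


def tokenize(modality: str, raw: str) -> list[str]:
    """Tokenize raw input per modality, with a prepended begin token.

    Protein: one token per residue, the token identity being the k-mer that
    starts at that residue (k is applied by the encoder). Text: lowercased
    whitespace tokens stripped of surrounding punctuation.
    """
    if not raw or not raw.strip():
        raise ValueError("cannot encode empty input")
    if modality == "protein":
        return [BEGIN_TOKEN] + list(raw.upper())
    words = [w.strip(".,;:!?()[]\"'").lower() for w in raw.split()]
    words = [w for w in words if w]
    if not words:
        raise ValueError("no tokens left after cleaning")
    return [BEGIN_TOKEN] + words


class ToyEncoder:
    """Deterministic offline encoder emitting hash-seeded token embeddings.

    For proteins each residue token is embedded by the k-mer (default k=3)
    starting at its position, so shared subsequences produce identical token
    vectors; for text each word is its own token. Purely functional in
    (spec, raw, vocab_seed).
    """

    def __init__(self, spec: EncoderSpec, vocab_seed: int = 0, k: int = 3):
        self.spec = spec
        self.vocab_seed = int(vocab_seed)
        self.k = int(k)

    def encode(self, raw: str, source_id: str = "") -> TokenEmbeddingSequence:
        tokens = tokenize(self.spec.modality, raw)[: self.spec.max_tokens]
        if self.spec.modality == "protein":
            seq = raw.upper()
            keys = [BEGIN_TOKEN] + [
                seq[i : i + self.k] for i in range(len(seq))
            ]
            keys = keys[: self.spec.max_tokens]
        else:
            keys = tokens
        emb = np.stack(
            [
                toy_embed_token(
                    self.spec.modality, key, self.vocab_seed, self.spec.hidden_size
                )
                for key in keys
            ]
        )
        mask = np.ones(len(keys), dtype=bool)
        return TokenEmbeddingSequence(embeddings=emb, mask=mask, source_id=source_id)


def encode(
    spec: EncoderSpec, raw: str, vocab_seed: int = 0, k: int = 3, source_id: str = ""
) -> TokenEmbeddingSequence:
    """Encode raw input under a spec with the deterministic toy encoder."""
    return ToyEncoder(spec, vocab_seed=vocab_seed, k=k).encode(raw, source_id)


class ExternalEncoderAdapter:
    """Adapter contract for pre-trained language-model encoders.

    Wraps a checkpoint (e.g. a protein language model for sequences or a
    biomedical text model for descriptions) and exposes the same
    ``encode(raw) -> TokenEmbeddingSequence`` surface as the toy encoder.
    Loading checkpoints requires an inference runtime and downloaded weights,
    so adapters are specified but intentionally outside the offline test
    surface.
    """

    def __init__(
        self,
        spec: EncoderSpec,
        checkpoint: str,
        backend: Optional[object] = None,
    ):
        self.spec = spec
        self.checkpoint = checkpoint
        self.backend = backend

    def encode(self, raw: str, source_id: str = "") -> TokenEmbeddingSequence:
        if self.backend is None:
            raise RuntimeError(
                f"no backend loaded for checkpoint {self.checkpoint!r}; "
                "external language-model encoders require an inference runtime"
            )
        out = self.backend.encode(raw)  # pragma: no cover - exercised via stubs
        return TokenEmbeddingSequence(
            embeddings=out["embeddings"], mask=out["mask"], source_id=source_id
        )


def project_to_fusion_dim(
    tes: TokenEmbeddingSequence, w_in: np.ndarray
) -> TokenEmbeddingSequence:
    """Map each token embedding into the shared fusion space (H_mod -> H_fusion).

    Padded rows stay zero and the mask is carried through unchanged.
    """
    w_in = np.asarray(w_in, dtype=float)
    if w_in.ndim != 2 or w_in.shape[0] != tes.hidden_size:
        raise ValueError(
            f"projection shape {w_in.shape} incompatible with hidden size "
            f"{tes.hidden_size}"
        )
    projected = tes.embeddings @ w_in
    projected[~tes.mask] = 0.0
    return TokenEmbeddingSequence(
        embeddings=projected, mask=tes.mask.copy(), source_id=tes.source_id
    )


__all__ = [
    "BEGIN_TOKEN",
    "EncoderSpec",
    "TokenEmbeddingSequence",
    "ToyEncoder",
    "ExternalEncoderAdapter",
    "encode",
    "tokenize",
    "toy_embed_token",
    "project_to_fusion_dim",
]
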
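"""Contrastive pre-training of the fusion layer with the infoNCE objective.

Each known (gene, disease) association is a positive pair. Within a
mini-batch the pooled gene vector is the anchor, its paired pooled disease
vector the positive, and the other diseases in the batch — excluding any
that are known positives of the anchor gene — the negatives. The per-anchor
loss is::

    L = -log  exp(G . K+ / tau) / sum_{i=0..k} exp(G . K_i / tau)

with the positive included in the denominator (index 0) and similarity the
raw dot product, no cosine normalization. tau defaults to 0.07. Only the
gene side anchors; a symmetric disease-anchored term is an extension point,
not implemented.

Optimization is Adam on the input maps and fusion projections (the toy
encoder is frozen), with exact analytic gradients assembled from the
fusion-layer backward pass. Deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .aggregation import pool_backward, pool_tokens
from .encoders import EncoderSpec, TokenEmbeddingSequence, ToyEncoder
from .fusion import fuse_backward, fuse_forward
from .params import FusionParameters
from .records import AssociationDataset, AssociationPair

logger = logging.getLogger("gdafusion")


@dataclass
class ContrastiveConfig:
    """Hyper-parameters of the contrastive pre-training phase."""

    temperature: float = 0.07
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class ContrastiveBatch:
    """Anchor/positive/negative pooled vectors for one mini-batch."""

    anchors: np.ndarray                 # B x H
    positives: np.ndarray               # B x H
    negatives: list[np.ndarray]         # per anchor: k_i x H, k_i >= 1

    def __post_init__(self) -> None:
        if len(self.negatives) != len(self.anchors):
            raise ValueError("one negative group per anchor required")
        for neg in self.negatives:
            if len(neg) < 1:
                raise ValueError("each anchor needs >= 1 negative")


def info_nce(batch: ContrastiveBatch, temperature: float = 0.07) -> float:
    """Mean infoNCE loss over a batch, log-sum-exp stabilized."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    losses = []
    for g, pos, negs in zip(batch.anchors, batch.positives, batch.negatives):
        sims = np.concatenate(([g @ pos], negs @ g)) / temperature
        if not np.isfinite(sims).all():
            raise FloatingPointError("non-finite similarity in contrastive batch")
        m = sims.max()
        losses.append(-(sims[0] - m - np.log(np.exp(sims - m).sum())))
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# entity encoding cache and the batched pair forward pass
# ---------------------------------------------------------------------------

class EntityCache:
    """Frozen token embeddings for every gene and disease in a dataset."""

    def __init__(
        self,
        dataset: AssociationDataset,
        protein_encoder: ToyEncoder,
        text_encoder: ToyEncoder,
    ):
        self.protein_encoder = protein_encoder
        self.text_encoder = text_encoder
        self.gene: dict[str, TokenEmbeddingSequence] = {
            gid: protein_encoder.encode(rec.sequence, source_id=gid)
            for gid, rec in dataset.genes.items()
        }
        self.disease: dict[str, TokenEmbeddingSequence] = {
            did: text_encoder.encode(rec.description, source_id=did)
            for did, rec in dataset.diseases.items()
        }


def _pad_stack(
    seqs: Sequence[TokenEmbeddingSequence],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length token sequences into (B, T_max, H) + mask."""
    t_max = max(s.n_tokens for s in seqs)
    h = seqs[0].hidden_size
    emb = np.zeros((len(seqs), t_max, h))
    mask = np.zeros((len(seqs), t_max), dtype=bool)
    for i, s in enumerate(seqs):
        emb[i, : s.n_tokens] = np.where(s.mask[:, None], s.embeddings, 0.0)
        mask[i, : s.n_tokens] = s.mask
    return emb, mask


def forward_pooled_batch(
    pairs: Sequence[AssociationPair],
    cache: EntityCache,
    params: FusionParameters,
    strategy: str = "pooling",
    with_cache: bool = False,
):
    """Encode -> project -> fuse -> pool a batch of pairs.

    Returns pooled gene vectors (B, H_fusion) and disease vectors (B, H_fusion),
    plus an opaque backward cache when requested.
    """
    g_seqs = [cache.gene[p.gene_id] for p in pairs]
    d_seqs = [cache.disease[p.disease_id] for p in pairs]
    eg, g_mask = _pad_stack(g_seqs)
    ed, d_mask = _pad_stack(d_seqs)
    xg = eg @ params.w_in_protein
    xd = ed @ params.w_in_text
    g_star, d_star, fcache = fuse_forward(xg, xd, g_mask, d_mask, params.proj)
    g_vec = pool_tokens(g_star, g_mask, strategy)
    d_vec = pool_tokens(d_star, d_mask, strategy)
    if not with_cache:
        return g_vec, d_vec
    bcache = {
        "eg": eg, "ed": ed, "g_mask": g_mask, "d_mask": d_mask,
        "fcache": fcache, "strategy": strategy,
        "tg": eg.shape[1], "td": ed.shape[1],
    }
    return g_vec, d_vec, bcache


def backward_pooled_batch(
    d_gvec: np.ndarray,
    d_dvec: np.ndarray,
    bcache: dict,
) -> dict[str, np.ndarray]:
    """Gradients of the pooled vectors w.r.t. every trainable weight."""
    strategy = bcache["strategy"]
    d_gstar = pool_backward(d_gvec, bcache["g_mask"], bcache["tg"], strategy)
    d_dstar = pool_backward(d_dvec, bcache["d_mask"], bcache["td"], strategy)
    d_xg, d_xd, grads = fuse_backward(d_gstar, d_dstar, bcache["fcache"])
    grads["w_in_protein"] = np.einsum("bti,bto->io", bcache["eg"], d_xg)
    grads["w_in_text"] = np.einsum("bti,bto->io", bcache["ed"], d_xd)
    return grads


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def _iter_epoch_batches(
    positives: list[AssociationPair],
    batch_size: int,
    rng: np.random.Generator,
) -> Iterator[list[AssociationPair]]:
    order = rng.permutation(len(positives))
    for start in range(0, len(order), batch_size):
        chunk = [positives[i] for i in order[start : start + batch_size]]
        if len(chunk) >= 2:
            yield chunk


def _negative_structure(
    batch: Sequence[AssociationPair],
    positive_keys: set[tuple[str, str]],
) -> tuple[list[int], list[list[int]]]:
    """For each anchor index, the in-batch disease indices usable as negatives.

    A disease at position j is a negative for anchor i when j != i and
    (gene_i, disease_j) is not a known positive pair. Anchors without any
    usable negative are skipped (with a warning).
    """
    used, neg_indices = [], []
    for i, anchor in enumerate(batch):
        negs = [
            j for j, other in enumerate(batch)
            if j != i and (anchor.gene_id, other.disease_id) not in positive_keys
        ]
        if negs:
            used.append(i)
            neg_indices.append(negs)
        else:
            logger.warning(
                "anchor %s skipped: no usable in-batch negatives", anchor.gene_id
            )
    return used, neg_indices


def build_batches(
    dataset: AssociationDataset,
    encoders: tuple[ToyEncoder, ToyEncoder],
    params: FusionParameters,
    aggregation: str = "pooling",
    batch_size: int = 32,
    seed: int = 0,
) -> Iterator[ContrastiveBatch]:
    """Yield one epoch of contrastive batches of pooled vectors.

    ``encoders`` is the (protein, text) encoder pair; pooled vectors are
    computed under the supplied fusion parameters.
    """
    cache = EntityCache(dataset, *encoders)
    positives = dataset.positive_pairs
    positive_keys = {p.key for p in positives}
    rng = np.random.default_rng(seed)
    for batch in _iter_epoch_batches(positives, batch_size, rng):
        used, neg_indices = _negative_structure(batch, positive_keys)
        if not used:
            continue
        g_vec, d_vec = forward_pooled_batch(batch, cache, params, aggregation)
        yield ContrastiveBatch(
            anchors=g_vec[used],
            positives=d_vec[used],
            negatives=[d_vec[negs] for negs in neg_indices],
        )


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

class _Adam:
    """Minimal Adam over a dict of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, flat: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            flat[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class PretrainResult:
    """Trained parameters plus the per-epoch mean loss trajectory."""

    params: FusionParameters
    loss_trajectory: list[float] = field(default_factory=list)
    config: Optional[ContrastiveConfig] = None


def _batch_loss_and_grads(
    batch: list[AssociationPair],
    cache: EntityCache,
    params: FusionParameters,
    positive_keys: set[tuple[str, str]],
    temperature: float,
    aggregation: str,
) -> tuple[Optional[float], Optional[dict[str, np.ndarray]]]:
    used, neg_indices = _negative_structure(batch, positive_keys)
    if not used:
        return None, None
    g_vec, d_vec, bcache = forward_pooled_batch(
        batch, cache, params, aggregation, with_cache=True
    )
    b = len(batch)
    sims = g_vec @ d_vec.T / temperature
    if not np.isfinite(sims).all():
        raise FloatingPointError("non-finite similarity during pre-training")
    # valid[i, j]: candidate j participates in anchor i's softmax
    valid = np.zeros((b, b), dtype=bool)
    for i, negs in zip(used, neg_indices):
        valid[i, i] = True
        valid[i, negs] = True
    logits = np.where(valid, sims, -np.inf)
    row_max = np.zeros(b)
    row_max[used] = logits[used].max(axis=1)
    expl = np.exp(logits - row_max[:, None], where=valid, out=np.zeros((b, b)))
    denom = expl.sum(axis=1)
    prob = np.zeros((b, b))
    prob[used] = expl[used] / denom[used, None]
    losses = -np.log(prob[used, used])
    loss = float(losses.mean())
    d_sims = prob.copy()
    d_sims[used, used] -= 1.0
    d_sims[[i for i in range(b) if i not in used]] = 0.0
    d_sims /= temperature * len(used)
    d_gvec = d_sims @ d_vec
    d_dvec = d_sims.T @ g_vec
    grads = backward_pooled_batch(d_gvec, d_dvec, bcache)
    return loss, grads


def pretrain(
    dataset: AssociationDataset,
    config: ContrastiveConfig,
    protein_encoder: Optional[ToyEncoder] = None,
    text_encoder: Optional[ToyEncoder] = None,
    h_fusion: int = 64,
    n_heads: int = 8,
    aggregation: str = "pooling",
    init_params: Optional[FusionParameters] = None,
) -> PretrainResult:
    """Minimize the mean infoNCE loss over the dataset's positive pairs.

    Returns the trained parameters and the per-epoch mean loss. Encoders
    default to toy encoders at hidden size 64. Deterministic given
    ``config.seed`` (and a fixed thread count in the BLAS backend).
    """
    if protein_encoder is None:
        protein_encoder = ToyEncoder(EncoderSpec("protein"))
    if text_encoder is None:
        text_encoder = ToyEncoder(EncoderSpec("text"))
    cache = EntityCache(dataset, protein_encoder, text_encoder)
    positives = dataset.positive_pairs
    if len(positives) < 2:
        raise ValueError("pre-training needs >= 2 positive pairs")
    positive_keys = {p.key for p in positives}
    params = (
        init_params.copy()
        if init_params is not None
        else FusionParameters.initialize(
            protein_encoder.spec.hidden_size,
            text_encoder.spec.hidden_size,
            h_fusion=h_fusion,
            n_heads=n_heads,
            seed=config.seed,
        )
    )
    flat = params.as_flat_dict()
    opt = _Adam(config.learning_rate)
    rng = np.random.default_rng(config.seed)
    trajectory: list[float] = []
    for epoch in range(config.epochs):
        epoch_losses = []
        for batch in _iter_epoch_batches(positives, config.batch_size, rng):
            loss, grads = _batch_loss_and_grads(
                batch, cache, params, positive_keys,
                config.temperature, aggregation,
            )
            if loss is None:
                continue
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"pre-training diverged at epoch {epoch}: loss={loss}"
                )
            opt.step(flat, grads)
            epoch_losses.append(loss)
        trajectory.append(float(np.mean(epoch_losses)))
        logger.debug("epoch %d: mean infoNCE loss %.4f", epoch, trajectory[-1])
    return PretrainResult(params=params, loss_trajectory=trajectory, config=config)


__all__ = [
    "ContrastiveConfig",
    "ContrastiveBatch",
    "EntityCache",
    "PretrainResult",
    "info_nce",
    "build_batches",
    "forward_pooled_batch",
    "backward_pooled_batch",
    "pretrain",
]
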
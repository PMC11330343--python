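"""scikit-learn style estimators composing the full GDA pipeline.

:class:`FusionEmbedder` is a transformer: ``fit`` contrastively pre-trains
the attention-fusion layer on the positive pairs it is given, ``transform``
maps (gene_id, disease_id) pairs to pooled multi-modal feature vectors.
:class:`GDAClassifier` stacks the embedder with the boosted-tree head and
exposes ``fit`` / ``predict_proba`` / ``predict``. Both follow sklearn
conventions (``get_params``/``set_params``, clone-ability, fitted
attributes with a trailing underscore) so they compose with sklearn
pipelines and model selection.

X is an (n, 2) array-like of string identifier pairs; the gene/disease
record maps are constructor parameters, mirroring how corpus-level lookups
are configured in other estimator APIs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .encoders import EncoderSpec, ToyEncoder
from .params import FusionParameters
from .predict import FusionState, HeadConfig, featurize_cached, fit_head
from .pretrain import ContrastiveConfig, EntityCache, pretrain
from .records import (
    AssociationDataset,
    AssociationPair,
    DiseaseRecord,
    GeneRecord,
)


def _as_gene_records(genes: dict) -> dict[str, GeneRecord]:
    return {
        k: v if isinstance(v, GeneRecord) else GeneRecord(gene_id=k, sequence=v)
        for k, v in genes.items()
    }


def _as_disease_records(diseases: dict) -> dict[str, DiseaseRecord]:
    return {
        k: v
        if isinstance(v, DiseaseRecord)
        else DiseaseRecord(disease_id=k, name=k, description=v)
        for k, v in diseases.items()
    }


def _check_pairs(X) -> list[tuple[str, str]]:
    X = np.asarray(X, dtype=object)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(
            f"X must be an (n, 2) array of (gene_id, disease_id) pairs, "
            f"got shape {X.shape}"
        )
    return [(str(g), str(d)) for g, d in X]


class FusionEmbedder(TransformerMixin, BaseEstimator):
    """Contrastively pre-trained attention-fusion feature transformer.

    Parameters
    ----------
    genes, diseases : dict
        Identifier -> record (or raw sequence/description string) maps.
    pretrain : bool
        If False, skip contrastive training and use the seeded random
        initialization (the "no pre-training" ablation arm).
    """

    def __init__(
        self,
        genes: Optional[dict] = None,
        diseases: Optional[dict] = None,
        h_fusion: int = 64,
        n_heads: int = 8,
        aggregation: str = "pooling",
        encoder_hidden: int = 64,
        protein_max_tokens: int = 128,
        text_max_tokens: int = 64,
        vocab_seed: int = 0,
        kmer: int = 3,
        pretrain: bool = True,
        temperature: float = 0.07,
        learning_rate: float = 1e-3,
        epochs: int = 20,
        batch_size: int = 128,
        random_state: int = 0,
    ):
        self.genes = genes
        self.diseases = diseases
        self.h_fusion = h_fusion
        self.n_heads = n_heads
        self.aggregation = aggregation
        self.encoder_hidden = encoder_hidden
        self.protein_max_tokens = protein_max_tokens
        self.text_max_tokens = text_max_tokens
        self.vocab_seed = vocab_seed
        self.kmer = kmer
        self.pretrain = pretrain
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _encoders(self) -> tuple[ToyEncoder, ToyEncoder]:
        p = ToyEncoder(
            EncoderSpec("protein", self.encoder_hidden, self.protein_max_tokens),
            vocab_seed=self.vocab_seed, k=self.kmer,
        )
        t = ToyEncoder(
            EncoderSpec("text", self.encoder_hidden, self.text_max_tokens),
            vocab_seed=self.vocab_seed,
        )
        return p, t

    def _dataset(self, pairs: list[AssociationPair]) -> AssociationDataset:
        if self.genes is None or self.diseases is None:
            raise ValueError("genes and diseases maps must be provided")
        return AssociationDataset(
            genes=_as_gene_records(self.genes),
            diseases=_as_disease_records(self.diseases),
            pairs=pairs,
        )

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y=None) -> "FusionEmbedder":
        keys = _check_pairs(X)
        if y is None:
            labels = [1] * len(keys)
        else:
            labels = [int(v) for v in np.asarray(y).ravel()]
            if len(labels) != len(keys):
                raise ValueError("X and y length mismatch")
        seen: set[tuple[str, str]] = set()
        pos_pairs = []
        for (g, d), lab in zip(keys, labels):
            if lab == 1 and (g, d) not in seen:
                seen.add((g, d))
                pos_pairs.append(AssociationPair(gene_id=g, disease_id=d, label=1))
        dataset = self._dataset(pos_pairs)
        protein_enc, text_enc = self._encoders()
        if self.pretrain:
            result = pretrain(
                dataset,
                ContrastiveConfig(
                    temperature=self.temperature,
                    learning_rate=self.learning_rate,
                    epochs=self.epochs,
                    batch_size=self.batch_size,
                    seed=self.random_state,
                ),
                protein_encoder=protein_enc,
                text_encoder=text_enc,
                h_fusion=self.h_fusion,
                n_heads=self.n_heads,
                aggregation=self.aggregation,
            )
            self.params_ = result.params
            self.loss_trajectory_ = result.loss_trajectory
        else:
            self.params_ = FusionParameters.initialize(
                protein_enc.spec.hidden_size,
                text_enc.spec.hidden_size,
                h_fusion=self.h_fusion,
                n_heads=self.n_heads,
                seed=self.random_state,
            )
            self.loss_trajectory_ = []
        self.state_ = FusionState(
            params=self.params_,
            protein_encoder=protein_enc,
            text_encoder=text_enc,
            aggregation=self.aggregation,
        )
        self._cache = EntityCache(self._dataset([]), protein_enc, text_enc)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "state_")
        keys = _check_pairs(X)
        pairs = []
        for g, d in keys:
            if g not in self._cache.gene:
                raise KeyError(f"unknown gene_id {g!r}")
            if d not in self._cache.disease:
                raise KeyError(f"unknown disease_id {d!r}")
            pairs.append(AssociationPair(gene_id=g, disease_id=d, label=0))
        return featurize_cached(pairs, self.state_, self._cache)


class GDAClassifier(ClassifierMixin, BaseEstimator):
    """Full GDA scorer: fusion embedding + boosted-tree prediction head.

    ``fit(X, y)`` pre-trains the fusion layer on the label-1 pairs of the
    training data, featurizes all training pairs with the frozen result,
    and fits the tree head; ``predict_proba`` returns association
    probabilities.
    """

    def __init__(
        self,
        genes: Optional[dict] = None,
        diseases: Optional[dict] = None,
        h_fusion: int = 64,
        n_heads: int = 8,
        aggregation: str = "pooling",
        encoder_hidden: int = 64,
        protein_max_tokens: int = 128,
        text_max_tokens: int = 64,
        vocab_seed: int = 0,
        kmer: int = 3,
        pretrain: bool = True,
        temperature: float = 0.07,
        learning_rate: float = 1e-3,
        epochs: int = 20,
        batch_size: int = 128,
        max_depth: int = 6,
        num_leaves: Optional[int] = None,
        boosting_mode: str = "gbdt",
        head_learning_rate: float = 0.1,
        n_trees: int = 100,
        random_state: int = 0,
    ):
        self.genes = genes
        self.diseases = diseases
        self.h_fusion = h_fusion
        self.n_heads = n_heads
        self.aggregation = aggregation
        self.encoder_hidden = encoder_hidden
        self.protein_max_tokens = protein_max_tokens
        self.text_max_tokens = text_max_tokens
        self.vocab_seed = vocab_seed
        self.kmer = kmer
        self.pretrain = pretrain
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_depth = max_depth
        self.num_leaves = num_leaves
        self.boosting_mode = boosting_mode
        self.head_learning_rate = head_learning_rate
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y) -> "GDAClassifier":
        y = np.asarray(y, dtype=int).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("fit requires both classes present in y")
        self.embedder_ = FusionEmbedder(
            genes=self.genes,
            diseases=self.diseases,
            h_fusion=self.h_fusion,
            n_heads=self.n_heads,
            aggregation=self.aggregation,
            encoder_hidden=self.encoder_hidden,
            protein_max_tokens=self.protein_max_tokens,
            text_max_tokens=self.text_max_tokens,
            vocab_seed=self.vocab_seed,
            kmer=self.kmer,
            pretrain=self.pretrain,
            temperature=self.temperature,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            random_state=self.random_state,
        ).fit(X, y)
        features = self.embedder_.transform(X)
        self.head_ = fit_head(
            features,
            y,
            HeadConfig(
                max_depth=self.max_depth,
                num_leaves=self.num_leaves,
                boosting_mode=self.boosting_mode,
                learning_rate=self.head_learning_rate,
                n_trees=self.n_trees,
            ),
            seed=self.random_state,
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "head_")
        p1 = self.head_.score(self.embedder_.transform(X))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


__all__ = ["FusionEmbedder", "GDAClassifier"]
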
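"""Fine-tuning head: pooled multi-modal features scored by boosted trees.

A pair's feature vector is the concatenation of its pooled fused gene and
disease vectors (gene half first, length 2 * H_fusion), computed with
frozen pre-trained fusion parameters. The score is the additive tree
ensemble's output through the logistic link, a probability p in [0, 1].
Defaults follow the reference configuration: max depth 6, num_leaves
2^(depth-1) = 32, gradient-boosted trees, learning rate 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from lightgbm import LGBMClassifier

from .encoders import EncoderSpec, ToyEncoder
from .params import FusionParameters
from .pretrain import EntityCache, forward_pooled_batch
from .records import AssociationDataset, AssociationPair

BOOSTING_MODES = ("gbdt", "rf", "dart")


@dataclass
class FusionState:
    """Everything needed to turn a (gene, disease) pair into features."""

    params: FusionParameters
    protein_encoder: ToyEncoder
    text_encoder: ToyEncoder
    aggregation: str = "pooling"

    @classmethod
    def default(
        cls, params: FusionParameters, aggregation: str = "pooling"
    ) -> "FusionState":
        return cls(
            params=params,
            protein_encoder=ToyEncoder(EncoderSpec("protein")),
            text_encoder=ToyEncoder(EncoderSpec("text")),
            aggregation=aggregation,
        )


@dataclass
class HeadConfig:
    """Boosted-tree head configuration (thin contract over the backend)."""

    max_depth: int = 6
    num_leaves: Optional[int] = None  # defaults to 2^(max_depth - 1)
    boosting_mode: str = "gbdt"
    learning_rate: float = 0.1
    n_trees: int = 100

    def __post_init__(self) -> None:
        if self.boosting_mode not in BOOSTING_MODES:
            raise ValueError(
                f"boosting_mode must be one of {BOOSTING_MODES}, "
                f"got {self.boosting_mode!r}"
            )
        if self.num_leaves is None:
            self.num_leaves = 2 ** (self.max_depth - 1)


def featurize(
    pairs: Sequence[AssociationPair],
    state: FusionState,
    dataset: AssociationDataset,
    batch_size: int = 64,
) -> np.ndarray:
    """Features for each pair: encode -> project -> fuse -> pool -> concat.

    Gene vector first. Deterministic; unknown identifiers raise KeyError.
    """
    for p in pairs:
        if p.gene_id not in dataset.genes:
            raise KeyError(f"unknown gene_id {p.gene_id!r}")
        if p.disease_id not in dataset.diseases:
            raise KeyError(f"unknown disease_id {p.disease_id!r}")
    cache = EntityCache(dataset, state.protein_encoder, state.text_encoder)
    return featurize_cached(pairs, state, cache, batch_size=batch_size)


def featurize_cached(
    pairs: Sequence[AssociationPair],
    state: FusionState,
    cache: EntityCache,
    batch_size: int = 64,
) -> np.ndarray:
    """Like :func:`featurize` but reusing a prebuilt entity cache."""
    blocks = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        g_vec, d_vec = forward_pooled_batch(
            chunk, cache, state.params, state.aggregation
        )
        blocks.append(np.hstack([g_vec, d_vec]))
    return np.vstack(blocks)


class TreeEnsembleModel:
    """Additive decision-tree ensemble with a logistic-link [0, 1] score.

    Thin contract over a gradient-boosting backend: what callers may rely
    on is the depth/leaf-count limits, the boosting mode switch, and that
    ``score`` returns calibrated probabilities. Serializes to a plain-text
    model file plus a JSON config.
    """

    def __init__(self, config: HeadConfig, booster: "lightgbm.Booster"):
        self.config = config
        self._booster = booster

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        n_feat = self._booster.num_feature()
        if features.ndim != 2 or features.shape[1] != n_feat:
            raise ValueError(
                f"feature matrix has shape {features.shape}, expected (n, {n_feat})"
            )
        return np.clip(self._booster.predict(features), 0.0, 1.0)

    def tree_depths(self) -> list[int]:
        """Actual depth of every tree (for introspection)."""
        dump = self._booster.dump_model()

        def depth(node: dict) -> int:
            if "leaf_value" in node and "left_child" not in node:
                return 0
            return 1 + max(depth(node["left_child"]), depth(node["right_child"]))

        return [depth(t["tree_structure"]) for t in dump["tree_info"]]

    def save(self, directory) -> None:
        from dataclasses import asdict
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "model.txt").write_text(self._booster.model_to_string())
        (directory / "head_config.json").write_text(
            json.dumps(asdict(self.config), indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, directory) -> "TreeEnsembleModel":
        from pathlib import Path

        import lightgbm

        directory = Path(directory)
        config = HeadConfig(
            **json.loads((directory / "head_config.json").read_text())
        )
        booster = lightgbm.Booster(
            model_str=(directory / "model.txt").read_text()
        )
        return cls(config=config, booster=booster)


def fit_head(
    features: np.ndarray,
    labels: Sequence[int],
    config: Optional[HeadConfig] = None,
    seed: int = 0,
) -> TreeEnsembleModel:
    """Train the boosted-tree head on frozen pooled features.

    Deterministic given the seed and single-threaded training.
    """
    config = config or HeadConfig()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("fit_head requires both classes present in labels")
    extra = {}
    if config.boosting_mode == "rf":
        # the rf mode requires row subsampling to be meaningful
        extra = {"bagging_fraction": 0.8, "bagging_freq": 1}
    booster = LGBMClassifier(
        boosting_type=config.boosting_mode,
        max_depth=config.max_depth,
        num_leaves=config.num_leaves,
        learning_rate=config.learning_rate,
        n_estimators=config.n_trees,
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbosity=-1,
        **extra,
    )
    booster.fit(np.asarray(features, dtype=float), labels)
    return TreeEnsembleModel(config=config, booster=booster.booster_)


def score_pairs(
    model: TreeEnsembleModel,
    pairs: Sequence[AssociationPair],
    features: np.ndarray,
) -> list[AssociationPair]:
    """Attach model scores to pairs (one score in [0, 1] per pair)."""
    if len(pairs) != len(features):
        raise ValueError(
            f"{len(pairs)} pairs but {len(features)} feature rows"
        )
    scores = model.score(features)
    return [replace(p, score=float(s)) for p, s in zip(pairs, scores)]


def rank_for_disease(
    model: TreeEnsembleModel,
    state: FusionState,
    dataset: AssociationDataset,
    disease_id: str,
    candidate_genes: Sequence[str],
    top_n: int = 10,
) -> list[AssociationPair]:
    """Rank candidate genes for one disease by predicted score.

    Descending by score, ties broken by lexicographically smaller gene_id;
    the first ``top_n`` scored pairs are returned.
    """
    if not candidate_genes:
        raise ValueError("candidate gene set is empty")
    if disease_id not in dataset.diseases:
        raise KeyError(f"unknown disease_id {disease_id!r}")
    for g in candidate_genes:
        if g not in dataset.genes:
            raise KeyError(f"unknown gene_id {g!r}")
    pairs = [
        AssociationPair(gene_id=g, disease_id=disease_id, label=0)
        for g in candidate_genes
    ]
    features = featurize(pairs, state, dataset)
    scored = score_pairs(model, pairs, features)
    scored.sort(key=lambda p: (-p.score, p.gene_id))
    return scored[:top_n]


__all__ = [
    "BOOSTING_MODES",
    "FusionState",
    "HeadConfig",
    "TreeEnsembleModel",
    "featurize",
    "featurize_cached",
    "fit_head",
    "score_pairs",
    "rank_for_disease",
]
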
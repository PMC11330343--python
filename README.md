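# gdafusion

Attention-fusion representation learning and boosted-tree scoring for
gene–disease association (GDA) prediction.

## The problem

Linking genes to the diseases they influence is a core task in systems
biology: given a gene's protein product and a textual description of a
disease, estimate the probability `p ∈ [0, 1]` that the pair is
associated. The two inputs live in different modalities — an amino-acid
sequence and biomedical prose — and simple concatenation of their
embeddings discards the mutual context between them. `gdafusion`
implements a bimodal pipeline for this task:

1. **Encoders** turn the protein sequence and the disease description into
   per-token embedding matrices (pluggable; a deterministic toy encoder is
   provided for fully offline work, and an adapter interface for
   pre-trained protein/text language models).
2. A **fusion layer** updates each modality's tokens as the average of its
   self-attention and its cross-attention onto the other modality:

       G* = ½ [ MHA(Q_s, K_s, V_s) + MHA(Q_s, K_t, V_t) ]
       D* = ½ [ MHA(Q_t, K_t, V_t) + MHA(Q_t, K_s, V_s) ]

   with 8-head scaled dot-product attention and per-modality projections.
3. **Aggregation** pools fused tokens to one vector per entity (CLS token
   or masked mean pooling).
4. **Contrastive pre-training** minimizes an infoNCE objective
   (`τ = 0.07`) over known associations: each pooled gene vector anchors
   its paired disease vector against in-batch negatives, pulling
   associated pairs together in the shared space.
5. A **gradient-boosted tree head** (LightGBM; depth 6, `2^(K−1)` leaves,
   gbdt/rf/dart modes) scores the concatenated pooled pair features
   through a logistic link.

Evaluation follows field practice: ROC-AUC, AUPR (average precision),
F-max and accuracy under five-fold cross-validation with equal-count
non-overlapping negative sampling, plus category-stratified AUC with
frequency correlations and top-N gene ranking per disease.

A synthetic-corpus generator with planted latent-cluster structure
(cluster-exclusive sequence motifs and description keywords) makes every
stage testable end to end with no downloads; see `docs/methods.md` for the
model, its assumptions, and what the synthetic experiments do and do not
show.

## Worked example

```python
import numpy as np
from gdafusion import GDAClassifier, SyntheticConfig, cross_validate, generate

# a 200-gene x 200-disease corpus with 4 latent clusters
dataset, truth = generate(SyntheticConfig(seed=42))
print(len(dataset.pairs))                      # 800  (400 positive, 400 negative)

# five-fold cross-validation of the full pipeline
result = cross_validate(dataset, k=5, seed=0)
print({k: round(v, 3) for k, v in result.mean.summary().items()})
# {'auc': 0.963, 'aupr': 0.958, 'f_max': 0.927, 'accuracy': 0.907}
```

The mean held-out AUC of ≈ 0.96 says the pipeline recovers the planted
cluster structure: pairs from the same latent cluster (true associations)
are ranked above cross-cluster pairs almost everywhere. The estimators are
scikit-learn compatible:

```python
X = np.array([[p.gene_id, p.disease_id] for p in dataset.pairs], dtype=object)
y = np.array([p.label for p in dataset.pairs])
clf = GDAClassifier(genes=dict(dataset.genes), diseases=dict(dataset.diseases),
                    random_state=0).fit(X, y)
clf.predict_proba(X[:2])[:, 1]                 # association probabilities
```

Or from the shell:

```bash
gdafusion simulate --out data/ --seed 7
gdafusion pretrain --data data/ --out ckpt/ --seed 7
gdafusion finetune --checkpoint ckpt/ --data data/ --out model/ --seed 7
gdafusion predict  --model model/ --checkpoint ckpt/ --data data/ \
                   --pairs pairs.tsv --out scores.tsv
gdafusion evaluate --data data/ --out eval/ --seed 7
```

Every stage writes a `run_manifest.json` (config echo, seed, input
digests) beside its outputs; identical config + seed reproduces identical
artifacts byte for byte.

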
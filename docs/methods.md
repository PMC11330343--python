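# Methods

## The model

`gdafusion` scores gene–disease associations (GDA) from two modalities: a
gene's protein sequence and a disease's textual description. The pipeline
has four stages.

**Encoders.** Each modality is turned into a per-token embedding matrix
`T x H` with a validity mask. For proteins there is one token per residue
(plus a prepended begin token); for text one token per lowercased word
(plus a begin token). In production these matrices come from pre-trained
language models through the adapter interface; for all offline work the
deterministic *toy encoder* embeds each token by a stable hash of its local
context — the k-mer starting at the residue (k = 3) for proteins, the word
itself for text — drawing a unit-norm vector from a hash-seeded normal
generator. Identical contexts always map to identical vectors and distinct
contexts are nearly orthogonal in expectation, so shared motifs and
keywords are linearly detectable after pooling. Per-modality learned input
maps `W_in` (`H_modality x H_fusion`) reconcile encoder widths into one
fusion space; the paper-facing encoders have different widths and the
method is agnostic to how they meet, so a learned linear map per modality
is the simplest faithful choice.

**Fusion layer.** With protein tokens `G` and text tokens `D` projected to
`H_fusion`, one attention layer computes

    G* = 1/2 [ MHA(Q_s, K_s, V_s) + MHA(Q_s, K_t, V_t) ]
    D* = 1/2 [ MHA(Q_t, K_t, V_t) + MHA(Q_t, K_s, V_s) ]

where `Q_s = G W_q^s`, `K_s = G W_k^s`, `V_s = G W_v^s` and likewise with
the text projections (`t`) on `D`: each side's updated tokens are the
average of its self-attention and its cross-attention onto the other
modality. MHA is standard multi-head scaled dot-product attention
(`QK'/sqrt(d_head)`, softmax over valid key positions, 8 heads by default,
heads concatenated, one output map per modality shared by the self and
cross terms). Deliberate literal choices: no residual connection, layer
normalization, feed-forward sublayer, or dropout — the defining equations
specify the bare average, and exactly one layer is applied to constrain
capacity. Padded keys are masked to −inf before the softmax; padded query
rows emit zero vectors.

**Aggregation.** Fused token matrices are pooled to one vector per entity
either by the CLS strategy (token 0, the begin token) or mean pooling
(default, the stronger variant in the reference ablation). The mean is
taken over *valid* tokens only, a documented deviation from the unmasked
sequence mean: padding is an artifact of batching, not of the method, and
must not dilute the pooled vector.

**Contrastive pre-training.** Known associations are positive pairs. Within
a mini-batch of positive pairs, each pooled gene vector `G` anchors an
infoNCE term

    L = −log exp(G·K₊/τ) / Σ_{i=0..k} exp(G·K_i/τ)

with its own pooled disease vector as `K₊`, the other in-batch disease
vectors as negatives `K_i` (excluding diseases that are known positives of
the anchor gene), the positive included in the denominator, similarity the
raw dot product, and τ = 0.07. Anchoring is gene-side only; a symmetric
disease-anchored term is an extension point, not implemented. Negatives
are in-batch (the sampling pool is otherwise unspecified in the method's
description); anchors left without a usable negative are skipped with a
warning.

**Prediction head.** A pair's feature vector is the concatenation of its
pooled fused gene and disease vectors (gene first, length `2·H_fusion`),
computed with frozen pre-trained fusion weights. A gradient-boosted
decision-tree ensemble (LightGBM behind a thin contract) maps features to
a probability via the logistic link. Defaults: max depth 6, `num_leaves =
2^(depth−1) = 32`, gbdt boosting (rf and dart switchable), learning rate
0.1, 100 trees. Tree count and depth are deliberately distinct parameters
(`n_trees`, `max_depth`) because the source description overloads one
symbol for both. Joint fine-tuning of encoders with the tree head is not
meaningful (trees pass no gradients) and is not attempted.

## Optimization

No tensor framework is used: forward and backward passes of the fusion
layer, pooling and the infoNCE objective are implemented directly in numpy
with analytic gradients (checked against central finite differences in the
test suite at relative error < 1e-5). The optimizer is Adam
(β = 0.9/0.999, ε = 1e-8) over the two input maps and the eight projection
matrices; the toy encoders are frozen. Defaults: learning rate 1e-3 (the
top of the method's stated 1e-4..1e-3 range — the small corpora used here
need the faster end to converge in 20 epochs), batch size 128 (large
batches give each anchor ~100 in-batch negatives, which stabilizes the
objective at this scale), 20 epochs. Projection weights initialize
uniformly in ±sqrt(1/H_fusion) with a fixed seed. Training is
deterministic given the config seed and a fixed BLAS thread count.

## Evaluation

Metrics follow fixed conventions: predicted-positive is `score >=
threshold` (boundary inclusive); ROC-AUC is the Mann–Whitney statistic
with ties credited 0.5; AUPR is the average-precision estimator (mean
precision at each positive's rank), not trapezoidal PR interpolation,
which is biased; F-max maximizes F1 over thresholds at the unique scores
plus +inf, returning the smallest maximizing threshold on ties; accuracy
is reported at threshold 0.5 (the reference tables never state their
accuracy threshold). All three headline metrics are fuzz-tested to 1e-9
against independent brute-force oracles.

Cross-validation assigns stratified folds (sizes within one pair, positive
counts within one pair of proportional — plain random partitioning is
noisier at desk scale) and retrains the *entire* pipeline, contrastive
pre-training included, inside each training fold, so no information leaks
from test pairs into the features. Category-stratified evaluation computes
per-category AUC from a user-supplied disease→category map, flags
single-class categories as undefined, and reports Pearson correlations of
AUC against both log10 pair count and distinct-disease count (the
"frequency" axis is ambiguous between the two, so both are given).

## The synthetic corpus

The generator emulates the latent structure a GDA corpus needs for the
pipeline to be learnable offline: genes and diseases are assigned
uniformly to C latent clusters; each cluster owns an exclusive protein
motif planted at a random position of its genes' otherwise-random
sequences, and an exclusive keyword set salted into its diseases'
filler-word descriptions (filler comes from a fixed 200-word pronounceable
lexicon so text embeddings overlap realistically). True associations are
within-cluster; observed labels can be corrupted by cross-cluster leakage
and by label flips with probability ε. Negatives are drawn uniformly from
the *cross-cluster* complement, so the clean label is exactly the
same-cluster indicator and noise enters only through ε and leakage; a
uniformly sampled negative set would silently contain structurally
positive pairs and impose an unstated accuracy ceiling. `motif_length = 0`
is the null configuration and disables the description keywords as well.

Default study conditions, chosen once to emulate a compact family-
structured corpus: 200 genes, 200 diseases, 4 clusters, 60-residue
sequences with a 16-residue motif (protein families share conserved
domains of this relative size), 40-word descriptions with half the words
drawn from 3 cluster keywords (disease families share core clinical
vocabulary), 2 positives per gene, equal-count negatives, no noise. Under
these conditions the pooled toy embeddings of same-cluster entities have a
positive mean-cosine gap over cross-cluster ones (`expected_separability`
certifies this before any model is blamed), and the full pipeline recovers
the structure (5-CV mean AUC ≈ 0.96).

What the corpus does *not* emulate: realistic protein evolution (motifs
are exact, not degenerate), clinical language, degree-skewed association
networks, or database-scale pair counts. Passing tests therefore
demonstrate that the implementation recovers plantable signal end to end
and that its components match their defining equations — not that the
method attains its published performance on real corpora, which requires
the original databases and large pre-trained encoders.

## Problem sizes

Desk-scale experiment sizes are package choices: the recovery experiment
runs 5-fold CV on 800 pairs with per-fold pre-training (20 epochs); the
null control permutes labels and repeats a single held-out fold over 5
seeds; the ablation compares pre-trained vs randomly initialized fusion
features on noisy corpora over 5 seeds. The CLI determinism check uses a
24x24 corpus.

## Known limitations

* The toy encoder is a stand-in with hash-random geometry; conclusions
  about encoder quality (the protein/text encoder comparisons of the
  reference work) cannot be drawn from it.
* Only the infoNCE objective is implemented; the loss-function slot is an
  extension point but the five alternatives are not provided.
* In-batch negatives only; no memory bank or corpus-wide sampling.
* The external-PLM adapter is an interface contract; loading checkpoints
  is outside the offline test surface.
* `AUPR` uses average precision; comparisons against trapezoidal-PR
  numbers from other software will differ slightly, especially at small n.
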
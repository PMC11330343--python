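"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately use naive loops and enumeration, never the package's
vectorized implementations, so they can serve as independent references.
"""

import numpy as np


def naive_mha(xq, xkv, kv_mask, w_q, w_k, w_v, w_o, n_heads):
    """Loop-based single-instance oracle for masked multi-head attention."""
    tq, h = xq.shape
    d = h // n_heads
    out = np.zeros((tq, h))
    q_full, k_full, v_full = xq @ w_q, xkv @ w_k, xkv @ w_v
    for i in range(tq):
        merged = []
        for head in range(n_heads):
            sl = slice(head * d, (head + 1) * d)
            q = q_full[i, sl]
            scores = np.array([
                q @ k_full[j, sl] / np.sqrt(d) if kv_mask[j] else -np.inf
                for j in range(len(xkv))
            ])
            weights = np.exp(scores - scores[kv_mask].max())
            weights[~kv_mask] = 0.0
            weights /= weights.sum()
            merged.append(weights @ v_full[:, sl])
        out[i] = np.concatenate(merged) @ w_o
    return out


def naive_fuse(xg, xd, g_mask, d_mask, proj):
    """Term-by-term oracle for the fusion layer equations."""
    s, t = proj.protein, proj.text
    nh = proj.n_heads
    g_star = 0.5 * (
        naive_mha(xg, xg, g_mask, s.w_q, s.w_k, s.w_v, s.w_o, nh)
        + naive_mha(xg, xd, d_mask, s.w_q, t.w_k, t.w_v, s.w_o, nh)
    )
    d_star = 0.5 * (
        naive_mha(xd, xd, d_mask, t.w_q, t.w_k, t.w_v, t.w_o, nh)
        + naive_mha(xd, xg, g_mask, t.w_q, s.w_k, s.w_v, t.w_o, nh)
    )
    g_star[~g_mask] = 0.0
    d_star[~d_mask] = 0.0
    return g_star, d_star


def auc_oracle(labels, scores):
    """Pairwise concordance count: concordant + half ties over pos*neg."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def aupr_oracle(labels, scores):
    """Rank enumeration: precision at each positive's rank, averaged."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp, precisions = 0, []
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
            precisions.append(tp / rank)
    return sum(precisions) / sum(labels)


def fmax_oracle(labels, scores):
    """Threshold enumeration over unique scores plus +inf."""
    best = 0.0
    for t in list(set(scores)) + [float("inf")]:
        tp = sum(1 for y, s in zip(labels, scores) if y == 1 and s >= t)
        fp = sum(1 for y, s in zip(labels, scores) if y == 0 and s >= t)
        fn = sum(1 for y, s in zip(labels, scores) if y == 1 and s < t)
        if 2 * tp + fp + fn:
            best = max(best, 2 * tp / (2 * tp + fp + fn))
    return best


def random_metric_instances(n_instances=200, max_n=30, seed=0, with_ties=True):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(2, max_n + 1))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[int(rng.integers(n))] = 1
        if labels.sum() == n:
            labels[int(rng.integers(n))] = 0
        if with_ties and rng.random() < 0.5:
            scores = rng.integers(0, 5, size=n) / 4.0  # heavy ties
        else:
            scores = rng.random(n)
        yield labels.tolist(), scores.tolist()
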
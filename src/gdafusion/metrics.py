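"""Evaluation statistics: ROC-AUC, AUPR, F-max, accuracy, CV driver.

Conventions fixed here (and relied on by tests):

* a sample is predicted positive iff ``score >= threshold`` (inclusive);
* ROC-AUC is the Mann-Whitney statistic — concordant pairs plus half the
  ties over n_pos * n_neg — equal to the area under the threshold-swept
  ROC curve;
* AUPR is the average-precision estimator (mean over positives, in score-
  descending order, of the precision at each positive's rank), not a
  trapezoidal PR interpolation, which is biased;
* F-max maximizes F1 over thresholds at the unique score values plus +inf,
  returning the smallest maximizing threshold on ties;
* accuracy is reported at threshold 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return labels, scores


def confusion_counts(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with score >= threshold predicted positive."""
    labels, scores = _validate(labels, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)  # midranks give ties 0.5 credit
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision: mean over positives of precision at their rank.

    Ties are broken by stable input order under a descending sort.
    """
    labels, scores = _validate(labels, scores)
    if labels.sum() == 0:
        raise ValueError("aupr requires >= 1 positive")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    ranks = np.arange(1, len(labels) + 1)
    precision_at = cum_tp / ranks
    return float(precision_at[sorted_labels == 1].mean())


def f_max(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[float, float]:
    """Maximum F1 over all thresholds; returns (F_max, threshold).

    Candidate thresholds are the unique score values plus +inf; on ties the
    smallest maximizing threshold is returned.
    """
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("f_max requires >= 1 positive")
    best_f, best_t = -1.0, np.inf
    for t in sorted(np.unique(scores)) + [np.inf]:
        tp, fp, _, fn = confusion_counts(labels, scores, t)
        denom = 2 * tp + fp + fn
        f = 2 * tp / denom if denom else 0.0
        if f > best_f:
            best_f, best_t = f, t
    return float(best_f), float(best_t)


def accuracy(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> float:
    labels, scores = _validate(labels, scores)
    return float(np.mean((scores >= threshold).astype(int) == labels))


def roc_curve_points(
    labels: Sequence[int], scores: Sequence[float]
) -> list[tuple[float, float]]:
    """(FPR, TPR) points swept over thresholds, ascending in FPR."""
    labels, scores = _validate(labels, scores)
    pts = []
    for t in [np.inf] + sorted(np.unique(scores), reverse=True):
        tp, fp, tn, fn = confusion_counts(labels, scores, t)
        tpr = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        pts.append((fpr, tpr))
    return pts


def pr_curve_points(
    labels: Sequence[int], scores: Sequence[float]
) -> list[tuple[float, float]]:
    """(recall, precision) points swept over thresholds, ascending in recall."""
    labels, scores = _validate(labels, scores)
    pts = []
    for t in [np.inf] + sorted(np.unique(scores), reverse=True):
        tp, fp, _, fn = confusion_counts(labels, scores, t)
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 1.0
        pts.append((recall, precision))
    return pts


@dataclass
class MetricReport:
    """Summary statistics plus the curves they integrate."""

    auc: float
    aupr: float
    f_max: float
    accuracy: float
    threshold_at_fmax: float
    roc_curve: list[tuple[float, float]] = field(default_factory=list)
    pr_curve: list[tuple[float, float]] = field(default_factory=list)
    n_test: int = 0

    @classmethod
    def from_scores(
        cls, labels: Sequence[int], scores: Sequence[float]
    ) -> "MetricReport":
        fm, t_fm = f_max(labels, scores)
        return cls(
            auc=roc_auc(labels, scores),
            aupr=aupr(labels, scores),
            f_max=fm,
            accuracy=accuracy(labels, scores),
            threshold_at_fmax=t_fm,
            roc_curve=roc_curve_points(labels, scores),
            pr_curve=pr_curve_points(labels, scores),
            n_test=len(labels),
        )

    def summary(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "f_max": self.f_max,
            "accuracy": self.accuracy,
        }

    def to_json(self, include_curves: bool = False) -> str:
        payload: dict = {**self.summary(),
                         "threshold_at_fmax": self.threshold_at_fmax,
                         "n_test": self.n_test}
        if include_curves:
            payload["roc_curve"] = self.roc_curve
            payload["pr_curve"] = self.pr_curve
        return json.dumps(payload, indent=2, sort_keys=True)


def mean_report(reports: Sequence[MetricReport]) -> MetricReport:
    """Arithmetic mean of the summary fields across fold reports."""
    return MetricReport(
        auc=float(np.mean([r.auc for r in reports])),
        aupr=float(np.mean([r.aupr for r in reports])),
        f_max=float(np.mean([r.f_max for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        threshold_at_fmax=float(np.mean([r.threshold_at_fmax for r in reports])),
        n_test=int(sum(r.n_test for r in reports)),
    )


# ---------------------------------------------------------------------------
# category-stratified evaluation
# ---------------------------------------------------------------------------

def evaluate_by_category(
    labels: Sequence[int],
    scores: Sequence[float],
    disease_ids: Sequence[str],
    category_of_disease: dict[str, str],
) -> dict:
    """Per-category AUC plus correlations of AUC with category frequency.

    Categories whose pairs lack one of the two classes are reported with
    ``auc=None`` and excluded from the correlations. Correlations reported:
    Pearson r of AUC against log10 pair count, and against the number of
    distinct diseases in the category.
    """
    labels, scores = _validate(labels, scores)
    per_cat: dict[str, dict] = {}
    for did in disease_ids:
        if did not in category_of_disease:
            raise KeyError(f"disease {did!r} has no category mapping")
    cats = np.array([category_of_disease[d] for d in disease_ids])
    for cat in sorted(set(cats)):
        sel = cats == cat
        sub_labels, sub_scores = labels[sel], scores[sel]
        dids = {d for d, s in zip(disease_ids, sel) if s}
        entry = {
            "n_pairs": int(sel.sum()),
            "n_diseases": len(dids),
            "auc": None,
        }
        if len(np.unique(sub_labels)) == 2:
            entry["auc"] = roc_auc(sub_labels, sub_scores)
        per_cat[cat] = entry
    defined = [c for c, e in per_cat.items() if e["auc"] is not None]
    corr: dict[str, Optional[float]] = {
        "auc_vs_log_pair_count": None,
        "auc_vs_disease_count": None,
    }
    if len(defined) >= 2:
        aucs = np.array([per_cat[c]["auc"] for c in defined])
        log_counts = np.log10([per_cat[c]["n_pairs"] for c in defined])
        d_counts = np.array([per_cat[c]["n_diseases"] for c in defined], dtype=float)
        if np.std(aucs) > 0 and np.std(log_counts) > 0:
            corr["auc_vs_log_pair_count"] = float(
                np.corrcoef(aucs, log_counts)[0, 1]
            )
        if np.std(aucs) > 0 and np.std(d_counts) > 0:
            corr["auc_vs_disease_count"] = float(np.corrcoef(aucs, d_counts)[0, 1])
    return {"categories": per_cat, "correlations": corr}


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold reports, their mean, and held-out scores for every pair."""

    fold_reports: list[MetricReport]
    mean: MetricReport
    scores: np.ndarray          # held-out score of each pair, dataset order
    fold_of_pair: list[int]


def cross_validate(dataset, estimator=None, k: int = 5, seed: int = 0) -> CVResult:
    """k-fold cross-validation of the full pipeline.

    Each fold in turn is held out; a fresh clone of the estimator (default
    :class:`~gdafusion.estimators.GDAClassifier`) is fitted — including
    contrastive pre-training — on the remaining folds and scores the held-out
    pairs. Folds are taken from ``dataset.fold_of_pair`` when present,
    otherwise assigned stratified with the given seed.
    """
    from sklearn.base import clone

    from .estimators import GDAClassifier
    from .io import make_folds

    if dataset.fold_of_pair is None:
        dataset = make_folds(dataset, k=k, seed=seed)
    folds = np.asarray(dataset.fold_of_pair)
    k = int(folds.max()) + 1
    keys = np.array([[p.gene_id, p.disease_id] for p in dataset.pairs], dtype=object)
    labels = np.array([p.label for p in dataset.pairs])
    if estimator is None:
        estimator = GDAClassifier(random_state=seed)
    reports: list[MetricReport] = []
    scores = np.full(len(labels), np.nan)
    for f in range(k):
        test = folds == f
        if len(np.unique(labels[test])) < 2:
            raise ValueError(f"fold {f} contains a single class; cannot evaluate")
        clf = clone(estimator)
        clf.set_params(
            genes=dict(dataset.genes), diseases=dict(dataset.diseases)
        )
        clf.fit(keys[~test], labels[~test])
        fold_scores = clf.predict_proba(keys[test])[:, 1]
        scores[test] = fold_scores
        reports.append(MetricReport.from_scores(labels[test], fold_scores))
    return CVResult(
        fold_reports=reports,
        mean=mean_report(reports),
        scores=scores,
        fold_of_pair=[int(f) for f in folds],
    )


def read_category_map(path) -> dict[str, str]:
    """TSV ``disease_id <tab> category`` (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "disease_id":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            out[parts[0]] = parts[1]
    return out


__all__ = [
    "confusion_counts",
    "roc_auc",
    "aupr",
    "f_max",
    "accuracy",
    "roc_curve_points",
    "pr_curve_points",
    "MetricReport",
    "mean_report",
    "CVResult",
    "cross_validate",
    "evaluate_by_category",
    "read_category_map",
]
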
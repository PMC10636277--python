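"""Model-level and epitope-level evaluation.

Model-level metrics (weighted F1/precision/recall, balanced accuracy) give a
single holistic number per classifier; per-class one-vs-rest AUROC gives the
epitope-specific view, with a paired Wilcoxon signed-rank test to compare two
classifiers over the same class set and a label-permutation control that
should sit at AUROC 0.5 for any model that has learned nothing spurious.

AUROC uses the rank-sum (Mann-Whitney) identity with midrank tie handling.
Classes with no positives or no negatives in the evaluation set have an
undefined AUROC; they are flagged and excluded from means rather than
imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
from scipy import stats
from sklearn.metrics import (balanced_accuracy_score, f1_score,
                             precision_score, recall_score, roc_curve)


@dataclass
class MetricsReport:
    weighted_f1: float
    balanced_accuracy: float
    weighted_precision: float
    weighted_recall: float
    per_class_auroc: dict = field(default_factory=dict)
    undefined_classes: list = field(default_factory=list)
    mean_auroc: float = float("nan")
    easy_mean_auroc: float = float("nan")
    hard_mean_auroc: float = float("nan")
    roc_points: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["roc_points"] = {k: {"fpr": list(v[0]), "tpr": list(v[1])}
                           for k, v in self.roc_points.items()}
        return json.dumps(d, indent=2)


def classification_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """(weighted F1, balanced accuracy, weighted precision, weighted recall).

    Support-weighted averages over per-class scores from the confusion
    matrix; classes never predicted contribute 0 precision, not NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("label sequences must be non-empty and equal length")
    return (
        float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
        float(balanced_accuracy_score(y_true, y_pred)),
        float(precision_score(y_true, y_pred, average="weighted", zero_division=0)),
        float(recall_score(y_true, y_pred, average="weighted", zero_division=0)),
    )


def binary_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUROC by the Mann-Whitney rank formulation (midrank ties)."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(y_true.sum())
    n_neg = int(y_true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined without both positives and negatives")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def per_class_auroc(y_true, score_matrix, class_order) -> tuple[dict, float, list]:
    """Per-class one-vs-rest AUROC and their unweighted mean.

    `score_matrix` columns follow `class_order`; rows align with `y_true`.
    Returns (per-class dict, mean over defined classes, undefined classes).
    """
    y_true = np.asarray(y_true)
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    if score_matrix.shape != (y_true.size, len(class_order)):
        raise ValueError("score matrix shape does not match labels / class order")
    out: dict = {}
    undefined: list = []
    for j, cls in enumerate(class_order):
        pos = y_true == cls
        if pos.all() or not pos.any():
            undefined.append(cls)
            continue
        out[cls] = binary_auroc(pos, score_matrix[:, j])
    mean = float(np.mean(list(out.values()))) if out else float("nan")
    return out, mean, undefined


def _wilcoxon_exact_brute(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments.

    Oracle-grade reference; only usable for small n.
    """
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = float(sum(r for s, r in zip(signs, ranks) if s))
        if min(w, ranks.sum() - w) <= w_obs + 1e-12:
            count += 1
    return w_obs, count / 2 ** n


def compare_models_wilcoxon(auroc_a: dict, auroc_b: dict) -> tuple[float, float]:
    """Two-sided paired signed-rank test on per-class AUROC differences.

    Zero differences are dropped (Wilcoxon's policy); the null distribution
    is exact for n <= 25 without ties in |difference|, normal approximation
    otherwise.  All-zero differences give (0.0, 1.0).
    """
    common = sorted(set(auroc_a) & set(auroc_b))
    if len(common) < 2:
        raise ValueError("need at least two shared classes to compare")
    a = np.array([auroc_a[c] for c in common])
    b = np.array([auroc_b[c] for c in common])
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    abs_d = np.abs(d)
    exact = d.size <= 25 and np.unique(abs_d).size == abs_d.size
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def label_permutation_control(y_true, score_matrix, class_order, seed: int = 0
                              ) -> float:
    """Mean one-vs-rest AUROC after a seeded shuffle of the labels.

    Under label exchangeability this sits at 0.5; a model whose unshuffled
    AUROC clears this band is not predicted by chance.
    """
    rng = np.random.default_rng(seed)
    shuffled = np.asarray(y_true).copy()
    rng.shuffle(shuffled)
    _, mean, _ = per_class_auroc(shuffled, score_matrix, class_order)
    return mean


def difficulty_report(per_class: dict, difficulty: dict) -> dict:
    """AUROC means within easy/hard class groups plus a rank-sum comparison."""
    missing = [c for c in per_class if c not in difficulty]
    if missing:
        raise ValueError(f"classes without a difficulty category: {missing}")
    easy = [v for c, v in per_class.items() if difficulty[c] == "easy"]
    hard = [v for c, v in per_class.items() if difficulty[c] == "hard"]
    out = {
        "easy_mean_auroc": float(np.mean(easy)) if easy else float("nan"),
        "hard_mean_auroc": float(np.mean(hard)) if hard else float("nan"),
        "n_easy": len(easy),
        "n_hard": len(hard),
        "rank_sum_p": float("nan"),
    }
    if easy and hard:
        res = stats.mannwhitneyu(easy, hard, alternative="two-sided")
        out["rank_sum_p"] = float(res.pvalue)
    return out


def full_report(y_true, y_pred, score_matrix, class_order,
                difficulty: dict | None = None,
                with_roc_points: bool = False) -> MetricsReport:
    """Assemble the complete metrics report for one model."""
    f1w, bal, prec, rec = classification_metrics(y_true, y_pred)
    per_class, mean, undefined = per_class_auroc(y_true, score_matrix, class_order)
    report = MetricsReport(weighted_f1=f1w, balanced_accuracy=bal,
                           weighted_precision=prec, weighted_recall=rec,
                           per_class_auroc=per_class, mean_auroc=mean,
                           undefined_classes=undefined)
    if difficulty:
        d = difficulty_report(per_class, difficulty)
        report.easy_mean_auroc = d["easy_mean_auroc"]
        report.hard_mean_auroc = d["hard_mean_auroc"]
    if with_roc_points:
        y_true = np.asarray(y_true)
        for j, cls in enumerate(class_order):
            pos = (y_true == cls).astype(int)
            if 0 < pos.sum() < pos.size:
                fpr, tpr, _ = roc_curve(pos, np.asarray(score_matrix)[:, j])
                report.roc_points[cls] = (fpr.tolist(), tpr.tolist())
    return report
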
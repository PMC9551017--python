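"""Edge-ranking evaluation against a gold standard.

AUROC is the Mann-Whitney rank statistic of gold positives vs.
negatives (ties handled by midranks); AUPRC is the step-wise average
precision (the sum of precision at each recall increment, with no
trapezoidal interpolation).  Gold pairs missing from the ranking are
appended below every ranked pair as lowest-confidence predictions,
following the DREAM evaluation convention.  Paired trial populations
(e.g. 100 runs with and without the grey association) are compared by
the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .io_formats import GoldStandard, RankedEdgeList, ValidationError

__all__ = [
    "EvaluationResult",
    "TrialComparison",
    "evaluate_ranking",
    "auroc_score",
    "auprc_score",
    "precision_at_k",
    "compare_trials",
    "confusion_at_k",
]


@dataclass
class EvaluationResult:
    auroc: float
    auprc: float
    roc_points: np.ndarray   # (FPR, TPR) pairs
    pr_points: np.ndarray    # (Recall, Precision) pairs
    n_positives: int
    n_negatives: int


@dataclass
class TrialComparison:
    sample_a: np.ndarray
    sample_b: np.ndarray
    statistic: float
    p_value: float
    alternative: str
    degenerate: bool = False  # all paired differences were zero


def auroc_score(labels, scores) -> float:
    """Mann-Whitney AUROC of binary labels under a score ranking
    (midrank tie handling)."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores, dtype=float)))


def auprc_score(labels, scores) -> float:
    """Step-wise average precision: mean of the precision at each
    positive hit down the ranking (no trapezoidal interpolation)."""
    return float(
        average_precision_score(np.asarray(labels), np.asarray(scores, dtype=float))
    )


def _labels_scores(
    ranked: RankedEdgeList, gold: GoldStandard, include_unranked: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    universe = gold.universe
    scores = {(r, t): s for r, t, s in ranked}
    extra = set(scores) - set(universe)
    if extra:
        raise ValidationError(f"ranked pairs outside gold universe: {sorted(extra)[:5]}")
    floor = min(scores.values()) - 1.0 if scores else 0.0
    ys, ss = [], []
    for pair in universe:
        if pair in scores:
            ys.append(1 if pair in gold.edges else 0)
            ss.append(scores[pair])
        elif include_unranked:
            ys.append(1 if pair in gold.edges else 0)
            ss.append(floor)
    return np.array(ys), np.array(ss, dtype=float)


def evaluate_ranking(
    ranked: RankedEdgeList, gold: GoldStandard, include_unranked: bool = True
) -> EvaluationResult:
    """AUROC/AUPRC of a ranked edge list against the gold standard."""
    y, s = _labels_scores(ranked, gold, include_unranked)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"metrics undefined with {n_pos} positives and {n_neg} negatives"
        )
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return EvaluationResult(
        auroc=auroc_score(y, s),
        auprc=auprc_score(y, s),
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec[::-1], prec[::-1]]),
        n_positives=n_pos,
        n_negatives=n_neg,
    )


def precision_at_k(ranked: RankedEdgeList, gold: GoldStandard, k: int) -> float:
    """Fraction of the k best-ranked pairs that are gold positives."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    top = ranked.rows[:k]
    if not top:
        raise ValidationError("empty ranking")
    hits = sum(1 for r, t, _ in top if (r, t) in gold.edges)
    return hits / len(top)


def confusion_at_k(
    ranked: RankedEdgeList, gold: GoldStandard, k: int
) -> dict[str, float]:
    """Threshold-dependent helpers at cutoff k: precision, recall,
    accuracy and Matthews correlation coefficient."""
    top = {(r, t) for r, t, _ in ranked.rows[:k]}
    pos = gold.edges
    universe = set(gold.universe)
    tp = len(top & pos)
    fp = len(top - pos)
    fn = len(pos - top)
    tn = len(universe) - tp - fp - fn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / len(universe)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {
        "precision": prec,
        "recall": rec,
        "accuracy": acc,
        "mcc": float(mcc),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def compare_trials(
    sample_a, sample_b, alternative: str = "two-sided"
) -> TrialComparison:
    """Wilcoxon signed-rank test on paired per-trial metrics.

    Uses the exact null distribution for n <= 25 paired differences and
    the continuity-corrected normal approximation beyond; identical
    samples short-circuit to p = 1 with a degenerate flag.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("compare_trials needs equal-length 1-D samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    diffs = a - b
    if np.all(diffs == 0):
        return TrialComparison(
            sample_a=a, sample_b=b, statistic=0.0, p_value=1.0,
            alternative=alternative, degenerate=True,
        )
    if len(diffs) <= 25:
        try:
            res = stats.wilcoxon(a, b, alternative=alternative, method="exact")
        except ValueError:  # ties / zeros make the exact null unavailable
            res = stats.wilcoxon(
                a, b, alternative=alternative, method="approx", correction=True
            )
    else:
        res = stats.wilcoxon(
            a, b, alternative=alternative, method="approx", correction=True
        )
    return TrialComparison(
        sample_a=a, sample_b=b, statistic=float(res.statistic),
        p_value=float(res.pvalue), alternative=alternative,
    )
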
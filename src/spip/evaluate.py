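"""Ranked-list benchmarking against curated truth sets.

A ranking is evaluated by treating a label source (e.g. a curated
hold-out set or a phenotype-screen subset) as the positive class:
confusion metrics at a rank cut-off, ROC and precision-recall curves
with their areas, windowed fold-enrichment near the top of the list,
the Wald-Wolfowitz runs test on the label sequence, and an empirical
permutation test on the prefix label count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as skm


@dataclass
class LabeledRanking:
    """Targets in rank order with a binary label per target."""

    targets: list[str]
    labels: np.ndarray  # 1 = true-positive-eligible, 0 = not
    source: str = "labels"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.targets) != len(self.labels):
            raise ValueError("targets and labels differ in length")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.targets)

    @classmethod
    def from_ranked_targets(
        cls, targets: Sequence[str], positives: Sequence[str], source: str = "labels"
    ) -> "LabeledRanking":
        pos = set(positives)
        return cls(list(targets), np.array([t in pos for t in targets], int), source)


def confusion_at(ranking: LabeledRanking, k: int) -> dict:
    """Confusion counts and derived metrics with top-k called positive."""
    n = len(ranking)
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside 1..{n}")
    labels = ranking.labels
    tp = int(labels[:k].sum())
    fp = k - tp
    fn = int(labels[k:].sum())
    tn = n - k - fn
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


def roc_pr_curves(ranking: LabeledRanking) -> dict:
    """ROC and PR curves over all rank thresholds, with both areas.

    The score fed to the curves is the negated rank, so threshold
    sweeps correspond to cutting the ranked list at every depth; the
    ROC area then equals the Mann-Whitney rank statistic.
    """
    y = ranking.labels
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes required for ROC/PR curves")
    score = -np.arange(1, len(y) + 1, dtype=float)
    fpr, tpr, _ = skm.roc_curve(y, score)
    prec, rec, _ = skm.precision_recall_curve(y, score)
    return {
        "roc": (fpr, tpr),
        "pr": (rec, prec),
        "auc_roc": float(skm.roc_auc_score(y, score)),
        "auc_pr": float(skm.average_precision_score(y, score)),
    }


def window_fold_enrichment(ranking: LabeledRanking, window: int) -> float:
    """Labelled-count ratio of ranks 1..w over ranks w+1..2w.

    Infinite (flagged as math.inf) when the second window carries no
    label; NaN when neither window does.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if 2 * window > len(ranking):
        raise ValueError("ranking shorter than two windows")
    first = int(ranking.labels[:window].sum())
    second = int(ranking.labels[window : 2 * window].sum())
    if second == 0:
        return math.inf if first > 0 else math.nan
    return first / second


def threshold_enrichment(
    ranking: LabeledRanking, k: int, normalized: bool = False
) -> float:
    """TP/FP ratio at rank k; optionally divided by the whole-list ratio."""
    c = confusion_at(ranking, k)
    if c["fp"] == 0:
        return math.inf
    ratio = c["tp"] / c["fp"]
    if normalized:
        pos = int(ranking.labels.sum())
        neg = len(ranking) - pos
        if pos == 0:
            return math.nan
        ratio /= pos / neg
    return ratio


def runs_test(ranking: LabeledRanking) -> dict:
    """Wald-Wolfowitz runs test on the label sequence in rank order.

    Fewer runs than expected (labels clumped at the top) gives a
    negative z; the p-value is two-sided from the normal approximation,
    which is warned about when either class has fewer than 10 members.
    """
    y = ranking.labels
    n1 = int(y.sum())
    n2 = len(y) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both label classes required for the runs test")
    weak = n1 < 10 or n2 < 10
    runs = 1 + int((y[1:] != y[:-1]).sum())
    n = n1 + n2
    mean = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    z = (runs - mean) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return {"runs": runs, "z": z, "p": min(p, 1.0), "weak_approximation": weak}


def ranking_auc(
    pvalues: dict[str, float],
    positives: Sequence[str],
    universe: Sequence[str],
) -> float:
    """ROC area of an integrated p-value map over a protein universe.

    Proteins absent from the map are tied at the bottom (p = 1); ties
    are handled by average ranks (the Mann-Whitney convention), so the
    value is invariant to any strictly monotone rescaling of p.
    """
    pos = set(positives)
    y = np.array([t in pos for t in universe], dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes required")
    score = np.array([-pvalues.get(t, 1.0) for t in universe], dtype=float)
    return float(skm.roc_auc_score(y, score))


def random_enrichment_test(
    ranking: LabeledRanking, k: int, n_perm: int = 1000, seed: int = 0
) -> float:
    """Empirical p-value for the label count in the top-k prefix.

    Permutes the label vector n_perm times; p = (1 + #{permutations
    with prefix count >= observed}) / (n_perm + 1).  Converges to the
    hypergeometric upper tail.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if not 1 <= k <= len(ranking):
        raise ValueError("invalid prefix size")
    rng = np.random.default_rng(seed)
    labels = ranking.labels.copy()
    observed = int(labels[:k].sum())
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        if int(labels[:k].sum()) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
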
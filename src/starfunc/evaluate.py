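"""Evaluation statistics for function predictions.

Accuracy and confusion matrices over the three ordered classes, AUROC for
each of the two ordinal scores (Mann-Whitney formulation, ties counted
half), variance in continuous activity explained by predicted labels (a
group-means linear model, so R^2 = SS_between / SS_total), and a one-way
ANOVA across predicted groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .core import Function

CLASS_ORDER = (Function.NONE, Function.DECREASED, Function.NORMAL)


@dataclass
class EvaluationReport:
    accuracy: float
    confusion: np.ndarray                 # (3, 3), rows = true classes
    auroc_notnone: float | None = None
    auroc_normal: float | None = None
    r_squared: float | None = None
    anova_f: float | None = None
    anova_p: float | None = None


def classification_report(predicted: Sequence[Function],
                          true: Sequence[Function]
                          ) -> tuple[float, np.ndarray]:
    """Accuracy and 3x3 confusion matrix (rows true, columns predicted)."""
    predicted, true = list(predicted), list(true)
    if not predicted or len(predicted) != len(true):
        raise ValueError("predicted and true labels must be equal, non-empty")
    for lab in (*predicted, *true):
        if lab not in CLASS_ORDER:
            raise ValueError(f"label {lab} outside the three function classes")
    order = [f.value for f in CLASS_ORDER]
    conf = _sk_confusion([t.value for t in true],
                         [p.value for p in predicted], labels=order)
    accuracy = float(np.trace(conf) / conf.sum())
    return accuracy, conf


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def variance_explained(predicted: Sequence, activities: Sequence[float]
                       ) -> float:
    """R^2 of a linear model on label indicators (group-means fit).

    Identical to SS_between / SS_total = 1 - SS_within / SS_total.
    """
    labels = np.asarray(predicted, dtype=object)
    y = np.asarray(activities, dtype=float)
    if labels.shape != y.shape:
        raise ValueError("labels and activities length mismatch")
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two distinct predicted labels")
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("degenerate: activities have zero variance")
    ss_within = 0.0
    for lab in set(labels.tolist()):
        g = y[labels == lab]
        ss_within += float(np.sum((g - g.mean()) ** 2))
    return 1.0 - ss_within / ss_total


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA across predicted groups: (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    n_total = sum(len(g) for g in groups)
    if n_total - len(groups) < 1:
        raise ValueError("insufficient degrees of freedom for ANOVA")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def evaluation_report(
    predicted: Sequence[Function],
    true: Sequence[Function],
    scores: np.ndarray | None = None,
    activities: Sequence[float] | None = None,
) -> EvaluationReport:
    """Bundle the full metric set for one prediction run.

    ``scores`` is the (n, 2) ordinal score array; AUROCs are computed
    against the cumulative targets derived from the true labels.
    ``activities`` enables the variance-explained and ANOVA entries,
    grouped by predicted label.
    """
    accuracy, conf = classification_report(predicted, true)
    report = EvaluationReport(accuracy=accuracy, confusion=conf)
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        t1 = np.array([int(t.rank >= 1) for t in true])
        t2 = np.array([int(t.rank >= 2) for t in true])
        report.auroc_notnone = auroc(scores[:, 0], t1)
        report.auroc_normal = auroc(scores[:, 1], t2)
    if activities is not None:
        report.r_squared = variance_explained(
            [p.value for p in predicted], activities)
        groups = [np.asarray(activities, dtype=float)[
            np.asarray([p == c for p in predicted])]
            for c in CLASS_ORDER]
        groups = [g for g in groups if len(g)]
        report.anova_f, report.anova_p = oneway_anova(groups)
    return report
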
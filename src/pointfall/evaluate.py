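"""Data-split strategies, the metric suite and confusion-matrix reporting.

Six split strategies: five ratio splits (50-50, 60-40, 70-30, 80-20, 90-10)
that mix all data from all subjects before cutting, and leave-one-out, where
one whole experiment (track) forms the test fold and the rest train.

Metrics are reported in percent: accuracy, macro precision / recall / F1 and
macro one-vs-rest AUC, plus the 3×3 confusion matrix ordered standing,
sitting, falling.  All metrics are recomputable from the confusion matrix
except AUC, which uses a rank (Mann-Whitney) statistic on the class scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import CLASS_CODES, ParameterError

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "make_splits",
    "evaluate",
    "one_vs_rest_auc",
    "mean_report",
]

ALLOWED_RATIOS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class SplitPlan:
    """Either a seeded ratio split or leave-one-experiment-out."""

    strategy: str  # "ratio" | "leave_one_out"
    ratio: Optional[float] = None  # train fraction, one of ALLOWED_RATIOS
    seed: int = 0
    stratified: bool = True
    any_ratio: bool = False  # escape hatch for non-protocol ratios

    def __post_init__(self) -> None:
        if self.strategy not in ("ratio", "leave_one_out"):
            raise ParameterError("strategy must be 'ratio' or 'leave_one_out'")
        if self.strategy == "ratio":
            if self.ratio is None:
                raise ParameterError("ratio plans need a ratio")
            if not self.any_ratio and not any(
                abs(self.ratio - r) < 1e-9 for r in ALLOWED_RATIOS
            ):
                raise ParameterError(
                    f"ratio {self.ratio} is not one of the protocol ratios {ALLOWED_RATIOS}; "
                    "pass any_ratio=True to override"
                )

    @property
    def name(self) -> str:
        if self.strategy == "leave_one_out":
            return "leave-one-out"
        return f"{int(round(self.ratio * 100))}-{int(round((1 - self.ratio) * 100))}"


def make_splits(
    n: int,
    plan: SplitPlan,
    labels: Optional[np.ndarray] = None,
    groups: Optional[np.ndarray] = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index folds for a split plan.

    Ratio plans shuffle (stratified by class when labels are given) and cut
    at ``floor(ratio·n)``; leave-one-out yields one fold per distinct group
    (experiment).  Train and test are disjoint and jointly exhaustive in
    every fold.
    """
    if n <= 0:
        raise ParameterError("empty dataset")
    if plan.strategy == "leave_one_out":
        if groups is None:
            raise ParameterError("leave-one-out requires experiment group ids")
        groups = np.asarray(groups)
        folds = []
        for g in np.unique(groups):
            test = np.flatnonzero(groups == g)
            train = np.flatnonzero(groups != g)
            folds.append((train, test))
        return folds

    rng = np.random.default_rng(plan.seed)
    n_train = int(np.floor(plan.ratio * n))
    if plan.stratified and labels is not None:
        labels = np.asarray(labels)
        train_parts, test_parts = [], []
        for c in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == c))
            k = int(np.floor(plan.ratio * len(idx)))
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train = np.concatenate(train_parts)
        test = np.concatenate(test_parts)
        # per-class flooring can undershoot the global cut; top up from test
        short = n_train - len(train)
        if short > 0:
            move = rng.permutation(len(test))[:short]
            train = np.concatenate([train, test[move]])
            test = np.delete(test, move)
    else:
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
    return [(np.sort(train), np.sort(test))]


@dataclass
class EvaluationReport:
    """Per-split metrics in percent plus the confusion matrix."""

    accuracy: float
    precision: float  # macro
    recall: float  # macro
    f1: float  # macro
    auc: Optional[float]  # macro one-vs-rest, None when no scores given
    confusion: np.ndarray  # (C, C), rows true, cols predicted
    classes: tuple[int, ...] = CLASS_CODES
    n: int = 0
    excluded_auc_classes: tuple[int, ...] = ()
    per_class_misclassification: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "n": self.n,
            "per_class_misclassification": self.per_class_misclassification,
        }


def one_vs_rest_auc(truths: np.ndarray, scores: np.ndarray, positive: int, classes: Sequence[int]) -> float:
    """AUC of one class against the rest, by the rank-sum (Mann-Whitney)
    statistic with tie correction; returns a fraction in [0, 1]."""
    classes = list(classes)
    col = classes.index(positive)
    y = (np.asarray(truths) == positive).astype(int)
    s = np.asarray(scores)[:, col]
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    if n_pos == 0 or n_neg == 0:
        raise ParameterError(f"class {positive} absent from truths or complements")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    preds: np.ndarray,
    truths: np.ndarray,
    scores: Optional[np.ndarray] = None,
    classes: Sequence[int] = CLASS_CODES,
) -> EvaluationReport:
    """Metric suite for one prediction set.

    Macro averages run over the three posture classes; classes absent from
    *truths* are excluded from the macro AUC (flagged in the report).
    """
    preds = np.asarray(preds, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if len(preds) != len(truths):
        raise ParameterError("preds and truths must have equal length")
    classes = tuple(classes)
    C = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((C, C), dtype=int)
    for t, p in zip(truths, preds):
        conf[pos[t], pos[p]] += 1

    total = conf.sum()
    accuracy = 100.0 * np.trace(conf) / total
    precisions, recalls, f1s = [], [], []
    miscls = {}
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
        miscls[c] = 100.0 * fn / max(conf[i, :].sum(), 1)

    auc = None
    excluded: list[int] = []
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        aucs = []
        for c in classes:
            try:
                aucs.append(one_vs_rest_auc(truths, scores, c, classes))
            except ParameterError:
                excluded.append(c)
                warnings.warn(f"class {c} absent: excluded from macro AUC", stacklevel=2)
        auc = 100.0 * float(np.mean(aucs)) if aucs else None

    return EvaluationReport(
        accuracy=float(accuracy),
        precision=100.0 * float(np.mean(precisions)),
        recall=100.0 * float(np.mean(recalls)),
        f1=100.0 * float(np.mean(f1s)),
        auc=auc,
        confusion=conf,
        classes=classes,
        n=int(total),
        excluded_auc_classes=tuple(excluded),
        per_class_misclassification=miscls,
    )


def mean_report(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Average of fold reports (used for leave-one-out); confusion matrices sum."""
    if not reports:
        raise ParameterError("no reports to average")
    aucs = [r.auc for r in reports if r.auc is not None]
    return EvaluationReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        auc=float(np.mean(aucs)) if aucs else None,
        confusion=np.sum([r.confusion for r in reports], axis=0),
        classes=reports[0].classes,
        n=int(sum(r.n for r in reports)),
    )
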
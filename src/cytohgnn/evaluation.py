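"""Validation designs and the classification metric suite.

Two protocols: a stratified 70/15/15 train/validation/test hold-out, and
stratified 5-fold cross-validation where each fold serves once as the test
set and 20% of the remaining samples (stratified) form the inner
validation split.  Per-class sample counts use largest-remainder rounding,
so every class deviates from its target fraction by at most one sample.

Metrics are computed one-vs-rest per class from the confusion matrix:

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 P R / (P + R)

with unweighted (macro) class averages as headline values, plus accuracy
and a rank-statistic one-vs-rest ROC AUC.  Ratios with zero denominator
are reported as 0 and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegenerateInputError, ShapeError

__all__ = [
    "SplitPlan",
    "stratified_holdout",
    "stratified_kfold",
    "compute_metrics",
    "EvaluationReport",
    "gcn_baseline",
    "cross_validate",
]

ROLES = ("train", "val", "test")


@dataclass
class SplitPlan:
    """Per-sample role assignment of one stratified split."""

    assignment: np.ndarray  # array of 'train' / 'val' / 'test'
    stratified: bool
    seed: int

    def indices(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ShapeError(f"unknown role {role!r}")
        return np.flatnonzero(self.assignment == role)

    @property
    def train_idx(self) -> np.ndarray:
        return self.indices("train")

    @property
    def val_idx(self) -> np.ndarray:
        return self.indices("val")

    @property
    def test_idx(self) -> np.ndarray:
        return self.indices("test")


def _largest_remainder(n: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer counts summing to n, each within one of n * fraction."""
    quotas = np.asarray(fractions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    short = n - counts.sum()
    # ties go to the earlier role (train before val before test)
    order = np.argsort(-remainder, kind="stable")
    for j in order[:short]:
        counts[j] += 1
    return counts


def stratified_holdout(
    labels: np.ndarray,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/val/test partition with the given fractions.

    Each class is shuffled independently (seeded) and divided by
    largest-remainder rounding, so per-class counts are within one sample
    of the target fraction and the roles partition the index set exactly.
    """
    labels = np.asarray(labels)
    fractions = tuple(fractions)
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise DegenerateInputError(f"fractions must be 3 values summing to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.shape[0], dtype=object)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise DegenerateInputError(
                f"class {cls} has only {idx.size} samples; need at least 3"
            )
        idx = rng.permutation(idx)
        n_train, n_val, n_test = _largest_remainder(idx.size, fractions)
        assignment[idx[:n_train]] = "train"
        assignment[idx[n_train : n_train + n_val]] = "val"
        assignment[idx[n_train + n_val :]] = "test"
    return SplitPlan(assignment=assignment.astype(str), stratified=True, seed=seed)


def stratified_kfold(
    labels: np.ndarray,
    n_folds: int = 5,
    inner_val_fraction: float = 0.20,
    seed: int = 0,
) -> List[SplitPlan]:
    """Stratified k-fold plans with an inner stratified validation split.

    Returns one :class:`SplitPlan` per fold; each sample is in the test
    role of exactly one plan.  Within a plan, ``inner_val_fraction`` of
    the non-test samples of each class (largest-remainder rounded) are
    validation, the rest train.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise DegenerateInputError("n_folds must be >= 2")
    if not (0 < inner_val_fraction < 1):
        raise DegenerateInputError("inner_val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    fold_members: List[List[np.ndarray]] = [[] for _ in range(n_folds)]
    rest_order: Dict[int, np.ndarray] = {}
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise DegenerateInputError(
                f"class {cls} has {idx.size} samples; need at least {n_folds}"
            )
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            fold_members[f].append(chunk)
    plans = []
    for f in range(n_folds):
        assignment = np.empty(labels.shape[0], dtype=object)
        test_idx = np.concatenate(fold_members[f])
        assignment[test_idx] = "test"
        inner_rng = np.random.default_rng(seed + 1000 * (f + 1))
        for cls in classes:
            rest = np.setdiff1d(np.flatnonzero(labels == cls), test_idx)
            rest = inner_rng.permutation(rest)
            n_val = _largest_remainder(rest.size, (inner_val_fraction, 1 - inner_val_fraction))[0]
            assignment[rest[:n_val]] = "val"
            assignment[rest[n_val:]] = "train"
        plans.append(SplitPlan(assignment=assignment.astype(str), stratified=True, seed=seed))
    return plans


# ------------------------------------------------------------------ #


@dataclass
class EvaluationReport:
    """Confusion matrix with per-class and macro one-vs-rest metrics."""

    confusion: np.ndarray
    per_class: pd.DataFrame  # columns: specificity, precision, recall, f1
    macro: Dict[str, float]
    accuracy: float
    auc_per_class: np.ndarray
    macro_auc: float
    class_names: List[str]
    undefined_metrics: List[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Evaluation report", "=" * 60]
        table = self.per_class.copy()
        lines.append(table.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("-" * 60)
        lines.append(
            "macro: "
            + "  ".join(f"{k}={v:.4f}" for k, v in self.macro.items())
        )
        lines.append(f"accuracy: {self.accuracy:.4f}")
        if np.isfinite(self.macro_auc):
            lines.append(f"macro AUC: {self.macro_auc:.4f}")
        if self.undefined_metrics:
            lines.append(f"flagged (zero denominator): {', '.join(self.undefined_metrics)}")
        return "\n".join(lines)

    def to_dict(self) -> Dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in self.per_class.iterrows()
            },
            "macro": {k: float(v) for k, v in self.macro.items()},
            "accuracy": float(self.accuracy),
            "auc_per_class": [float(a) for a in self.auc_per_class],
            "macro_auc": float(self.macro_auc),
            "class_names": list(self.class_names),
            "undefined_metrics": list(self.undefined_metrics),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path) -> None:
        """Per-class table in column order specificity, precision, recall, f1."""
        self.per_class.to_csv(path, index_label="class")

    def confusion_to_csv(self, path) -> None:
        pd.DataFrame(
            self.confusion, index=self.class_names, columns=self.class_names
        ).to_csv(path, index_label="true\\pred")


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """One-vs-rest AUC via the Mann-Whitney rank statistic (tie-aware)."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    probabilities: Optional[np.ndarray] = None,
    n_classes: Optional[int] = None,
    class_names: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from labels and predictions.

    Per-class metrics come from the one-vs-rest confusion counts; macro
    values are unweighted class means.  AUC needs ``probabilities`` (rows
    summing to 1); classes absent from ``true_labels`` have undefined AUC,
    reported as 0 and flagged.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    yhat = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != yhat.shape:
        raise ShapeError(f"label vectors differ in length: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise DegenerateInputError("cannot evaluate an empty label vector")
    if n_classes is None:
        n_classes = int(max(y.max(), yhat.max())) + 1
    if class_names is None:
        class_names = [f"class_{c}" for c in range(n_classes)]
    class_names = list(class_names)

    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y, yhat), 1)
    total = confusion.sum()
    flagged: List[str] = []

    def _ratio(num, den, name):
        if den == 0:
            flagged.append(name)
            return 0.0
        return num / den

    rows = {}
    for c in range(n_classes):
        tp = confusion[c, c]
        fn = confusion[c].sum() - tp
        fp = confusion[:, c].sum() - tp
        tn = total - tp - fn - fp
        name = class_names[c]
        precision = _ratio(tp, tp + fp, f"precision[{name}]")
        recall = _ratio(tp, tp + fn, f"recall[{name}]")
        specificity = _ratio(tn, tn + fp, f"specificity[{name}]")
        f1 = _ratio(2 * precision * recall, precision + recall, f"f1[{name}]")
        rows[name] = {
            "specificity": specificity,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    per_class = per_class[["specificity", "precision", "recall", "f1"]]
    macro = {k: float(per_class[k].mean()) for k in per_class.columns}
    accuracy = float(np.trace(confusion) / total)

    auc = np.full(n_classes, np.nan)
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=np.float64)
        if probabilities.shape != (y.size, n_classes):
            raise ShapeError(
                f"probabilities must be ({y.size}, {n_classes}), got {probabilities.shape}"
            )
        for c in range(n_classes):
            auc[c] = _rank_auc(probabilities[:, c], y == c)
            if np.isnan(auc[c]):
                flagged.append(f"auc[{class_names[c]}]")
                auc[c] = 0.0
        macro_auc = float(np.mean(auc))
    else:
        macro_auc = np.nan

    return EvaluationReport(
        confusion=confusion,
        per_class=per_class,
        macro=macro,
        accuracy=accuracy,
        auc_per_class=auc,
        macro_auc=macro_auc,
        class_names=class_names,
        undefined_metrics=flagged,
    )


# ------------------------------------------------------------------ #


def gcn_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    k: int,
    split: SplitPlan,
    config=None,
    class_names: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Train and evaluate the conventional-GCN comparison model.

    Uses the same features, split and hyperparameters as a hypergraph run
    so the two reports are comparable row for row.
    """
    from .classifier import GCNClassifier

    model = GCNClassifier(features, labels, k=k, config=config, class_names=class_names)
    result = model.fit(split.train_idx, split.val_idx)
    return result.evaluate(split.test_idx)


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    config=None,
    n_folds: int = 5,
    seed: int = 0,
    model_cls=None,
    class_names: Optional[Sequence[str]] = None,
):
    """Stratified k-fold evaluation of a transductive classifier.

    Returns ``(per_fold_reports, aggregate)`` where the aggregate carries
    the mean accuracy and macro metrics over folds.
    """
    from .classifier import HypergraphClassifier

    if model_cls is None:
        model_cls = HypergraphClassifier
    plans = stratified_kfold(labels, n_folds=n_folds, seed=seed)
    reports = []
    for plan in plans:
        model = model_cls(features, labels, k=k, config=config, class_names=class_names)
        result = model.fit(plan.train_idx, plan.val_idx)
        reports.append(result.evaluate(plan.test_idx))
    aggregate = {
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "macro_precision": float(np.mean([r.macro["precision"] for r in reports])),
        "macro_recall": float(np.mean([r.macro["recall"] for r in reports])),
        "macro_f1": float(np.mean([r.macro["f1"] for r in reports])),
        "macro_specificity": float(np.mean([r.macro["specificity"] for r in reports])),
    }
    return reports, aggregate
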
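"""Cross-validation harness and open-set-aware metrics.

The confusion matrix always carries an "unassigned" prediction column.
Accuracy-type metrics treat an unassigned prediction as an error for the
cell's true class; the assignment rate (fraction of cells given a known
label) is reported separately, so closed-set experiments can verify both
that cells are classified correctly and that few are needlessly rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from . import annotator as ann_mod
from .annotator import UNASSIGNED
from .network import NetworkConfig
from .pathways import IndicatorMatrix
from .preprocessing import ExpressionMatrix


@dataclass
class ConfusionMatrix:
    """True-label rows x predicted-label columns (always incl. "unassigned")."""

    true_labels: list
    pred_labels: list
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.true_labels), len(self.pred_labels)):
            raise ValueError("count shape inconsistent with label lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if UNASSIGNED not in self.pred_labels:
            raise ValueError("prediction axis must include the unassigned column")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Row-normalized view (each true label sums to 1)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        return self.counts / np.where(sums == 0, 1, sums)

    def to_frame(self, normalize: bool = False) -> pd.DataFrame:
        data = self.normalized() if normalize else self.counts
        return pd.DataFrame(data, index=self.true_labels, columns=self.pred_labels)

    def add(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        """Aggregate two confusion matrices over the union of their label axes."""
        true_labels = sorted(set(self.true_labels) | set(other.true_labels))
        pred_known = sorted(
            (set(self.pred_labels) | set(other.pred_labels)) - {UNASSIGNED}
        )
        pred_labels = pred_known + [UNASSIGNED]
        counts = np.zeros((len(true_labels), len(pred_labels)), dtype=np.int64)
        for cm in (self, other):
            ti = [true_labels.index(t) for t in cm.true_labels]
            pi = [pred_labels.index(p) for p in cm.pred_labels]
            counts[np.ix_(ti, pi)] += cm.counts
        return ConfusionMatrix(true_labels, pred_labels, counts)


def confusion(true, pred) -> ConfusionMatrix:
    """Count (true, predicted) label pairs; unassigned is always a column."""
    true = list(true)
    pred = list(pred)
    if len(true) != len(pred):
        raise ValueError(f"length mismatch: {len(true)} true vs {len(pred)} predicted")
    true_labels = sorted(set(true))
    pred_known = sorted((set(pred) | set(true)) - {UNASSIGNED})
    pred_labels = pred_known + [UNASSIGNED]
    ti = {t: i for i, t in enumerate(true_labels)}
    pi = {p: j for j, p in enumerate(pred_labels)}
    counts = np.zeros((len(true_labels), len(pred_labels)), dtype=np.int64)
    for t, p in zip(true, pred):
        counts[ti[t], pi[p]] += 1
    return ConfusionMatrix(true_labels, pred_labels, counts)


def metrics(cm: ConfusionMatrix) -> dict:
    """Precision/recall/F1 (macro and support-weighted), accuracy, balanced
    accuracy, and assignment rate.

    Per-class recall divides by true-class support, so unassigned predictions
    count as errors; per-class precision divides by the number of predictions
    of that class.  Balanced accuracy is the macro average of recalls;
    assignment rate is the fraction of cells not predicted "unassigned".
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    support = cm.counts.sum(axis=1).astype(np.float64)
    total = support.sum()
    pred_sums = {p: cm.counts[:, j].sum() for j, p in enumerate(cm.pred_labels)}

    recalls, precisions, f1s = [], [], []
    correct = 0
    for i, lab in enumerate(cm.true_labels):
        tp = cm.counts[i, cm.pred_labels.index(lab)] if lab in cm.pred_labels else 0
        correct += tp
        rec = tp / support[i] if support[i] else 0.0
        denom = pred_sums.get(lab, 0)
        prec = tp / denom if denom else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        recalls.append(rec)
        precisions.append(prec)
        f1s.append(f1)
    recalls, precisions, f1s = map(np.asarray, (recalls, precisions, f1s))
    weights = support / total
    unassigned_count = cm.counts[:, cm.pred_labels.index(UNASSIGNED)].sum()
    return {
        "accuracy": float(correct / total),
        "balanced_accuracy": float(recalls.mean()),
        "macro_precision": float(precisions.mean()),
        "macro_recall": float(recalls.mean()),
        "macro_f1": float(f1s.mean()),
        "weighted_precision": float((weights * precisions).sum()),
        "weighted_recall": float((weights * recalls).sum()),
        "weighted_f1": float((weights * f1s).sum()),
        "assignment_rate": float(1.0 - unassigned_count / total),
    }


def repeated_stratified_cv(
    counts: ExpressionMatrix,
    labels,
    indicator: IndicatorMatrix,
    config: NetworkConfig | None = None,
    k_folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    **fit_kwargs,
) -> tuple:
    """Repeated cell-type-stratified k-fold cross-validation.

    Per fold: fit the full annotator on the training cells and predict the
    held-out cells; confusions are summed across all folds and repeats.
    Returns ``(aggregated ConfusionMatrix, per-fold metrics DataFrame)``.
    """
    y = np.asarray(labels.reindex(counts.cell_ids) if isinstance(labels, pd.Series) else labels)
    class_sizes = pd.Series(y).value_counts()
    if (class_sizes < k_folds).any():
        small = sorted(class_sizes[class_sizes < k_folds].index)
        raise ValueError(f"classes smaller than k_folds={k_folds}: {small}")
    splitter = RepeatedStratifiedKFold(n_splits=k_folds, n_repeats=repeats, random_state=seed)
    aggregate = None
    fold_rows = []
    for fold_id, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        model = ann_mod.fit(
            counts.subset_cells(train_idx),
            y[train_idx],
            indicator,
            config=config,
            seed=seed + fold_id,
            **fit_kwargs,
        )
        results = ann_mod.predict(model, counts.subset_cells(test_idx))
        cm = confusion(y[test_idx], [r.label for r in results])
        aggregate = cm if aggregate is None else aggregate.add(cm)
        fold_rows.append({"repeat": fold_id // k_folds, "fold": fold_id % k_folds, **metrics(cm)})
    return aggregate, pd.DataFrame(fold_rows)
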
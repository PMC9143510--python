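"""Performance metrics: confusion matrix, accuracy/precision/recall/F1,
ROC curve with trapezoid AUC, and stratified k-fold cross-validation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import PhenodeepError
from .model import NetworkConfig
from .preprocess import PreprocessConfig
from .table import AbundanceTable, SampleMetadata

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_curve",
    "evaluate_predictions",
    "cross_validate",
]


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    roc_thresholds: list[float] = field(default_factory=list)
    confusion: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Counts matrix, rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise PhenodeepError("label vectors differ in length")
    for arr, what in ((t, "true"), (p, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise PhenodeepError(f"{what} label out of range [0, {n_classes})")
    out = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(out, (t, p), 1)
    return out


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def classification_metrics(
    confusion: np.ndarray, positive_index: int = 1
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from a confusion matrix.

    Binary: the positive class is ``positive_index`` (default: label index
    1, the lexicographically second label).  Multiclass: macro-averaged
    one-vs-rest.  Zero denominators give 0 by convention.
    """
    c = np.asarray(confusion, dtype=float)
    if c.size == 0 or c.sum() == 0:
        raise PhenodeepError("empty confusion matrix")
    total = c.sum()
    accuracy = float(np.trace(c) / total)
    n = c.shape[0]
    if n == 2:
        k = positive_index
        tp = c[k, k]
        fp = c[1 - k, k]
        fn = c[k, 1 - k]
        precision, recall, f1 = _prf(tp, fp, fn)
    else:
        ps, rs, fs = [], [], []
        for k in range(n):
            tp = c[k, k]
            fp = c[:, k].sum() - tp
            fn = c[k, :].sum() - tp
            p_, r_, f_ = _prf(tp, fp, fn)
            ps.append(p_)
            rs.append(r_)
            fs.append(f_)
        precision, recall, f1 = float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))
    return accuracy, float(precision), float(recall), float(f1)


def roc_curve(true_labels, positive_scores):
    """ROC points, thresholds, and trapezoid AUC for binary truth.

    Thresholds sweep the distinct scores in descending order with ties
    grouped.  With a single-class truth the AUC is undefined (``None``).
    """
    t = np.asarray(true_labels, dtype=int)
    s = np.asarray(positive_scores, dtype=float)
    if t.shape != s.shape:
        raise PhenodeepError("labels and scores differ in length")
    if len(np.unique(t)) < 2:
        return [(0.0, 0.0), (1.0, 1.0)], [], None
    fpr, tpr, thresholds = _sk_roc_curve(t, s)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, thresholds.tolist(), auc


def evaluate_predictions(
    true_labels, proba: np.ndarray, positive_index: int = 1
) -> EvaluationReport:
    """Full report from integer truth and a class-probability matrix.

    For binary problems the ROC uses the positive class's probability
    column; multiclass AUC is macro one-vs-rest."""
    t = np.asarray(true_labels, dtype=int)
    proba = np.asarray(proba, dtype=float)
    n_classes = proba.shape[1]
    pred = proba.argmax(axis=1)
    conf = confusion_matrix(t, pred, n_classes)
    accuracy, precision, recall, f1 = classification_metrics(conf, positive_index)
    if n_classes == 2:
        points, thresholds, auc = roc_curve(
            (t == positive_index).astype(int), proba[:, positive_index]
        )
    else:
        points, thresholds = [], []
        aucs = []
        for k in range(n_classes):
            _, _, a = roc_curve((t == k).astype(int), proba[:, k])
            if a is not None:
                aucs.append(a)
        auc = float(np.mean(aucs)) if aucs else None
    return EvaluationReport(accuracy, precision, recall, f1, auc, points, thresholds, conf)


def cross_validate(
    table: AbundanceTable,
    meta: SampleMetadata,
    preprocess_config: PreprocessConfig | None = None,
    network_config: NetworkConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Stratified k-fold accuracy with per-fold refit of the preprocessing.

    Abundance filtering and the CSS reference scale are recomputed inside
    each fold from its training portion only, so no information leaks from
    the held-out fold.  Returns per-fold accuracies and their mean.
    """
    from .pipeline import _fit_fold  # local import to avoid a cycle

    pre = preprocess_config or PreprocessConfig()
    net_cfg = network_config or NetworkConfig()
    from .table import align_table_metadata

    table, meta = align_table_metadata(table, meta, "intersect")
    y = meta.encoded(table.sample_ids)
    counts = np.bincount(y, minlength=meta.n_classes)
    small = [meta.label_order[i] for i, c in enumerate(counts) if c < k]
    if small:
        raise PhenodeepError(f"classes smaller than k={k}: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs: list[float] = []
    ids = np.array(table.sample_ids)
    for fold, (train_idx, test_idx) in enumerate(skf.split(ids, y)):
        cfg = replace(net_cfg, seed=net_cfg.seed + fold)
        acc = _fit_fold(
            table,
            meta,
            pre,
            cfg,
            list(ids[train_idx]),
            list(ids[test_idx]),
        )
        accs.append(acc)
    return accs, float(np.mean(accs))
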
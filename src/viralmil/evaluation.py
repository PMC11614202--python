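"""Classifier evaluation: confusion-based metrics, ROC-AUC, the
80/20 + 5-fold cross-validation protocol, and taxonomic-rank accuracy.

Binary metrics follow the standard confusion-matrix definitions:
accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
precision = TP/(TP+FP), and F1 the harmonic mean of precision and recall,
macro-averaged over labels. Ratios with a zero denominator are reported as
NaN sentinels rather than silently as 0, so macro averages are not
distorted. AUC is the area under the ROC curve of the continuous scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import mil_core
from .bags import VirusBag
from .datasets import RANKS, TaxonomyRecord
from .mil_core import BagPrediction, MILConfig

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CrossValidationResult",
    "confusion",
    "metrics",
    "auc_score",
    "cross_validate",
    "rank_accuracy",
    "random_baseline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """One evaluation's metrics; undefined ratios are NaN."""

    auc: float
    accuracy: float
    f1_macro: float
    sensitivity: float
    specificity: float
    precision: float
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc, "accuracy": self.accuracy, "f1_macro": self.f1_macro,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision,
        }


def confusion(predicted: list[int] | np.ndarray, labels: list[int] | np.ndarray) -> ConfusionCounts:
    """Confusion counts for binary hard predictions."""
    predicted = np.asarray(predicted, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predicted.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    return ConfusionCounts(
        tp=int(np.sum((predicted == 1) & (labels == 1))),
        tn=int(np.sum((predicted == 0) & (labels == 0))),
        fp=int(np.sum((predicted == 1) & (labels == 0))),
        fn=int(np.sum((predicted == 0) & (labels == 1))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def _f1_from(prec: float, rec: float) -> float:
    if math.isnan(prec) or math.isnan(rec) or prec + rec == 0:
        return math.nan
    return 2 * prec * rec / (prec + rec)


def auc_score(scores, labels) -> float:
    """Area under the ROC curve (midrank tie handling)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def metrics(scores, predicted, labels) -> MetricReport:
    """Full binary metric report from continuous scores and hard labels.

    F1 is macro-averaged: the per-class F1 of the negative class (treating
    0 as positive) and of the positive class are averaged unweighted.
    """
    c = confusion(predicted, labels)
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    # negative class viewed as positive
    prec_neg = _ratio(c.tn, c.tn + c.fn)
    f1_pos = _f1_from(prec, sens)
    f1_neg = _f1_from(prec_neg, spec)
    f1_macro = np.nanmean([f1_pos, f1_neg]) if not (math.isnan(f1_pos) and math.isnan(f1_neg)) else math.nan
    return MetricReport(
        auc=auc_score(scores, labels),
        accuracy=_ratio(c.tp + c.tn, c.total),
        f1_macro=float(f1_macro),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        counts=c,
    )


def multiclass_metrics(predictions: list[BagPrediction], labels) -> dict[str, float]:
    """Accuracy, macro-F1 and macro one-vs-rest AUC for K-class predictions."""
    from sklearn.metrics import f1_score
    labels = np.asarray(labels, dtype=int)
    hard = np.array([p.label for p in predictions])
    probas = np.stack([np.asarray(p.theta) for p in predictions])
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least two classes in the evaluation set")
    try:
        auc = float(roc_auc_score(labels, probas, multi_class="ovr",
                                  average="macro", labels=np.arange(probas.shape[1])))
    except ValueError:
        auc = math.nan  # a class absent from labels
    return {
        "auc": auc,
        "accuracy": float(np.mean(hard == labels)),
        "f1_macro": float(f1_score(labels, hard, average="macro", zero_division=0)),
    }


@dataclass
class CrossValidationResult:
    """Per-fold held-out-test metrics, the best fold, and fold means."""

    fold_reports: list[MetricReport | dict]
    best_fold: int
    best_params: mil_core.MILParameters
    test_ids: list[str]
    fold_val_auc: list[float] = field(default_factory=list)

    def summary(self) -> dict[str, tuple[float, float]]:
        keys = (self.fold_reports[0].as_dict() if isinstance(self.fold_reports[0], MetricReport)
                else self.fold_reports[0]).keys()
        out = {}
        for k in keys:
            vals = [(r.as_dict() if isinstance(r, MetricReport) else r)[k]
                    for r in self.fold_reports]
            out[k] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out


def cross_validate(bags: list[VirusBag], config: MILConfig, seed: int = 0,
                   n_folds: int = 5, test_frac: float = 0.2) -> CrossValidationResult:
    """The evaluation protocol: stratified 80/20 split, then stratified
    k-fold cross-validation on the 80%, each fold model tested on the 20%.

    Each fold trains on k−1 folds with the held-out fold as the early
    stopping monitor, then is evaluated on the outer 20% test set. The fold
    with the highest monitor AUC is flagged best and its parameters
    returned. Deterministic given ``seed``.
    """
    if len(bags) < 10:
        raise ValueError(f"need at least 10 bags for {n_folds}-fold CV with a test split")
    labels = np.array([b.label for b in bags])
    idx = np.arange(len(bags))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, random_state=seed, stratify=labels)
    test_bags = [bags[i] for i in test_idx]
    test_labels = labels[test_idx]
    binary = config.n_classes == 2

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_reports, fold_val_auc, fold_params = [], [], []
    for fold, (tr, va) in enumerate(skf.split(train_idx, labels[train_idx])):
        fit_bags = [bags[train_idx[i]] for i in tr]
        val_bags = [bags[train_idx[i]] for i in va]
        fold_config = MILConfig(**{**config.__dict__, "seed": config.seed + fold})
        params = mil_core.fit(fit_bags, fold_config, val_bags=val_bags)
        val_preds = mil_core.predict(val_bags, params)
        val_y = np.array([b.label for b in val_bags])
        if binary:
            val_auc = auc_score([p.score for p in val_preds], val_y)
        else:
            val_auc = multiclass_metrics(val_preds, val_y)["auc"]
            if math.isnan(val_auc):
                val_auc = float(np.mean([p.label == y for p, y in zip(val_preds, val_y)]))
        fold_val_auc.append(val_auc)
        fold_params.append(params)

        test_preds = mil_core.predict(test_bags, params)
        if binary:
            fold_reports.append(metrics([p.score for p in test_preds],
                                        [p.label for p in test_preds], test_labels))
        else:
            fold_reports.append(multiclass_metrics(test_preds, test_labels))
    best = int(np.argmax(fold_val_auc))
    return CrossValidationResult(
        fold_reports=fold_reports, best_fold=best, best_params=fold_params[best],
        test_ids=[b.virus_id for b in test_bags], fold_val_auc=fold_val_auc)


def rank_accuracy(predicted_hosts: list[str], true_hosts: list[str],
                  taxonomy: dict[str, TaxonomyRecord]) -> dict[str, dict]:
    """Fraction of predictions whose host shares the true host's taxon per rank.

    A virus whose predicted or true host lacks a taxon at some rank is
    excluded at that rank; the exclusion count is reported alongside.
    """
    if len(predicted_hosts) != len(true_hosts):
        raise ValueError("prediction/truth length mismatch")
    out = {}
    for rank in RANKS:
        hits = n = excluded = 0
        for pred, true in zip(predicted_hosts, true_hosts):
            tp_ = taxonomy.get(pred)
            tt = taxonomy.get(true)
            a = tp_.taxon(rank) if tp_ else None
            b = tt.taxon(rank) if tt else None
            if a is None or b is None:
                excluded += 1
                continue
            n += 1
            hits += a == b
        out[rank] = {"accuracy": hits / n if n else math.nan,
                     "n": n, "excluded": excluded}
    return out


def random_baseline(k: int) -> float:
    """Expected accuracy of a uniform random K-class classifier, 1/K to 3 dp."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return round(1.0 / k, 3)
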
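"""pH labeling, imbalance-aware metrics, and stratified ten-fold evaluation.

The objective outcome label is umbilical-artery pH: a record is
*pathological* when pH < 7.15 and *normal* otherwise.  Following the
clinical convention used throughout, the POSITIVE class is *normal* and the
negative class is *pathological*.

Because pathological records are heavily outnumbered, accuracy alone is
misleading; the report therefore includes F-measure, balanced error rate
(BER), the geometric-mean quality index QI = sqrt(Se * Sp) and the Matthews
correlation coefficient.  Note the numerator placement in the default BER,
(FP/(FN+TP) + FN/(FP+TN)) / 2; the conventional definition
(FN/(TP+FN) + FP/(FP+TN)) / 2 is available with ``ber_standard=True``.

Cross-validation is stratified ten-fold with a fixed seed; normalization
and selection are fitted on the training folds only (pass
``paper_mode=True`` to fit them globally before splitting, reproducing the
leakier historical protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .records import ClinicalMeta
from .features import (
    FeatureMatrix,
    SelectionResult,
    apply_selection,
    ga_normalize,
    minmax_normalize,
    select_auc,
    select_st,
    reduce_pca,
)

__all__ = [
    "ConfusionMatrix", "EvalReport", "label_from_ph", "metrics", "run_cv",
    "DEFAULT_SEED", "PH_THRESHOLD",
]

PH_THRESHOLD = 7.15
DEFAULT_SEED = 20180820
METRIC_NAMES = ["acc", "se", "sp", "precision", "fm", "ber", "qi", "mcc"]


@dataclass
class ConfusionMatrix:
    """Counts with positive = normal, negative = pathological."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class EvalReport:
    classifier: str
    seed: int
    per_fold: list = field(default_factory=list)  # ConfusionMatrix per fold
    metrics: dict = field(default_factory=dict)  # fold-averaged
    per_fold_metrics: list = field(default_factory=list)
    flags: set = field(default_factory=set)

    @property
    def pooled(self) -> ConfusionMatrix:
        out = ConfusionMatrix()
        for cm in self.per_fold:
            out = out + cm
        return out


def label_from_ph(meta: ClinicalMeta) -> str:
    """'pathological' iff pH < 7.15, 'normal' iff pH >= 7.15."""
    if meta.ph is None:
        raise ValueError("unlabeled record: pH absent")
    return "pathological" if meta.ph < PH_THRESHOLD else "normal"


def _safe_div(num: float, den: float, flags: set, name: str) -> float:
    if den == 0:
        flags.add(f"{name}_undefined")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, ber_standard: bool = False) -> tuple[dict, set]:
    """The full metric suite from one confusion matrix; 0/0 cases yield 0
    with a flag."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: set[str] = set()
    tp, fp, fn, tn = float(cm.tp), float(cm.fp), float(cm.fn), float(cm.tn)
    se = _safe_div(tp, tp + fn, flags, "se")
    sp = _safe_div(tn, tn + fp, flags, "sp")
    precision = _safe_div(tp, tp + fp, flags, "precision")
    fm = _safe_div(2 * precision * se, precision + se, flags, "fm")
    if ber_standard:
        ber = 0.5 * (_safe_div(fn, tp + fn, flags, "ber") + _safe_div(fp, fp + tn, flags, "ber"))
    else:
        ber = 0.5 * (_safe_div(fp, fn + tp, flags, "ber") + _safe_div(fn, fp + tn, flags, "ber"))
    qi = float(np.sqrt(se * sp))
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, "mcc")
    out = {
        "acc": (tp + tn) / cm.total,
        "se": se,
        "sp": sp,
        "precision": precision,
        "fm": fm,
        "ber": ber,
        "qi": qi,
        "mcc": mcc,
    }
    return out, flags


def make_classifier(kind: str, seed: int):
    """The three classifier families, with declared default hyperparameters."""
    if kind == "dt":
        return DecisionTreeClassifier(criterion="entropy", ccp_alpha=0.005,
                                      random_state=seed)
    if kind == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", class_weight="balanced",
                   random_state=seed)
    if kind == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=100, random_state=seed,
        )
    raise ValueError(f"unknown classifier {kind!r}")


def _fit_selection(mat: FeatureMatrix, method: Optional[str]) -> Optional[SelectionResult]:
    if method is None or method == "none":
        return None
    if method == "st":
        return select_st(mat)
    if method == "auc":
        return select_auc(mat)
    if method == "pca":
        return reduce_pca(mat)
    raise ValueError(f"unknown selection method {method!r}")


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    pos_t = y_true == "normal"
    pos_p = y_pred == "normal"
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def run_cv(
    mat: FeatureMatrix,
    classifier: str = "adaboost",
    selection: Optional[str] = None,
    normalization: Optional[str] = None,  # None | "ga" | "minmax"
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    paper_mode: bool = False,
    ber_standard: bool = False,
) -> EvalReport:
    """Stratified k-fold evaluation of one classifier family.

    Per fold: fit normalization and selection on the training rows, fit the
    classifier, predict the held-out rows.  ``paper_mode=True`` instead fits
    normalization/selection once on the full matrix before splitting.
    """
    labels = mat.labels
    for cls in ("normal", "pathological"):
        if np.sum(labels == cls) < folds:
            raise ValueError(
                f"class {cls!r} has fewer than {folds} members; use fewer folds"
            )

    def normalize(train: FeatureMatrix, target: FeatureMatrix) -> FeatureMatrix:
        if normalization in (None, "none"):
            return target
        if normalization == "ga":
            return ga_normalize(train, target)
        if normalization == "minmax":
            return minmax_normalize(train, target)
        raise ValueError(f"unknown normalization {normalization!r}")

    if paper_mode:
        mat_global = normalize(mat, mat)
        sel_global = _fit_selection(mat_global, selection)

    report = EvalReport(classifier=classifier, seed=seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(np.zeros(mat.n), labels):
        if paper_mode:
            train = mat_global.subset(tr_idx)
            test = mat_global.subset(te_idx)
            sel = sel_global
        else:
            raw_train = mat.subset(tr_idx)
            train = normalize(raw_train, raw_train)
            test = normalize(raw_train, mat.subset(te_idx))
            sel = _fit_selection(train, selection)
        x_tr = apply_selection(train, sel) if sel else train.values.to_numpy()
        x_te = apply_selection(test, sel) if sel else test.values.to_numpy()
        clf = make_classifier(classifier, seed)
        clf.fit(x_tr, train.labels)
        cm = _confusion(test.labels, clf.predict(x_te))
        report.per_fold.append(cm)
        m, fl = metrics(cm, ber_standard=ber_standard)
        report.per_fold_metrics.append(m)
        report.flags |= fl
    report.metrics = {
        k: float(np.mean([m[k] for m in report.per_fold_metrics])) for k in METRIC_NAMES
    }
    return report
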
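"""Classifier preset registry, confusion-matrix metrics, and the
holdout + cross-validation evaluation protocol.

The registry covers the ten presets commonly used in point-and-click
classification-learner workflows for plant-disease feature tables.  The
published abbreviation expansions for several of these presets are
internally inconsistent (e.g. "Q-SVM" expanded as quantum SVM yet behaving
as the quadratic-kernel preset; "F-KNN" as fuzzy vs fine KNN; "KNB" as
k-nearest-neighbour Bayes vs kernel naive Bayes; "MG-SVM" as multiple-group
vs medium-Gaussian; "SDA" as sparse vs subspace discriminant; "Co-KNN" as
collaborative vs cosine; "C-KNN" as contextual vs cubic).  This registry
implements the widely used preset semantics:

==========  =====================================================
preset id   estimator
==========  =====================================================
C-SVM       cubic-kernel SVM (poly degree 3, coef0=1)
Q-SVM       quadratic-kernel SVM (poly degree 2, coef0=1)
MG-SVM      medium-width Gaussian (RBF) SVM
LDA         linear discriminant analysis
SDA         subspace-discriminant ensemble (bagged LDA on random
            feature subspaces)
F-KNN       fine KNN: k=1, Euclidean
W-KNN       weighted KNN: k=10, inverse-distance weights
Co-KNN      cosine KNN: k=10, cosine metric
C-KNN       cubic KNN: k=10, Minkowski p=3
KNB         kernel naive Bayes (per-class, per-feature Gaussian
            KDE with Scott bandwidth)
==========  =====================================================

Every hyperparameter is overridable through ``make_classifier``.

Metrics follow the standard one-vs-rest reading of a K-class confusion
matrix: per-class sensitivity/recall TP/(TP+FN), precision TP/(TP+FP),
FPR FP/(FP+TN), F1 = 2PR/(P+R), and overall accuracy = trace/total, all
reported in percent.  Macro averages are unweighted means over classes.
Zero-denominator metrics are reported as NaN and flagged, never coerced to
zero.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

__all__ = [
    "PRESET_IDS",
    "KernelNaiveBayes",
    "make_classifier",
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "macro_average",
    "harmonic_f1",
    "evaluate",
    "EvaluationReport",
    "format_report_table",
]


class KernelNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes with a 1-D Gaussian kernel density per class and feature.

    Bandwidth per (class, feature) follows Scott's rule,
    ``h = sigma * n**(-1/5)``, floored at a small epsilon so constant
    features do not produce degenerate densities.
    """

    def __init__(self, bandwidth: Optional[float] = None):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.X_by_class_ = [X[y_idx == c] for c in range(len(self.classes_))]
        self.log_priors_ = np.log(
            np.bincount(y_idx, minlength=len(self.classes_)) / len(y)
        )
        self.bandwidths_ = []
        for Xc in self.X_by_class_:
            if self.bandwidth is not None:
                h = np.full(X.shape[1], float(self.bandwidth))
            else:
                h = Xc.std(axis=0, ddof=1) * Xc.shape[0] ** (-0.2)
            self.bandwidths_.append(np.maximum(h, 1e-9))
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X):
        jll = np.empty((X.shape[0], len(self.classes_)))
        for c, (Xc, h) in enumerate(zip(self.X_by_class_, self.bandwidths_)):
            # log density per feature: logsumexp over training points
            z = (X[:, None, :] - Xc[None, :, :]) / h  # (n, m, d)
            log_k = -0.5 * z**2 - np.log(h * np.sqrt(2 * np.pi))
            log_f = logsumexp(log_k, axis=1) - np.log(Xc.shape[0])  # (n, d)
            jll[:, c] = self.log_priors_[c] + log_f.sum(axis=1)
        return jll

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X)
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


#: Default factory per preset id.  ``seed`` feeds stochastic estimators only.
_PRESETS: Dict[str, Any] = {
    "C-SVM": lambda seed, **kw: SVC(
        kernel="poly", degree=3, coef0=1.0, gamma="scale", C=1.0, **kw
    ),
    "Q-SVM": lambda seed, **kw: SVC(
        kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0, **kw
    ),
    "MG-SVM": lambda seed, **kw: SVC(kernel="rbf", gamma="scale", C=1.0, **kw),
    "LDA": lambda seed, **kw: LinearDiscriminantAnalysis(**kw),
    "SDA": lambda seed, **kw: BaggingClassifier(
        estimator=LinearDiscriminantAnalysis(),
        n_estimators=kw.pop("n_estimators", 30),
        max_features=kw.pop("max_features", 0.5),
        bootstrap=False,
        random_state=seed,
        **kw,
    ),
    "F-KNN": lambda seed, **kw: KNeighborsClassifier(n_neighbors=1, **kw),
    "W-KNN": lambda seed, **kw: KNeighborsClassifier(
        n_neighbors=kw.pop("n_neighbors", 10), weights="distance", **kw
    ),
    "Co-KNN": lambda seed, **kw: KNeighborsClassifier(
        n_neighbors=kw.pop("n_neighbors", 10), metric="cosine", **kw
    ),
    "C-KNN": lambda seed, **kw: KNeighborsClassifier(
        n_neighbors=kw.pop("n_neighbors", 10), metric="minkowski", p=3, **kw
    ),
    "KNB": lambda seed, **kw: KernelNaiveBayes(**kw),
}

PRESET_IDS = tuple(_PRESETS)


def make_classifier(preset_id: str, seed: int = 0, **hyperparams):
    """Instantiate a fresh sklearn estimator for one of the ten presets."""
    try:
        factory = _PRESETS[preset_id]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset_id!r}; choose one of {sorted(_PRESETS)}"
        ) from None
    return factory(seed, **hyperparams)


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: np.ndarray

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class and macro metrics in percent; NaN marks an undefined value
    (zero denominator), with the affected (class, metric) pairs listed in
    ``undefined``."""

    labels: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    fnr: np.ndarray
    fpr: np.ndarray
    accuracy: float
    macro: Dict[str, float] = field(default_factory=dict)
    undefined: list = field(default_factory=list)
    wall_time: float = 0.0

    def as_dict(self) -> dict:
        return {
            "labels": [int(l) if np.issubdtype(type(l), np.integer) else l
                       for l in self.labels],
            "per_class": {
                "recall": self.recall.tolist(),
                "precision": self.precision.tolist(),
                "f1": self.f1.tolist(),
                "fnr": self.fnr.tolist(),
                "fpr": self.fpr.tolist(),
            },
            "macro": self.macro,
            "accuracy": self.accuracy,
            "undefined": self.undefined,
            "wall_time": self.wall_time,
        }


def confusion(y_true, y_pred, k: Optional[int] = None,
              labels: Optional[Sequence] = None) -> ConfusionMatrix:
    """Count K x K confusion matrix.

    ``k`` implies integer labels 1..k; alternatively pass ``labels``
    explicitly.  A prediction or truth outside the label set is rejected.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        if k is None:
            labels = np.unique(np.concatenate([y_true, y_pred]))
        else:
            labels = np.arange(1, k + 1)
    labels = np.asarray(labels)
    seen = set(np.unique(np.concatenate([y_true, y_pred])).tolist())
    if not seen <= set(labels.tolist()):
        raise ValueError(f"labels outside the declared set: {seen - set(labels.tolist())}")
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    return ConfusionMatrix(counts=counts.astype(int), labels=labels)


def _safe_pct(num: np.ndarray, den: np.ndarray):
    """Percent ratio with NaN where the denominator is zero."""
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = 100.0 * num[ok] / den[ok]
    return out


def per_class_metrics(cm: ConfusionMatrix, wall_time: float = 0.0) -> MetricsReport:
    """One-vs-rest metrics from a confusion matrix, in percent.

    recall + FNR = 100 per class; accuracy = 100 * trace / total; F1 is the
    harmonic mean of a class's precision and recall.  Metrics with a zero
    denominator come back NaN and are flagged in ``undefined``.
    """
    c = cm.counts.astype(float)
    if c.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = c.sum() - tp - fn - fp

    recall = _safe_pct(tp, tp + fn)
    precision = _safe_pct(tp, tp + fp)
    fpr = _safe_pct(fp, fp + tn)
    fnr = 100.0 - recall
    with np.errstate(invalid="ignore"):
        f1 = np.where(
            np.isnan(precision) | np.isnan(recall) | ((precision + recall) == 0),
            np.nan,
            2.0 * precision * recall / (precision + recall),
        )
    accuracy = 100.0 * tp.sum() / c.sum()

    undefined = []
    for name, vals in [("recall", recall), ("precision", precision),
                       ("f1", f1), ("fpr", fpr)]:
        for lbl, v in zip(cm.labels, vals):
            if np.isnan(v):
                undefined.append((str(lbl), name))

    macro = {
        name: macro_average(vals)
        for name, vals in [
            ("recall", recall), ("precision", precision), ("f1", f1),
            ("fnr", fnr), ("fpr", fpr),
        ]
    }
    return MetricsReport(
        labels=cm.labels, recall=recall, precision=precision, f1=f1,
        fnr=fnr, fpr=fpr, accuracy=accuracy, macro=macro,
        undefined=undefined, wall_time=wall_time,
    )


def macro_average(values) -> float:
    """Unweighted mean of the defined (non-NaN) per-class values; NaN if
    every value is undefined."""
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if not ok.any():
        return float("nan")
    return float(values[ok].mean())


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2PR/(P+R) on whatever scale P and R share."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Both evaluation surfaces, kept distinct: K-fold CV on the training
    split, and the untouched holdout split."""

    preset_id: str
    cv: MetricsReport
    holdout: MetricsReport
    protocol: dict

    def as_dict(self) -> dict:
        return {
            "preset_id": self.preset_id,
            "cv": self.cv.as_dict(),
            "holdout": self.holdout.as_dict(),
            "protocol": self.protocol,
        }


def evaluate(
    preset_id: str,
    X,
    y,
    holdout_fraction: float = 0.2,
    cv_folds: int = 10,
    seed: int = 0,
    hyperparams: Optional[dict] = None,
) -> EvaluationReport:
    """Stratified holdout + CV evaluation of one classifier preset.

    The data are split stratified into (1 - holdout_fraction) training and
    holdout_fraction testing.  Cross-validated metrics are computed on the
    training split only; holdout metrics on the untouched test split.  The
    two are reported side by side and never mixed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    hyperparams = hyperparams or {}
    labels = np.unique(y)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=seed
    )
    for part, name in [(y_tr, "training"), (y_te, "holdout")]:
        if len(np.unique(part)) < len(labels):
            raise ValueError(f"a class is absent from the {name} partition")

    # CV surface on the training split
    t0 = time.perf_counter()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_pred = np.empty_like(y_tr)
    for tr_idx, te_idx in skf.split(X_tr, y_tr):
        clf = make_classifier(preset_id, seed=seed, **hyperparams)
        clf.fit(X_tr[tr_idx], y_tr[tr_idx])
        cv_pred[te_idx] = clf.predict(X_tr[te_idx])
    cv_report = per_class_metrics(
        confusion(y_tr, cv_pred, labels=labels), wall_time=time.perf_counter() - t0
    )

    # Holdout surface
    t0 = time.perf_counter()
    clf = make_classifier(preset_id, seed=seed, **hyperparams)
    clf.fit(X_tr, y_tr)
    ho_pred = clf.predict(X_te)
    ho_report = per_class_metrics(
        confusion(y_te, ho_pred, labels=labels), wall_time=time.perf_counter() - t0
    )

    return EvaluationReport(
        preset_id=preset_id,
        cv=cv_report,
        holdout=ho_report,
        protocol={
            "holdout_fraction": holdout_fraction,
            "cv_folds": cv_folds,
            "seed": seed,
            "n_samples": int(len(y)),
            "hyperparams": hyperparams,
        },
    )


def format_report_table(reports: Sequence[EvaluationReport],
                        surface: str = "holdout") -> str:
    """Plain-text table: Recall, Precision, FNR, Time, F1, Accuracy per
    preset (macro values), mirroring the usual results-table layout."""
    header = (
        f"{'Classifier':<10} {'Recall(%)':>10} {'Precision(%)':>13} "
        f"{'FNR(%)':>8} {'Time(s)':>9} {'F1(%)':>8} {'Accuracy(%)':>12}"
    )
    lines = [header]
    for rep in reports:
        m = getattr(rep, surface)
        lines.append(
            f"{rep.preset_id:<10} {m.macro['recall']:>10.2f} "
            f"{m.macro['precision']:>13.2f} {m.macro['fnr']:>8.2f} "
            f"{m.wall_time:>9.3f} {m.macro['f1']:>8.2f} {m.accuracy:>12.2f}"
        )
    return "\n".join(lines)
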
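"""Venetian-blinds cross-validation, latent-variable selection and metrics.

Venetian blinds assigns sample ``i`` (in stored data order) to fold
``i mod n_splits`` — the scheme the study software uses with ten splits.  For
every candidate number of latent variables the cross-validated classification
error average is computed, defined per class (one-vs-rest) as

    error_k = 1 - (sensitivity_k + specificity_k) / 2

and averaged over classes; the number of latent variables is the one
minimising this CV error (ties resolved toward fewer components).  The same
machinery reports RMSECV/RMSEC per class, ROC curves (calibration and
cross-validated) and the confusion matrix at the chosen complexity.

Scaling is refit inside every training fold by default so no held-out
statistics leak into the model; ``scale_once=True`` reproduces the
fit-once-on-everything alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plsda import (
    DummyMatrix,
    GaussianThresholds,
    _nipals,
    classify,
    encode_labels,
    fit_gaussian_thresholds,
)
from .preprocess import autoscale_apply, autoscale_fit

__all__ = [
    "CVScheme",
    "CVCurve",
    "ClassificationReport",
    "venetian_blinds_folds",
    "confusion_matrix",
    "classification_error_average",
    "roc_curve",
    "cross_validate",
]


@dataclass(frozen=True)
class CVScheme:
    kind: str = "venetian_blinds"
    n_splits: int = 10

    def __post_init__(self) -> None:
        if self.kind != "venetian_blinds":
            raise ValueError(f"unknown CV scheme {self.kind!r}")
        if self.n_splits < 2:
            raise ValueError("n_splits must be at least 2")


def venetian_blinds_folds(n: int, scheme: CVScheme) -> np.ndarray:
    """Fold index per sample: position i -> i mod n_splits."""
    if n < 2:
        raise ValueError("need at least two samples to cross-validate")
    if n < scheme.n_splits:
        warnings.warn(
            f"only {n} samples for {scheme.n_splits} splits; "
            "folds collapse to leave-one-out",
            stacklevel=2,
        )
        return np.arange(n)
    return np.arange(n) % scheme.n_splits


def confusion_matrix(true_idx: np.ndarray, pred_idx: np.ndarray, c: int) -> np.ndarray:
    """c x c counts, rows = true class, columns = predicted class."""
    conf = np.zeros((c, c), dtype=int)
    np.add.at(conf, (np.asarray(true_idx), np.asarray(pred_idx)), 1)
    return conf


def classification_error_average(confusion: np.ndarray) -> float:
    """Mean over classes of the one-vs-rest balanced error.

    For class k: error_k = 1 - (sensitivity_k + specificity_k)/2, computed
    from the confusion matrix in one-vs-rest terms.
    """
    conf = np.asarray(confusion, dtype=float)
    c = conf.shape[0]
    total = conf.sum()
    errors = np.zeros(c)
    for k in range(c):
        pos = conf[k].sum()
        if pos == 0:
            raise ValueError(f"true class {k} has no samples")
        tp = conf[k, k]
        fp = conf[:, k].sum() - tp
        neg = total - pos
        sens = tp / pos
        spec = (neg - fp) / neg if neg > 0 else 1.0
        errors[k] = 1.0 - 0.5 * (sens + spec)
    return float(errors.mean())


def roc_curve(scores: np.ndarray, truth: np.ndarray):
    """ROC points over all distinct score thresholds plus trapezoidal area.

    ``truth`` is boolean (in-class / out-of-class).  Returns
    ``(fpr, tpr, thresholds, auc)`` with the curve ordered from the strictest
    threshold (0, 0) to the loosest (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    tps = np.cumsum(t)
    fps = np.cumsum(~t)
    distinct = np.flatnonzero(np.diff(s) != 0)
    idx = np.r_[distinct, s.size - 1]
    tpr = np.r_[0.0, tps[idx] / n_pos]
    fpr = np.r_[0.0, fps[idx] / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


@dataclass
class CVCurve:
    """Per-LV cross-validation and calibration summaries."""

    A_values: np.ndarray          # 1..A_max
    cv_error_avg: np.ndarray      # (A_max,)
    cal_error_avg: np.ndarray     # (A_max,)
    rmsecv: np.ndarray            # (A_max, c)
    rmsec: np.ndarray             # (A_max, c)
    class_order: tuple[str, ...]
    chosen_A: int

    def to_frame(self) -> pd.DataFrame:
        rows = {"A": self.A_values,
                "cv_error_avg": self.cv_error_avg,
                "cal_error_avg": self.cal_error_avg}
        for j, cls in enumerate(self.class_order):
            rows[f"rmsecv_{cls}"] = self.rmsecv[:, j]
            rows[f"rmsec_{cls}"] = self.rmsec[:, j]
        return pd.DataFrame(rows)


@dataclass
class ClassificationReport:
    """Everything the study reports at the chosen model complexity."""

    class_order: tuple[str, ...]
    chosen_A: int
    confusion: np.ndarray             # rows true, columns predicted (CV)
    per_class_tpr: np.ndarray
    overall_accuracy: float
    n_correct: int
    n_samples: int
    cv_predictions: np.ndarray        # n x c dummy values at chosen_A
    cal_predictions: np.ndarray       # n x c training predictions at chosen_A
    scores: np.ndarray                # n x chosen_A full-data X-scores
    roc: dict = field(default_factory=dict)   # per class: cv/cal curves + auc
    thresholds: GaussianThresholds | None = None

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "chosen_A": self.chosen_A,
            "confusion": self.confusion.tolist(),
            "per_class_tpr": self.per_class_tpr.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "n_correct": self.n_correct,
            "n_samples": self.n_samples,
            "roc": {
                cls: {
                    curve: {k: np.asarray(v).tolist() for k, v in data.items()}
                    for curve, data in curves.items()
                }
                for cls, curves in self.roc.items()
            },
            "thresholds": None if self.thresholds is None else self.thresholds.thresholds.tolist(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _per_component_predictions(Xs_tr, Yc_tr, Xs_te, A_max):
    """Cumulative test-set predictions for A = 1..A_max from one NIPALS run.

    P'W is unit upper triangular for NIPALS, so the coefficient matrix for
    the first A components is a prefix of the full decomposition.
    """
    W, P, Q, T = _nipals(Xs_tr, Yc_tr, A_max)
    R = W @ np.linalg.solve(P.T @ W, np.eye(A_max))
    T_te = Xs_te @ R                              # n_te x A
    increments = T_te[:, :, None] * Q.T[None, :, :]   # n_te x A x c
    return np.cumsum(increments, axis=1), (W, P, Q, T, R)


def cross_validate(
    X: np.ndarray,
    labels,
    scheme: CVScheme = CVScheme(),
    A_max: int = 20,
    rule: str = "argmax",
    scale_once: bool = False,
):
    """Cross-validate PLS-DA over A = 1..A_max and report at the best A.

    Returns ``(CVCurve, ClassificationReport)``.  Scaling and Y-centring are
    refit on each training fold unless ``scale_once`` is set.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    dummy = encode_labels(labels)
    c = dummy.Y.shape[1]
    true_idx = np.argmax(dummy.Y, axis=1)
    folds = venetian_blinds_folds(n, scheme)
    min_train = min(int(n - (folds == f).sum()) for f in np.unique(folds))
    if not 1 <= A_max <= min(min_train - 1, p):
        raise ValueError(
            f"A_max={A_max} out of range 1..min(n_train-1={min_train - 1}, p={p})"
        )

    global_scaling = autoscale_fit(X) if scale_once else None

    cv_pred = np.zeros((n, A_max, c))
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        Ytr = dummy.Y[tr]
        if np.any(Ytr.sum(axis=0) == 0):
            missing = dummy.class_order[int(np.argmin(Ytr.sum(axis=0)))]
            warnings.warn(
                f"training fold {f} lacks class {missing!r}", stacklevel=2
            )
        scaling = global_scaling if scale_once else autoscale_fit(X[tr])
        Xs_tr = autoscale_apply(scaling, X[tr])
        Xs_te = autoscale_apply(scaling, X[te])
        y_means = Ytr.mean(axis=0)
        preds, _ = _per_component_predictions(Xs_tr, Ytr - y_means, Xs_te, A_max)
        cv_pred[te] = preds + y_means

    # calibration fit on all samples
    scaling = autoscale_fit(X)
    Xs = autoscale_apply(scaling, X)
    y_means = dummy.Y.mean(axis=0)
    cal_pred_cum, (W, P, Q, T, R) = _per_component_predictions(
        Xs, dummy.Y - y_means, Xs, A_max
    )
    cal_pred = cal_pred_cum + y_means

    A_values = np.arange(1, A_max + 1)
    cv_err = np.zeros(A_max)
    cal_err = np.zeros(A_max)
    rmsecv = np.zeros((A_max, c))
    rmsec = np.zeros((A_max, c))
    for a in range(A_max):
        for pred, err, rmse in (
            (cv_pred[:, a, :], cv_err, rmsecv),
            (cal_pred[:, a, :], cal_err, rmsec),
        ):
            pred_idx = np.argmax(pred, axis=1)
            conf = confusion_matrix(true_idx, pred_idx, c)
            if err is cv_err:
                cv_err[a] = classification_error_average(conf)
            else:
                cal_err[a] = classification_error_average(conf)
            rmse[a] = np.sqrt(np.mean((pred - dummy.Y) ** 2, axis=0))

    chosen_A = int(A_values[np.argmin(cv_err)])  # argmin takes the smallest A on ties
    curve = CVCurve(
        A_values=A_values,
        cv_error_avg=cv_err,
        cal_error_avg=cal_err,
        rmsecv=rmsecv,
        rmsec=rmsec,
        class_order=dummy.class_order,
        chosen_A=chosen_A,
    )

    yhat_cv = cv_pred[:, chosen_A - 1, :]
    yhat_cal = cal_pred[:, chosen_A - 1, :]
    thresholds = None
    if rule == "gaussian_threshold":
        thresholds = fit_gaussian_thresholds(yhat_cal, dummy)
    pred_labels = classify(yhat_cv, dummy.class_order, rule=rule, thresholds=thresholds)
    pred_idx = np.array([dummy.class_order.index(l) for l in pred_labels])
    conf = confusion_matrix(true_idx, pred_idx, c)
    tpr = conf.diagonal() / conf.sum(axis=1)
    n_correct = int(conf.trace())

    roc = {}
    for k, cls in enumerate(dummy.class_order):
        truth = dummy.Y[:, k] == 1
        curves = {}
        for name, yhat in (("cal", yhat_cal[:, k]), ("cv", yhat_cv[:, k])):
            fpr, tpr_k, thr, auc = roc_curve(yhat, truth)
            curves[name] = {"fpr": fpr, "tpr": tpr_k, "thresholds": thr, "auc": auc}
        if thresholds is not None:
            curves["operating_threshold"] = {"value": np.array([thresholds.thresholds[k]])}
        roc[cls] = curves

    report = ClassificationReport(
        class_order=dummy.class_order,
        chosen_A=chosen_A,
        confusion=conf,
        per_class_tpr=tpr,
        overall_accuracy=n_correct / n,
        n_correct=n_correct,
        n_samples=n,
        cv_predictions=yhat_cv,
        cal_predictions=yhat_cal,
        scores=T[:, :chosen_A],
        roc=roc,
        thresholds=thresholds,
    )
    return curve, report
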
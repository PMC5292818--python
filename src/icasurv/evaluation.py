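"""Logistic combination index and ROC-based prediction metrics.

Significant risk factors are combined into a single per-subject index by a
maximum-likelihood logistic fit (IRLS); prediction of converter status is
summarised by the ROC curve, trapezoidal AUC and accuracy / sensitivity /
specificity (in percent) at an operating threshold chosen by Youden's J
(default) or a fixed cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LogisticResult",
    "RocResult",
    "fit_logistic",
    "roc_curve",
    "auc",
    "classification_metrics",
    "evaluate_index",
]


@dataclass
class LogisticResult:
    weights: pd.Series
    intercept: float
    index: np.ndarray          # fitted probability per subject
    n_iter: int
    converged: bool
    separation: bool = False


@dataclass
class RocResult:
    """Table-4-style prediction summary for one combined index."""

    auc: float
    accuracy: float            # percent
    sensitivity: float         # percent
    specificity: float         # percent
    operating_threshold: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    thresholds: np.ndarray = field(repr=False, default=None)


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def fit_logistic(
    factors: pd.DataFrame,
    labels,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticResult:
    """Maximum-likelihood logistic regression by IRLS.

    Complete separation is detected (diverging coefficients with perfect
    classification); the fit is then stopped, capped and flagged with a
    warning rather than raised.
    """
    y = _check_labels(labels)
    x = factors.to_numpy(dtype=float)
    if np.any(x.std(axis=0) == 0):
        bad = [c for c, s in zip(factors.columns, x.std(axis=0)) if s == 0]
        raise ValueError(f"constant factor column(s): {bad}")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise ValueError("collinear factor columns")
    design = np.column_stack([np.ones(len(y)), x])
    w = np.zeros(design.shape[1])
    converged = separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(design @ w, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        weight = np.clip(mu * (1 - mu), 1e-12, None)
        grad = design.T @ (y - mu)
        hess = design.T @ (design * weight[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        w = w + step
        if np.linalg.norm(step) < tol:
            converged = True
            break
        if np.abs(w[1:] * x.std(axis=0)).max() > 30:
            predicted = (design @ w) > 0
            if np.array_equal(predicted, y.astype(bool)):
                separation = True
                warnings.warn(
                    "complete separation: logistic coefficients capped",
                    RuntimeWarning,
                )
                break
    eta = np.clip(design @ w, -500, 500)
    return LogisticResult(
        weights=pd.Series(w[1:], index=factors.columns),
        intercept=float(w[0]),
        index=1.0 / (1.0 + np.exp(-eta)),
        n_iter=it,
        converged=converged,
        separation=separation,
    )


def roc_curve(index, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points for the inclusive rule ``score >= threshold -> positive``.

    One point per distinct score, preceded by (0, 0) at threshold +inf; the
    final point is (1, 1).  FPR and TPR are non-decreasing.
    """
    y = _check_labels(labels)
    s = np.asarray(index, dtype=float)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    n_pos, n_neg = y.sum(), (1 - y).sum()
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[distinct]])
    return fpr, tpr, thresholds


def auc(index, labels) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Equals the pairwise concordance probability (ties counted one half).
    """
    fpr, tpr, _ = roc_curve(index, labels)
    return float(np.trapezoid(tpr, fpr))


def classification_metrics(
    index,
    labels,
    rule: str = "youden",
    threshold: float = 0.5,
) -> tuple[float, float, float, float]:
    """Accuracy, sensitivity and specificity (percent) at an operating point.

    ``rule="youden"`` maximises J = sensitivity + specificity - 1 over all
    candidate thresholds (ties resolved toward higher sensitivity);
    ``rule="fixed"`` uses the given ``threshold``.  The positive decision is
    ``score >= threshold``.
    """
    y = _check_labels(labels)
    s = np.asarray(index, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if rule == "fixed":
        thr = float(threshold)
    elif rule == "youden":
        fpr, tpr, thresholds = roc_curve(s, y)
        j = tpr - fpr
        best = np.flatnonzero(j == j.max())
        # ties -> higher sensitivity; curve is ordered by decreasing threshold
        # so later indices have higher TPR
        thr = float(thresholds[best[np.argmax(tpr[best])]])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    pred = s >= thr
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = 100.0 * tp / n_pos
    spec = 100.0 * tn / n_neg
    acc = 100.0 * (tp + tn) / len(y)
    return acc, sens, spec, thr


def evaluate_index(
    factors: pd.DataFrame,
    labels,
    rule: str = "youden",
    threshold: float = 0.5,
) -> RocResult:
    """Combine factors into a logistic index and score it (in sample)."""
    fit = fit_logistic(factors, labels)
    fpr, tpr, thresholds = roc_curve(fit.index, labels)
    acc, sens, spec, thr = classification_metrics(
        fit.index, labels, rule=rule, threshold=threshold
    )
    return RocResult(
        auc=float(np.trapezoid(tpr, fpr)),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        operating_threshold=thr,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
    )
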
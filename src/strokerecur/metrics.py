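"""Classification performance: confusion-matrix metrics, ROC/AUC with DeLong
variance, Youden-optimal thresholds, bootstrap metric distributions, and the
paired DeLong comparison of two correlated AUCs.

Conventions: probabilities >= threshold predict the event; metrics whose
denominator is empty are reported as NaN (undefined), never silently 0; F1
and accuracy are reported on the 0-100 scale and all other metrics on [0,1],
mirroring the report layout this package reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rand import child_rng

__all__ = [
    "MetricSet",
    "confusion_metrics",
    "roc_auc",
    "bootstrap_metrics",
    "delong_compare",
    "evaluate_model",
]


@dataclass
class MetricSet:
    """One model's metric row; F1/accuracy on 0-100, everything else on [0,1]."""

    auc: float = float("nan")
    auc_ci: tuple[float, float] | None = None
    best_threshold: float = float("nan")
    youden: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    f1: float = float("nan")
    accuracy: float = float("nan")
    recall: float = float("nan")
    precision: float = float("nan")

    def to_series(self) -> pd.Series:
        d = {
            "auc": self.auc,
            "auc_ci_lower": self.auc_ci[0] if self.auc_ci else float("nan"),
            "auc_ci_upper": self.auc_ci[1] if self.auc_ci else float("nan"),
            "best_threshold": self.best_threshold,
            "youden": self.youden,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
        }
        return pd.Series(d)


def _validate(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return p, y


def confusion_metrics(probs, labels, threshold: float = 0.5) -> MetricSet:
    """Threshold-dependent metrics from the 2x2 confusion table."""
    p, y = _validate(probs, labels)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    f1 = (
        2.0 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    acc = _ratio(tp + tn, tp + fp + fn + tn)
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        recall=sens,
        f1=100.0 * f1,
        accuracy=100.0 * acc,
    )


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (ties get the average rank), 1-based."""
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_cov(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for k score vectors on shared labels.

    scores: (k, n). Returns (aucs (k,), cov (k,k)). Requires both classes.
    """
    pos = labels == 1
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong requires both classes present")
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        x = scores[r, pos]
        y = scores[r, ~pos]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    def _cov(v: np.ndarray) -> np.ndarray:
        # variance inestimable from a single positive/negative: report NaN
        if v.shape[1] < 2:
            return np.full((k, k), np.nan)
        return np.atleast_2d(np.cov(v))

    cov = _cov(v01) / m + _cov(v10) / n
    return aucs, cov


def roc_auc(probs, labels, level: float = 0.95) -> MetricSet:
    """AUC with DeLong CI plus the Youden-optimal observed threshold.

    Among thresholds tied on the Youden index, the lowest is reported.
    Constant scores yield AUC 0.5 with a warning.
    """
    from sklearn.metrics import roc_curve

    p, y = _validate(probs, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    out = MetricSet()
    if np.all(p == p[0]):
        warnings.warn("constant scores: AUC is 0.5 by convention")
        out.auc = 0.5
        out.auc_ci = (float("nan"), float("nan"))
        out.best_threshold = float(p[0])
        out.youden = 0.0
        return out
    aucs, cov = _delong_cov(p[None, :], y)
    out.auc = float(aucs[0])
    z = norm.ppf(0.5 + level / 2.0)
    se = float(np.sqrt(cov[0, 0]))
    out.auc_ci = (max(0.0, out.auc - z * se), min(1.0, out.auc + z * se))

    fpr, tpr, thr = roc_curve(y, p, drop_intermediate=False)
    j = tpr - fpr
    observed = np.arange(len(thr)) > 0  # thr[0] is the +inf sentinel
    jmax = j[observed].max()
    ties = observed & (j >= jmax - 1e-15)
    best = float(thr[np.nonzero(ties)[0].max()])  # thresholds descend: last tie = lowest
    out.best_threshold = best
    out.youden = float(jmax)
    return out


def delong_compare(probs_a, probs_b, labels) -> dict:
    """Paired DeLong test of AUC(A) − AUC(B) on the same patients."""
    pa, y = _validate(probs_a, labels)
    pb, y2 = _validate(probs_b, labels)
    if pa.shape != pb.shape:
        raise ValueError("paired score vectors must have equal length")
    aucs, cov = _delong_cov(np.vstack([pa, pb]), y)
    diff = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if np.isnan(var):
        z_stat = float("nan")
    elif var <= 0:
        z_stat = 0.0 if diff == 0 else float("inf") * np.sign(diff)
    else:
        z_stat = diff / np.sqrt(var)
    if np.isnan(z_stat):
        p_value = float("nan")
    else:
        p_value = float(2.0 * norm.sf(abs(z_stat))) if np.isfinite(z_stat) else 0.0
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return {
        "auc_a": float(aucs[0]),
        "auc_b": float(aucs[1]),
        "z": float(z_stat),
        "p_value": p_value,
        "diff": diff,
        "diff_ci": (diff - half, diff + half),
    }


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_metrics(
    probs,
    labels,
    n_boot: int = 1000,
    threshold: float = 0.5,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Percentile CIs and spreads of the metric suite under patient resampling.

    Resamples missing one of the classes are redrawn and counted; more than
    20% redraws aborts.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    p, y = _validate(probs, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("bootstrap requires both classes in the input")
    rng = child_rng(seed, "bootstrap")
    n = len(y)
    rows = []
    redraws = 0
    max_redraws = int(0.2 * n_boot)
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            redraws += 1
            if redraws > max_redraws:
                raise ValueError(
                    f"bootstrap aborted: more than {max_redraws} single-class resamples"
                )
        ms = confusion_metrics(p[idx], y[idx], threshold)
        ra = roc_auc(p[idx], y[idx])
        row = ms.to_series()
        row["auc"] = ra.auc
        rows.append(row)
    draws = pd.DataFrame(rows)
    alpha = 1.0 - level
    summary = pd.DataFrame(
        {
            "mean": draws.mean(),
            "sd": draws.std(ddof=1),
            "ci_lower": draws.quantile(alpha / 2.0),
            "ci_upper": draws.quantile(1.0 - alpha / 2.0),
        }
    )
    return {"summary": summary, "n_redraws": redraws}


def evaluate_model(probs, labels, threshold: float = 0.5) -> MetricSet:
    """Full metric row: ROC/AUC quantities plus confusion metrics at `threshold`."""
    ms = confusion_metrics(probs, labels, threshold)
    ra = roc_auc(probs, labels)
    ms.auc = ra.auc
    ms.auc_ci = ra.auc_ci
    ms.best_threshold = ra.best_threshold
    ms.youden = ra.youden
    return ms
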
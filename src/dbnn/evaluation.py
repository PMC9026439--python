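"""Prediction and the full metric/statistics panel.

Conventions: the positive class is pCR throughout; a pair is predicted
positive when its pCR softmax probability is >= the decision threshold
(default 0.5).  The evaluation unit is the image pair; a patient-level
majority-vote aggregate is available separately.

AUC is the Mann-Whitney pair statistic, its confidence interval and the
paired comparison of two correlated AUCs use DeLong's structural
components (nonparametric AUC variance/covariance estimator with a
normal approximation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ValidationError, ContractError, ReconstructionError
from .manifest import load_pairs


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class MetricsReport:
    """Metric panel; a field is None where its denominator is zero."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    n_pos: int
    n_neg: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def undefined_fields(self) -> list[str]:
        return [k for k in ("accuracy", "sensitivity", "specificity",
                            "ppv", "npv", "f1") if getattr(self, k) is None]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


# ---------------------------------------------------------------- predict

def predict(model, manifest: pd.DataFrame, split: str = "test",
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-pair pCR probability for one split.

    Returns ``(scores, labels, pairs)`` with ``labels`` binary
    (1 = pCR) and ``pairs`` the provenance table.
    """
    pre, post, y, pairs = load_pairs(manifest, split)
    scores = np.concatenate(
        [model.forward(pre[i:i + batch_size], post[i:i + batch_size])[:, 0]
         for i in range(0, len(pre), batch_size)])
    return scores, y[:, 0].astype(int), pairs


def aggregate_patients(scores: np.ndarray, labels: np.ndarray,
                       patient_ids) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level mean-score aggregate (majority vote on thresholded
    scores equals thresholding this mean for symmetric votes)."""
    df = pd.DataFrame({"pid": patient_ids, "score": scores, "label": labels})
    g = df.groupby("pid").agg(score=("score", "mean"), label=("label", "first"))
    return g["score"].to_numpy(), g["label"].to_numpy()


# ---------------------------------------------------------------- metrics

def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ContractError(f"scores {scores.shape} vs labels {labels.shape}")
    if scores.size == 0:
        raise ValidationError("empty input")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary 0/1 (1 = pCR)")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(tp=int(np.sum(pred & pos)),
                           fp=int(np.sum(pred & ~pos)),
                           fn=int(np.sum(~pred & pos)),
                           tn=int(np.sum(~pred & ~pos)))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and
    F1 = 2TP / (2TP + FP + FN); undefined cells are None, never 0."""
    f1_den = 2 * c.tp + c.fp + c.fn
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.n),
        sensitivity=_ratio(c.tp, c.n_pos),
        specificity=_ratio(c.tn, c.n_neg),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        f1=(2 * c.tp / f1_den) if f1_den > 0 else None,
        n_pos=c.n_pos, n_neg=c.n_neg)


# ---------------------------------------------------------------- ROC / AUC

def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValidationError("both classes must be present")
    return pos, ~pos


def auc_mann_whitney(scores, labels) -> float:
    """AUC as (#concordant + 0.5 * #ties) / (n_pos * n_neg), via ranks."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    r = stats.rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    return (r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr), auc_mann_whitney(scores, labels)


# ---------------------------------------------------------------- DeLong

def _delong_components(scores: np.ndarray, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus structural components V10 (per positive) and V01 (per
    negative), where psi(x, y) = 1[x > y] + 0.5 * 1[x == y]."""
    pos, neg = _check_two_classes(labels)
    x = np.asarray(scores, dtype=float)[pos]
    y = np.asarray(scores, dtype=float)[neg]
    # psi matrix via broadcasting; m, n are a few hundred at most here
    diff = x[:, None] - y[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(scores, labels) -> tuple[float, float]:
    auc, v10, v01 = _delong_components(np.asarray(scores), labels)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValidationError("need at least 2 samples per class")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with its DeLong normal-approximation CI, clipped to [0, 1]."""
    auc, var = delong_variance(scores, labels)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired (same items) covariance-corrected z-test for two correlated
    AUCs; returns (z, two-sided p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape or scores_a.shape != np.asarray(labels).shape:
        raise ContractError("score vectors and labels must have identical length")
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise ValidationError("need at least 2 samples per class")
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    s = s10 / m + s01 / n
    var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------- Mann-Whitney

def mann_whitney(x_sample, y_sample) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small tie-free
    samples (both n <= 8), tie-corrected normal approximation otherwise."""
    x = np.asarray(x_sample, dtype=float)
    y = np.asarray(y_sample, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------- panel

def full_report(scores, labels, threshold: float = 0.5,
                level: float = 0.95) -> MetricsReport:
    rep = metrics(confusion(scores, labels, threshold))
    auc, lo, hi = delong_ci(scores, labels, level)
    rep.auc, rep.auc_ci = auc, (lo, hi)
    return rep


# ---------------------------------------------------------------- inversion

def reconstruct_confusion(accuracy: float, sensitivity: float,
                          n_pos: int, n_neg: int,
                          decimals: int = 2) -> ConfusionCounts:
    """Invert a printed (accuracy %, sensitivity %) panel back to integer
    confusion counts by exhaustive search over tp and tn.

    Raises :class:`ReconstructionError` when no or several integer
    solutions reproduce the rounded percentages — never a silent guess.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("n_pos and n_neg must be >= 1")
    n = n_pos + n_neg
    matches = []
    for tp in range(n_pos + 1):
        if round(100.0 * tp / n_pos, decimals) != round(sensitivity, decimals):
            continue
        for tn in range(n_neg + 1):
            if round(100.0 * (tp + tn) / n, decimals) == round(accuracy, decimals):
                matches.append(ConfusionCounts(tp=tp, fp=n_neg - tn,
                                               fn=n_pos - tp, tn=tn))
    if len(matches) != 1:
        raise ReconstructionError(
            f"printed panel (accuracy={accuracy}, sensitivity={sensitivity}, "
            f"n_pos={n_pos}, n_neg={n_neg}) admits {len(matches)} integer "
            f"solutions", candidates=matches)
    return matches[0]
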
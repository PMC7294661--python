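"""ROC curves, AUC and the DeLong test for correlated AUCs.

Two independent AUC code paths are kept deliberately: a rank-based
Mann-Whitney estimator (ties credited 0.5) and the trapezoidal area under
the empirical ROC staircase; they agree to machine precision on every input
and are cross-asserted in the test suite. Integer composite scores produce
heavy ties, so explicit 0.5 tie crediting matters.

A patient is called positive when their score is at or above the threshold
(the published cut-off is phrased ">= 10 points"), and candidate thresholds
are the observed score values.

The DeLong variance/covariance machinery works on placement values: the
placement of an event is the fraction of non-events it outranks (ties count
half), and vice versa. The two-model comparison is reported as a 1-df
chi-square, (AUC_a - AUC_b)^2 / var(diff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCCurve",
    "AUCComparison",
    "roc_curve",
    "auc_mann_whitney",
    "delong_compare",
    "delong_variance",
    "best_cutoff",
]


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray     # descending; leading +inf gives the (0, 1) corner
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    statistic: float
    p_value: float


def _split(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must be the same length")
    if np.isnan(scores).any():
        raise ValueError("scores must not contain NaN")
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    return pos, neg


def roc_curve(scores, outcomes) -> ROCCurve:
    """Empirical ROC: one operating point per distinct observed score."""
    pos, neg = _split(scores, outcomes)
    thresholds = np.concatenate(
        [[np.inf], np.unique(np.concatenate([pos, neg]))[::-1]])
    sens = np.array([(pos >= t).mean() if np.isfinite(t) else 0.0
                     for t in thresholds])
    spec = np.array([(neg < t).mean() if np.isfinite(t) else 1.0
                     for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds=thresholds, sensitivities=sens,
                    specificities=spec, auc=auc)


def auc_mann_whitney(scores, outcomes) -> float:
    """AUC as the tie-corrected probability an event outranks a non-event."""
    pos, neg = _split(scores, outcomes)
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    greater = pos[:, None] > neg[None, :]
    tied = pos[:, None] == neg[None, :]
    psi = greater + 0.5 * tied
    v_pos = psi.mean(axis=1)   # per-event placement
    v_neg = psi.mean(axis=0)   # per-non-event placement
    return v_pos, v_neg, float(psi.mean())


def delong_variance(scores, outcomes) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single score."""
    pos, neg = _split(scores, outcomes)
    v_pos, v_neg, auc = _placements(pos, neg)
    var = (np.var(v_pos, ddof=1) / len(pos) if len(pos) > 1 else 0.0) + \
          (np.var(v_neg, ddof=1) / len(neg) if len(neg) > 1 else 0.0)
    return auc, float(var)


def delong_compare(scores_a, scores_b, outcomes) -> AUCComparison:
    """DeLong test of two correlated AUCs measured on the same patients."""
    pos_a, neg_a = _split(scores_a, outcomes)
    pos_b, neg_b = _split(scores_b, outcomes)
    va_pos, va_neg, auc_a = _placements(pos_a, neg_a)
    vb_pos, vb_neg, auc_b = _placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s_pos = np.cov(np.vstack([va_pos, vb_pos]), ddof=1) if m > 1 else np.zeros((2, 2))
    s_neg = np.cov(np.vstack([va_neg, vb_neg]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov_matrix = s_pos / m + s_neg / n
    var_a, var_b = float(cov_matrix[0, 0]), float(cov_matrix[1, 1])
    cov_ab = float(cov_matrix[0, 1])
    var_diff = var_a + var_b - 2 * cov_ab
    if var_diff <= 1e-15:
        statistic, p = 0.0, 1.0
    else:
        statistic = (auc_a - auc_b) ** 2 / var_diff
        p = float(stats.chi2.sf(statistic, df=1))
    return AUCComparison(auc_a=auc_a, auc_b=auc_b, variance_a=var_a,
                         variance_b=var_b, covariance=cov_ab,
                         statistic=float(statistic), p_value=p)


def best_cutoff(roc: ROCCurve) -> tuple[float, float, float]:
    """Youden-optimal threshold: maximize sensitivity + specificity.

    Ties go to the higher sensitivity, then to the lower threshold.
    """
    j = roc.sensitivities + roc.specificities
    best = 0
    for i in range(1, len(roc.thresholds)):
        if (j[i], roc.sensitivities[i], -roc.thresholds[i]) > \
           (j[best], roc.sensitivities[best], -roc.thresholds[best]):
            best = i
    return (float(roc.thresholds[best]), float(roc.sensitivities[best]),
            float(roc.specificities[best]))
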
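"""Per-feature univariate logistic regression and cross-validated AUC.

Each candidate predictor of new digital ulcers is assessed on its own, the
way the score was derived: a univariate logistic fit of the outcome on the
predictor, the apparent AUC, and a k-fold (k=10) cross-validated AUC. With
only ~2 events per fold at the derivation-cohort size, per-fold AUCs are
degenerate, so the cvAUC is computed once on the pooled out-of-fold
predictions. Folds are stratified by outcome.

The logistic fit is a plain two-parameter Newton (IRLS) maximum-likelihood
fit. Quasi-complete separation (e.g. the history-of-ulcers feature, which
was present in every event) sends the slope to infinity; the fit flags
separation once |slope| exceeds SLOPE_CAP and clamps it there. The odds
ratio reported for such features comes from the continuity-corrected
contingency table, not from the diverged logistic slope.

Missing predictor values are handled complete-case per feature, matching
the varying per-feature denominators of the derivation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import score as score_mod
from .contingency import OREstimate, from_predictions, odds_ratio, sens_spec
from .published import NC_PATTERN_LEVELS
from .roc import auc_mann_whitney

__all__ = [
    "SLOPE_CAP",
    "LogisticFit",
    "FeatureAssessment",
    "fit_logistic",
    "predict_prob",
    "cv_auc",
    "assess_feature",
]

#: |slope| beyond which the fit is declared separated and clamped.
SLOPE_CAP = 15.0


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    converged: bool
    separation_detected: bool
    n_used: int


@dataclass(frozen=True)
class FeatureAssessment:
    """One row of the derivation table: diagnostics for a single feature."""

    feature: str
    or_estimate: OREstimate
    sensitivity: float
    specificity: float
    auc: float
    cv_auc: float
    weight: int | None     # None = excluded from the score by the cvAUC rule


def _complete_case(predictor, outcomes) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predictor and outcomes must be the same length")
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    if np.isnan(y).any() or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary with no missing values")
    return x, y.astype(int)


def fit_logistic(predictor, outcomes, max_iter: int = 100,
                 tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood univariate logistic fit by Newton/IRLS."""
    x, y = _complete_case(predictor, outcomes)
    if len(np.unique(x)) < 2:
        raise ValueError("predictor is constant; logistic slope is unidentifiable")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; model is unfittable")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        w = p * (1 - p)
        hessian = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(hessian, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if abs(beta[1]) > SLOPE_CAP:
            separated = True
            break
    if separated or abs(beta[1]) > SLOPE_CAP:
        separated = True
        converged = False
        beta[1] = math.copysign(SLOPE_CAP, beta[1]) if beta[1] != 0 else SLOPE_CAP
    return LogisticFit(intercept=float(beta[0]), slope=float(beta[1]),
                       converged=converged, separation_detected=separated,
                       n_used=len(x))


def predict_prob(fit: LogisticFit, predictor) -> np.ndarray:
    """Inverse-logit of the fitted linear predictor."""
    x = np.asarray(predictor, dtype=float)
    eta = np.clip(fit.intercept + fit.slope * x, -700, 700)
    return 1.0 / (1.0 + np.exp(-eta))


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold label per patient: each class shuffled then dealt round-robin."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cv_auc(predictor, outcomes, k: int = 10, seed: int = 0,
           stratified: bool = True) -> float:
    """AUC on pooled out-of-fold predictions from k-fold cross-validation."""
    x, y = _complete_case(predictor, outcomes)
    if len(x) < k:
        raise ValueError(f"need at least k={k} patients, got {len(x)}")
    if stratified:
        folds = _stratified_folds(y, k, seed)
    else:
        rng = np.random.default_rng(seed)
        folds = rng.permutation(len(y)) % k
    oof = np.empty(len(y))
    for fold in range(k):
        train = folds != fold
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"training fold {fold} contains a single outcome class; "
                "use stratified folds or fewer folds")
        fit = fit_logistic(x[train], y[train])
        oof[folds == fold] = predict_prob(fit, x[folds == fold])
    return auc_mann_whitney(oof, y)


def _numeric_predictor(frame, feature: str) -> np.ndarray:
    """Feature column as numbers: binary 0/1, NC pattern as grade 0-3."""
    col = frame[feature]
    if feature == "nc_pattern" or col.dtype == object:
        mapping = {level: i for i, level in enumerate(NC_PATTERN_LEVELS)}
        return np.array([np.nan if (v is None or (isinstance(v, float) and np.isnan(v)))
                         else float(mapping[str(v)]) for v in col])
    return col.to_numpy(dtype=float)


def assess_feature(frame, feature: str, weight_rule=None, k: int = 10,
                   seed: int = 0) -> FeatureAssessment:
    """Full diagnostic work-up of one feature against the ulcer outcome.

    Contingency statistics dichotomize the NC pattern as any scleroderma
    pattern vs normal; AUC and cvAUC use the ordinal grade. The weight comes
    from ``weight_rule`` (default: the published cvAUC banding rule) applied
    to the cvAUC; features with cvAUC <= 0.6 are excluded (weight None).
    """
    if feature not in frame.columns:
        raise KeyError(f"feature {feature!r} not in cohort")
    if weight_rule is None:
        weight_rule = score_mod.weight_from_cvauc
    y_all = frame["outcome"].to_numpy(dtype=int)
    x = _numeric_predictor(frame, feature)
    binary = (x > 0).astype(float)
    binary[np.isnan(x)] = np.nan
    keep = ~np.isnan(x)
    table = from_predictions(y_all[keep], binary[keep])
    or_est = odds_ratio(table, correction="haldane_if_zero")
    se, sp = sens_spec(table)
    auc = auc_mann_whitney(x[keep], y_all[keep])
    cvauc = cv_auc(x, y_all, k=k, seed=seed)
    return FeatureAssessment(feature=feature, or_estimate=or_est,
                             sensitivity=se, specificity=sp, auc=auc,
                             cv_auc=cvauc, weight=weight_rule(cvauc))
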
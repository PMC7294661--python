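"""Calibration and added-value statistics for comparing score variants.

The published analysis asks whether the imaging components (fluorescence
optical imaging and Doppler ultrasound) earn their place in the score. The
tools for that question live here:

* Hosmer-Lemeshow chi-square calibration test on risk-quantile groups,
  chi2 = sum over groups of (O - E)^2 / (E * (1 - E/n_g)), df = groups - 2
  by default (configurable; the publication does not state its df).
* Continuous ("any movement") net reclassification improvement: a patient
  counts as reclassified up/down when the new model's predicted probability
  is strictly higher/lower. This is the flavor under which the published
  counts (14 up / 4 down of 22 events; 18 down / 9 up of 54 non-events)
  give exactly NRI = 62.1 on the x100 scale. The p-value is the standard
  asymptotic two-proportion z-test.
* Integrated discrimination improvement: the change in discrimination slope
  (mean predicted probability in events minus non-events), x100, with an
  unpaired-groups z-test on the per-patient probability changes.
* ``compare_models``: full vs imaging-free score on one cohort — each score
  is mapped to a predicted probability through its own univariate logistic
  fit (or an empirical score->event-rate lookup behind a flag), then both
  AUCs, the DeLong test, NRI, IDI and both calibration results are bundled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .published import SCORE_CUTOFF
from .roc import AUCComparison, delong_compare
from .score import WeightScheme, score_cohort
from .univariate import fit_logistic, predict_prob

__all__ = [
    "CalibrationResult",
    "ReclassificationResult",
    "ModelComparison",
    "hosmer_lemeshow",
    "reclassification",
    "nri",
    "idi",
    "compare_models",
]


@dataclass(frozen=True)
class CalibrationResult:
    chi_square: float
    degrees_freedom: int
    p_value: float
    group_table: pd.DataFrame   # per group: n, observed events, expected events


@dataclass(frozen=True)
class ReclassificationResult:
    n_events: int
    n_nonevents: int
    events_up: int
    events_down: int
    nonevents_up: int
    nonevents_down: int
    nri: float        # x100 scale
    nri_p: float
    idi: float        # x100 scale
    idi_p: float


@dataclass(frozen=True)
class ModelComparison:
    auc_full: float
    auc_reduced: float
    delong: AUCComparison
    reclassification: ReclassificationResult
    calibration_full: CalibrationResult
    calibration_reduced: CalibrationResult


def _check_probs(name: str, p: np.ndarray) -> None:
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError(f"{name} must be probabilities in [0, 1]")


def hosmer_lemeshow(probabilities, outcomes, n_groups: int = 10,
                    degrees_freedom: int | None = None) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over probability-quantile groups.

    Ties are kept together by binning on probability values; when fewer than
    3 distinct probability values exist (e.g. all patients share the overall
    event rate) the fall-back is equal-size positional groups, so the
    statistic then reflects pure binomial group fluctuation.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes must be the same length")
    _check_probs("probabilities", p)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(p, kind="stable")
    if len(np.unique(p)) >= 3:
        groups = pd.qcut(p, q=min(n_groups, len(np.unique(p))),
                         duplicates="drop", labels=False)
    else:
        groups = np.empty(len(p), dtype=int)
        groups[order] = (np.arange(len(p)) * n_groups) // len(p)
    chi2 = 0.0
    rows = []
    for g in np.unique(groups):
        mask = groups == g
        n_g = int(mask.sum())
        obs = int(y[mask].sum())
        exp = float(p[mask].sum())
        denom = exp * (1.0 - exp / n_g)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
        rows.append({"group": int(g), "n": n_g, "observed": obs, "expected": exp})
    table = pd.DataFrame(rows)
    df = degrees_freedom if degrees_freedom is not None else max(len(rows) - 2, 1)
    p_value = float(stats.chi2.sf(chi2, df=df))
    return CalibrationResult(chi_square=float(chi2), degrees_freedom=int(df),
                             p_value=p_value, group_table=table)


def reclassification(probs_old, probs_new, outcomes) -> ReclassificationResult:
    """Continuous NRI and IDI for a new model against an old one (x100)."""
    p_old = np.asarray(probs_old, dtype=float)
    p_new = np.asarray(probs_new, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if not (p_old.shape == p_new.shape == y.shape):
        raise ValueError("inputs must be aligned, same length")
    _check_probs("probs_old", p_old)
    _check_probs("probs_new", p_new)
    ev, ne = y == 1, y == 0
    n_events, n_nonevents = int(ev.sum()), int(ne.sum())
    if n_events == 0 or n_nonevents == 0:
        raise ValueError("both outcome classes must be present")
    delta = p_new - p_old
    events_up = int((delta[ev] > 0).sum())
    events_down = int((delta[ev] < 0).sum())
    nonevents_up = int((delta[ne] > 0).sum())
    nonevents_down = int((delta[ne] < 0).sum())

    nri_raw = (events_up - events_down) / n_events \
        + (nonevents_down - nonevents_up) / n_nonevents
    se_nri = math.sqrt((events_up + events_down) / n_events ** 2
                       + (nonevents_up + nonevents_down) / n_nonevents ** 2)
    nri_p = 1.0 if se_nri == 0 else float(2 * stats.norm.sf(abs(nri_raw) / se_nri))

    idi_raw = float(delta[ev].mean() - delta[ne].mean())
    var_e = float(np.var(delta[ev], ddof=1)) if n_events > 1 else 0.0
    var_n = float(np.var(delta[ne], ddof=1)) if n_nonevents > 1 else 0.0
    se_idi = math.sqrt(var_e / n_events + var_n / n_nonevents)
    idi_p = 1.0 if se_idi == 0 else float(2 * stats.norm.sf(abs(idi_raw) / se_idi))

    return ReclassificationResult(
        n_events=n_events, n_nonevents=n_nonevents,
        events_up=events_up, events_down=events_down,
        nonevents_up=nonevents_up, nonevents_down=nonevents_down,
        nri=100.0 * nri_raw, nri_p=nri_p, idi=100.0 * idi_raw, idi_p=idi_p)


# The two published added-value statistics share all their bookkeeping, so
# both entry points return the complete ReclassificationResult.
nri = reclassification
idi = reclassification


def _score_probs(records: list[PatientRecord], scheme: WeightScheme,
                 mapping: str) -> tuple[np.ndarray, np.ndarray]:
    frame = score_cohort(records, scheme)
    scores = frame["score"].to_numpy(dtype=float)
    y = frame["outcome"].to_numpy(dtype=int)
    if mapping == "logistic":
        fit = fit_logistic(scores, y)
        return predict_prob(fit, scores), y
    if mapping == "empirical":
        rates = pd.Series(y).groupby(scores).mean()
        return np.array([rates[s] for s in scores]), y
    raise ValueError(f"unknown probability mapping {mapping!r}")


def compare_models(records: list[PatientRecord], scheme_full: WeightScheme,
                   scheme_reduced: WeightScheme, cutoff: int = SCORE_CUTOFF,
                   n_groups: int = 10,
                   prob_mapping: str = "logistic") -> ModelComparison:
    """Head-to-head evaluation of two score variants on one cohort."""
    probs_full, y = _score_probs(records, scheme_full, prob_mapping)
    probs_reduced, _ = _score_probs(records, scheme_reduced, prob_mapping)
    comparison = delong_compare(probs_full, probs_reduced, y)
    reclass = reclassification(probs_reduced, probs_full, y)
    return ModelComparison(
        auc_full=comparison.auc_a, auc_reduced=comparison.auc_b,
        delong=comparison, reclassification=reclass,
        calibration_full=hosmer_lemeshow(probs_full, y, n_groups=n_groups),
        calibration_reduced=hosmer_lemeshow(probs_reduced, y, n_groups=n_groups))
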
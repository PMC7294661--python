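"""End-to-end study replication: assess -> weight -> score -> evaluate.

``run_full_analysis`` turns a cohort (records or CSV path) into a
machine-readable report with one diagnostic row per feature, score-level
performance for the full and imaging-free instruments (AUC, cross-validated
AUC, Youden-optimal cut-off, calibration), their head-to-head comparison
(DeLong, NRI, IDI) and provenance (seed, config hash, package version).
It is deterministic given the seed.

``verify_published_values`` needs no input data at all: it rebuilds every
reconstructable 2x2 table from the printed sensitivity/specificity summaries
and recomputes the published odds ratios, subgroup ulcer rates, NRI and
score maxima, emitting a computed-vs-printed comparison table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import PatientRecord, cohort_to_frame
from .contingency import odds_ratio, reconstruct_table
from .evaluate import ModelComparison, compare_models
from .published import (
    DIFFUSE_DU_COUNTS,
    LIMITED_DU_COUNTS,
    N_EVENTS,
    N_NONEVENTS,
    NC_PATTERN_WEIGHTS,
    PUBLISHED_FEATURES,
    RECLASSIFICATION_COUNTS,
    SCORE_CUTOFF,
)
from .roc import auc_mann_whitney, best_cutoff, roc_curve
from .score import canonical_weights, score_cohort
from .univariate import FeatureAssessment, assess_feature, cv_auc
from .io import read_cohort

__all__ = ["StudyReport", "run_full_analysis", "verify_published_values",
           "assessment_frame"]

_FEATURES = [row.name for row in PUBLISHED_FEATURES] + ["nc_pattern"]


@dataclass(frozen=True)
class ScoreSummary:
    auc: float
    cv_auc: float
    best_cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    calibration_chi_square: float
    calibration_df: int
    calibration_p: float


@dataclass(frozen=True)
class StudyReport:
    assessments: list[FeatureAssessment]
    full_score: ScoreSummary
    reduced_score: ScoreSummary
    comparison: ModelComparison
    seed: int
    cutoff: int
    config_hash: str
    version: str

    def to_json(self) -> str:
        def fa_dict(fa: FeatureAssessment) -> dict:
            d = {"feature": fa.feature, "sensitivity": fa.sensitivity,
                 "specificity": fa.specificity, "auc": fa.auc,
                 "cv_auc": fa.cv_auc, "weight": fa.weight}
            d.update({f"or_{k}": v for k, v in asdict(fa.or_estimate).items()})
            return d

        data = {
            "features": [fa_dict(fa) for fa in self.assessments],
            "full_score": asdict(self.full_score),
            "reduced_score": asdict(self.reduced_score),
            "comparison": {
                "auc_full": self.comparison.auc_full,
                "auc_reduced": self.comparison.auc_reduced,
                "delong_statistic": self.comparison.delong.statistic,
                "delong_p": self.comparison.delong.p_value,
                "nri": self.comparison.reclassification.nri,
                "nri_p": self.comparison.reclassification.nri_p,
                "nri_components": {
                    k: getattr(self.comparison.reclassification, k)
                    for k in ("events_up", "events_down", "nonevents_up",
                              "nonevents_down", "n_events", "n_nonevents")},
                "idi": self.comparison.reclassification.idi,
                "idi_p": self.comparison.reclassification.idi_p,
            },
            "provenance": {"seed": self.seed, "cutoff": self.cutoff,
                           "config_hash": self.config_hash,
                           "version": self.version},
        }
        return json.dumps(data, indent=2, sort_keys=True)


def assessment_frame(assessments: list[FeatureAssessment]) -> pd.DataFrame:
    """Tabular view of feature assessments (CSV-ready, derivation-table layout)."""
    return pd.DataFrame([
        {"feature": fa.feature, "or": fa.or_estimate.or_value,
         "ci_low": fa.or_estimate.ci_low, "ci_high": fa.or_estimate.ci_high,
         "p": fa.or_estimate.p_value, "sensitivity": fa.sensitivity,
         "specificity": fa.specificity, "auc": fa.auc, "cv_auc": fa.cv_auc,
         "weight": fa.weight}
        for fa in assessments])


def _score_summary(records: list[PatientRecord], scheme, seed: int,
                   comparison_cal) -> ScoreSummary:
    frame = score_cohort(records, scheme)
    scores = frame["score"].to_numpy(dtype=float)
    y = frame["outcome"].to_numpy(dtype=int)
    curve = roc_curve(scores, y)
    cut, se, sp = best_cutoff(curve)
    return ScoreSummary(
        auc=auc_mann_whitney(scores, y),
        cv_auc=cv_auc(scores, y, k=10, seed=seed),
        best_cutoff=cut, cutoff_sensitivity=se, cutoff_specificity=sp,
        calibration_chi_square=comparison_cal.chi_square,
        calibration_df=comparison_cal.degrees_freedom,
        calibration_p=comparison_cal.p_value)


def run_full_analysis(cohort, seed: int = 0, cutoff: int = SCORE_CUTOFF,
                      k: int = 10) -> StudyReport:
    """Run the whole pipeline on a cohort (list of records or CSV path)."""
    if isinstance(cohort, (str, Path)):
        records = read_cohort(cohort)
    else:
        records = list(cohort)
    frame = cohort_to_frame(records)
    features = [f for f in _FEATURES if f in frame.columns]
    assessments = [assess_feature(frame, f, k=k, seed=seed) for f in features]
    full = canonical_weights(includes_imaging=True)
    reduced = canonical_weights(includes_imaging=False)
    comparison = compare_models(records, full, reduced, cutoff=cutoff)
    digest = hashlib.sha256()
    digest.update(frame.to_csv(index=False).encode())
    digest.update(f"seed={seed},cutoff={cutoff},k={k}".encode())
    return StudyReport(
        assessments=assessments,
        full_score=_score_summary(records, full, seed, comparison.calibration_full),
        reduced_score=_score_summary(records, reduced, seed,
                                     comparison.calibration_reduced),
        comparison=comparison, seed=seed, cutoff=cutoff,
        config_hash=digest.hexdigest(), version=__version__)


def verify_published_values() -> pd.DataFrame:
    """Recompute the published summary numbers from printed constants only.

    Returns a frame with columns quantity, computed, printed, match
    (match = computed agrees with the printed value at its printed rounding).
    """
    rows = []

    def add(quantity: str, computed: float, printed: float, decimals: int) -> None:
        rows.append({"quantity": quantity, "computed": computed,
                     "printed": printed,
                     "match": round(computed, decimals) == printed})

    for feat in PUBLISHED_FEATURES:
        table = reconstruct_table(feat.sensitivity, feat.specificity,
                                  feat.n_events, feat.n_nonevents)
        est = odds_ratio(table, correction="haldane_if_zero")
        add(f"or_{feat.name}", est.or_value, feat.or_printed, 1)
        if est.corrected:
            # separation row: published CI lower bound is also reconstructable
            add(f"ci_low_{feat.name}", est.ci_low, feat.ci_printed[0], 1)

    add("du_rate_overall_pct", 100 * N_EVENTS / (N_EVENTS + N_NONEVENTS), 29.0, 0)
    add("du_rate_diffuse_pct", 100 * DIFFUSE_DU_COUNTS[0] / DIFFUSE_DU_COUNTS[1],
        48.1, 1)
    add("du_rate_limited_pct", 100 * LIMITED_DU_COUNTS[0] / LIMITED_DU_COUNTS[1],
        18.4, 1)

    c = RECLASSIFICATION_COUNTS
    nri_value = 100 * ((c["events_up"] - c["events_down"]) / c["n_events"]
                       + (c["nonevents_down"] - c["nonevents_up"]) / c["n_nonevents"])
    add("nri_from_printed_counts", nri_value, 62.1, 1)

    add("max_score_full", canonical_weights(True).max_score, 16, 0)
    add("max_score_reduced", canonical_weights(False).max_score, 14, 0)
    add("nc_pattern_late_points", NC_PATTERN_WEIGHTS["late"], 3, 0)

    return pd.DataFrame(rows)
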
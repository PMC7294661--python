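"""The additive digital-ulcer risk score (CIP-DUS) and its weighting rule.

The score sums integer points over the selected predictors: each positive
binary feature contributes its weight, and the nailfold-capillaroscopy
pattern contributes 0/1/2/3 points for normal/early/active/late. Weights
were assigned from the cross-validated AUC by banding: excluded at
cvAUC <= 0.6, then 1 / 2 / 3 points for cvAUC in (0.6, 0.65] / (0.65, 0.7] /
(0.7, 1].

Two weight schemes are canonical. The published instrument
(``canonical_weights``) uses the exact printed weights — which depart from
the banding rule in two places: the skin score received 2 points despite
cvAUC 0.73 (rule says 3), and pulmonary arterial hypertension was kept with
1 point despite cvAUC 0.54 (rule says exclude). The rule-based path
(``weight_from_cvauc``) exists separately for building new scores. The
imaging-free variant drops the FOI and Doppler-ultrasound components
(maximum 14 points instead of 16).

Missing components contribute 0 points but are counted, since the
publication is silent on scoring incomplete patients. Patients at or above
the cut-off (>= 10 points by default) are classified at risk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import MISSING, PatientRecord
from .published import NC_PATTERN_WEIGHTS, SCORE_CUTOFF

__all__ = [
    "EXCLUDED",
    "WeightScheme",
    "ScoreResult",
    "weight_from_cvauc",
    "canonical_weights",
    "compute_score",
    "classify",
    "score_cohort",
]

#: Sentinel returned by the weighting rule for features that do not qualify.
EXCLUDED = None

_IMAGING_FEATURES = ("foi_missing_enhancement", "cdus_pathologic_gt35")


@dataclass(frozen=True)
class WeightScheme:
    """Feature -> points map defining one additive score variant."""

    weights: dict[str, int]
    nc_pattern_weights: dict[str, int] = field(
        default_factory=lambda: dict(NC_PATTERN_WEIGHTS))
    includes_imaging: bool = True

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()) or \
           any(w < 0 for w in self.nc_pattern_weights.values()):
            raise ValueError("weights must be non-negative")

    @property
    def max_score(self) -> int:
        return sum(self.weights.values()) + max(self.nc_pattern_weights.values())

    def to_json(self) -> str:
        return json.dumps({"weights": self.weights,
                           "nc_pattern_weights": self.nc_pattern_weights,
                           "includes_imaging": self.includes_imaging},
                          indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WeightScheme":
        data = json.loads(text)
        return cls(weights={k: int(v) for k, v in data["weights"].items()},
                   nc_pattern_weights={k: int(v) for k, v in
                                       data["nc_pattern_weights"].items()},
                   includes_imaging=bool(data["includes_imaging"]))


@dataclass(frozen=True)
class ScoreResult:
    patient_id: str
    score: int
    components: dict[str, int]
    n_missing_components: int
    predicted_positive: bool


def weight_from_cvauc(cvauc: float):
    """Banding rule mapping a cross-validated AUC to an integer weight.

    Returns ``EXCLUDED`` (None) for cvAUC <= 0.6, else 1, 2 or 3.
    """
    if not 0.0 <= cvauc <= 1.0:
        raise ValueError(f"cvAUC must be in [0, 1], got {cvauc!r}")
    if cvauc <= 0.60:
        return EXCLUDED
    if cvauc <= 0.65:
        return 1
    if cvauc <= 0.70:
        return 2
    return 3


def canonical_weights(includes_imaging: bool = True) -> WeightScheme:
    """The published instrument's exact weights (full or imaging-free)."""
    weights = {
        "diffuse_subtype": 1,
        "mrss_gt8": 2,
        "pah": 1,
        "present_du_ps": 3,
        "history_du_ps": 3,
        "nc_density_reduced": 1,
        "foi_missing_enhancement": 1,
        "cdus_pathologic_gt35": 1,
    }
    if not includes_imaging:
        for name in _IMAGING_FEATURES:
            del weights[name]
    return WeightScheme(weights=weights, includes_imaging=includes_imaging)


def compute_score(patient: PatientRecord, scheme: WeightScheme,
                  cutoff: int = SCORE_CUTOFF) -> ScoreResult:
    """Sum the patient's points under a scheme; missing features score 0."""
    unknown = set(patient.values) - set(scheme.weights) - {"nc_pattern"} \
        - set(_IMAGING_FEATURES)
    if unknown:
        raise KeyError(f"unknown features in record: {sorted(unknown)}")
    components: dict[str, int] = {}
    n_missing = 0
    for name, weight in scheme.weights.items():
        value = patient.values.get(name, MISSING)
        if value is MISSING or (isinstance(value, float) and np.isnan(value)):
            components[name] = 0
            n_missing += 1
        else:
            components[name] = weight * int(value)
    pattern = patient.values.get("nc_pattern", MISSING)
    if pattern is MISSING or (isinstance(pattern, float) and np.isnan(pattern)):
        components["nc_pattern"] = 0
        n_missing += 1
    else:
        if str(pattern) not in scheme.nc_pattern_weights:
            raise ValueError(f"unknown nc_pattern level {pattern!r}")
        components["nc_pattern"] = scheme.nc_pattern_weights[str(pattern)]
    total = sum(components.values())
    return ScoreResult(patient_id=patient.patient_id, score=total,
                       components=components, n_missing_components=n_missing,
                       predicted_positive=classify(total, cutoff))


def classify(score: int, cutoff: int = SCORE_CUTOFF) -> bool:
    """At-risk classification: positive iff score >= cutoff."""
    return score >= cutoff


def score_cohort(records: list[PatientRecord], scheme: WeightScheme,
                 cutoff: int = SCORE_CUTOFF) -> "pandas.DataFrame":  # noqa: F821
    """Score every patient; returns one row per patient with components."""
    import pandas as pd

    rows = []
    for rec in records:
        res = compute_score(rec, scheme, cutoff)
        row = {"patient_id": res.patient_id, "outcome": rec.outcome,
               "score": res.score, "predicted_positive": res.predicted_positive,
               "n_missing_components": res.n_missing_components}
        row.update({f"pts_{k}": v for k, v in res.components.items()})
        rows.append(row)
    return pd.DataFrame(rows)
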
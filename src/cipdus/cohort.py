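"""Synthetic patient cohorts with outcome-conditional feature prevalences.

No patient-level data accompany the published score, so every downstream
stage (contingency statistics, logistic fits, score evaluation) is exercised
on synthetic cohorts. A cohort is generated *stratified by outcome*: exactly
``n_events`` patients with a new digital ulcer at follow-up and
``n_nonevents`` without, mirroring the realized 22/54 split of the
derivation cohort rather than sampling prevalence. Each binary feature is an
independent Bernoulli draw whose success probability equals the feature's
sensitivity (events) or one minus its specificity (non-events), so the
population 2x2 tables reproduce the published diagnostic summaries. The
capillaroscopy pattern is an ordinal draw over the four Cutolo grades.

Per-feature missingness is Bernoulli as well, applied only to the two
features whose published denominators fall short of the cohort size
(capillary density, FOI). The outcome itself is never missing.

Reproducibility: a single integer seed drives everything; each feature gets
its own deterministic substream keyed on (seed, crc32(feature name)), so
adding or removing one feature never perturbs the values drawn for another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .published import (
    N_EVENTS,
    N_NONEVENTS,
    NC_PATTERN_LEVELS,
    NC_PATTERN_SPECIFICITY,
    PUBLISHED_FEATURES,
)

__all__ = [
    "MISSING",
    "FeatureSpec",
    "CohortConfig",
    "PatientRecord",
    "published_cohort_config",
    "generate_cohort",
    "scale_config",
    "cohort_to_frame",
    "frame_to_records",
]

#: Marker for a missing feature value in a :class:`PatientRecord`.
MISSING = None

_ORDINAL = "ordinal_nc_pattern"


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class FeatureSpec:
    """Generative description of one predictor.

    For a binary feature, ``p_given_event`` is the feature's sensitivity and
    ``p_given_nonevent`` is one minus its specificity. For the ordinal
    capillaroscopy pattern the two ``ordinal_distribution_*`` vectors give
    the probability of each grade in ``NC_PATTERN_LEVELS`` order.
    """

    name: str
    kind: Literal["binary", "ordinal_nc_pattern"] = "binary"
    p_given_event: float = 0.0
    p_given_nonevent: float = 0.0
    missing_rate_events: float = 0.0
    missing_rate_nonevents: float = 0.0
    ordinal_distribution_event: tuple[float, ...] | None = None
    ordinal_distribution_nonevent: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", _ORDINAL):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        for attr in ("p_given_event", "p_given_nonevent",
                     "missing_rate_events", "missing_rate_nonevents"):
            _check_prob(f"{self.name}.{attr}", getattr(self, attr))
        if self.kind == _ORDINAL:
            for attr in ("ordinal_distribution_event", "ordinal_distribution_nonevent"):
                dist = getattr(self, attr)
                if dist is None or len(dist) != len(NC_PATTERN_LEVELS):
                    raise ValueError(f"{self.name}.{attr} must have "
                                     f"{len(NC_PATTERN_LEVELS)} entries")
                if any(p < 0 for p in dist) or abs(sum(dist) - 1.0) > 1e-12:
                    raise ValueError(f"{self.name}.{attr} must be a probability "
                                     f"vector summing to 1")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, feature specs and master seed for one synthetic cohort."""

    n_events: int
    n_nonevents: int
    features: dict[str, FeatureSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1 or self.n_nonevents < 1:
            raise ValueError("n_events and n_nonevents must be >= 1")
        for name, spec in self.features.items():
            if name != spec.name:
                raise ValueError(f"feature key {name!r} != spec name {spec.name!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifier, follow-up outcome and feature values.

    ``values`` maps feature name to 0/1 (binary), a capillaroscopy grade
    string, or :data:`MISSING`.
    """

    patient_id: str
    outcome: int
    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome!r}")


def published_cohort_config(seed: int = 0) -> CohortConfig:
    """Config reproducing the statistical structure of the derivation cohort.

    22 events / 54 non-events; one binary feature per published score
    component with p(feature|event) equal to the printed sensitivity and
    p(feature|non-event) equal to one minus the printed specificity;
    missingness on capillary density (3/22 events, 9/54 non-events) and FOI
    (6/22 events, 10/54 non-events) so the expected group denominators match
    the published 19/45 and 16/44. The capillaroscopy pattern puts zero
    event mass on "normal" (the any-scleroderma-pattern finding had 100%
    sensitivity) and splits the remaining mass uniformly across
    early/active/late — a synthetic-only choice, the publication does not
    give the split.
    """
    features: dict[str, FeatureSpec] = {}
    for row in PUBLISHED_FEATURES:
        features[row.name] = FeatureSpec(
            name=row.name,
            kind="binary",
            p_given_event=row.sensitivity,
            p_given_nonevent=round(1.0 - row.specificity, 12),
            missing_rate_events=(N_EVENTS - row.n_events) / N_EVENTS,
            missing_rate_nonevents=(N_NONEVENTS - row.n_nonevents) / N_NONEVENTS,
        )
    nonevent_normal = NC_PATTERN_SPECIFICITY
    rest = (1.0 - nonevent_normal) / 3.0
    features["nc_pattern"] = FeatureSpec(
        name="nc_pattern",
        kind=_ORDINAL,
        ordinal_distribution_event=(0.0, 1 / 3, 1 / 3, 1 / 3),
        ordinal_distribution_nonevent=(nonevent_normal, rest, rest, rest),
    )
    return CohortConfig(n_events=N_EVENTS, n_nonevents=N_NONEVENTS,
                        features=features, seed=seed)


def scale_config(config: CohortConfig, factor: int) -> CohortConfig:
    """Multiply both outcome-group sizes by an integer factor (>= 1)."""
    if not isinstance(factor, (int, np.integer)) or isinstance(factor, bool):
        raise TypeError(f"factor must be an integer, got {type(factor).__name__}")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return replace(config, n_events=config.n_events * int(factor),
                   n_nonevents=config.n_nonevents * int(factor))


def _feature_rng(seed: int, name: str) -> np.random.Generator:
    # keyed on the feature name, not its position, so streams are stable
    # under adding/removing other features
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0xFFFFFFFF, zlib.crc32(name.encode())])
    )


def _draw_feature(spec: FeatureSpec, n_events: int, n_nonevents: int,
                  seed: int) -> list[object]:
    rng = _feature_rng(seed, spec.name)
    if spec.kind == "binary":
        ev = (rng.random(n_events) < spec.p_given_event).astype(int)
        ne = (rng.random(n_nonevents) < spec.p_given_nonevent).astype(int)
        values: list[object] = list(ev) + list(ne)
    else:
        levels = np.array(NC_PATTERN_LEVELS)
        ev = rng.choice(levels, size=n_events, p=spec.ordinal_distribution_event)
        ne = rng.choice(levels, size=n_nonevents, p=spec.ordinal_distribution_nonevent)
        values = list(ev) + list(ne)
    miss_ev = rng.random(n_events) < spec.missing_rate_events
    miss_ne = rng.random(n_nonevents) < spec.missing_rate_nonevents
    missing = np.concatenate([miss_ev, miss_ne])
    return [MISSING if m else (int(v) if isinstance(v, (int, np.integer)) else str(v))
            for v, m in zip(values, missing)]


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw one cohort: exactly ``n_events`` events followed by the non-events.

    Fully reproducible from ``config.seed``; see the module docstring for the
    per-feature substream scheme.
    """
    n = config.n_events + config.n_nonevents
    outcomes = [1] * config.n_events + [0] * config.n_nonevents
    columns = {name: _draw_feature(spec, config.n_events, config.n_nonevents,
                                   config.seed)
               for name, spec in config.features.items()}
    width = max(4, len(str(n)))
    return [
        PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            outcome=outcomes[i],
            values={name: columns[name][i] for name in config.features},
        )
        for i in range(n)
    ]


def cohort_to_frame(records: list[PatientRecord]) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate records as a DataFrame (missing values become NaN/None)."""
    import pandas as pd

    rows = []
    for rec in records:
        row: dict[str, object] = {"patient_id": rec.patient_id, "outcome": rec.outcome}
        for name, value in rec.values.items():
            row[name] = np.nan if value is MISSING else value
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame


def frame_to_records(frame) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    feature_cols = [c for c in frame.columns if c not in ("patient_id", "outcome")]
    records = []
    for _, row in frame.iterrows():
        values: dict[str, object] = {}
        for col in feature_cols:
            v = row[col]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                values[col] = MISSING
            elif isinstance(v, str):
                values[col] = v
            else:
                values[col] = int(v)
        records.append(PatientRecord(patient_id=str(row["patient_id"]),
                                     outcome=int(row["outcome"]), values=values))
    return records
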
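"""Cohort and config file I/O.

Cohort CSV dialect: UTF-8, comma-separated, header row with columns
patient_id, outcome, then one column per feature. Binary cells are "0"/"1",
the capillaroscopy pattern is one of normal/early/active/late (case-folded
on read), and missing values are empty cells. The round trip
write -> read is lossless, including missingness.

Validation is strict and reports the offending row/column; nothing is
silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import (
    MISSING,
    CohortConfig,
    FeatureSpec,
    PatientRecord,
)
from .published import NC_PATTERN_LEVELS

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_config",
    "write_config",
    "CohortValidationError",
]

#: Canonical column order for the published feature set.
COHORT_COLUMNS = (
    "patient_id", "outcome", "diffuse_subtype", "mrss_gt8", "pah",
    "present_du_ps", "history_du_ps", "nc_pattern", "nc_density_reduced",
    "foi_missing_enhancement", "cdus_pathologic_gt35",
)


class CohortValidationError(ValueError):
    """A cohort file violated the schema; message carries row/column."""


def write_cohort(records: list[PatientRecord], path) -> None:
    if not records:
        raise ValueError("refusing to write an empty cohort")
    feature_names = list(records[0].values.keys())
    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id, "outcome": rec.outcome}
        for name in feature_names:
            v = rec.values.get(name, MISSING)
            row[name] = "" if v is MISSING else str(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> list[PatientRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    required = {"patient_id", "outcome"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise CohortValidationError(f"missing required columns: {sorted(missing_cols)}")
    if frame["patient_id"].duplicated().any():
        dupes = frame.loc[frame["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortValidationError(f"duplicate patient_id values: {dupes}")
    feature_cols = [c for c in frame.columns if c not in required]
    records = []
    for i, row in frame.iterrows():
        line = i + 2   # header is line 1
        if row["outcome"] not in ("0", "1"):
            raise CohortValidationError(
                f"line {line}, column outcome: expected 0 or 1, "
                f"got {row['outcome']!r}")
        values: dict[str, object] = {}
        for col in feature_cols:
            cell = row[col].strip()
            if cell == "":
                values[col] = MISSING
            elif col == "nc_pattern":
                level = cell.lower()
                if level not in NC_PATTERN_LEVELS:
                    raise CohortValidationError(
                        f"line {line}, column nc_pattern: unknown level {cell!r}")
                values[col] = level
            elif cell in ("0", "1"):
                values[col] = int(cell)
            else:
                raise CohortValidationError(
                    f"line {line}, column {col}: expected 0, 1 or empty, "
                    f"got {cell!r}")
        records.append(PatientRecord(patient_id=row["patient_id"],
                                     outcome=int(row["outcome"]), values=values))
    if not records:
        raise CohortValidationError("cohort file contains no patients")
    return records


def write_config(config: CohortConfig, path) -> None:
    data = {
        "n_events": config.n_events,
        "n_nonevents": config.n_nonevents,
        "seed": config.seed,
        "features": {
            name: {
                "name": spec.name,
                "kind": spec.kind,
                "p_given_event": spec.p_given_event,
                "p_given_nonevent": spec.p_given_nonevent,
                "missing_rate_events": spec.missing_rate_events,
                "missing_rate_nonevents": spec.missing_rate_nonevents,
                "ordinal_distribution_event": spec.ordinal_distribution_event,
                "ordinal_distribution_nonevent": spec.ordinal_distribution_nonevent,
            }
            for name, spec in config.features.items()
        },
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def read_config(path) -> CohortConfig:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    features = {}
    for name, spec in data["features"].items():
        for key in ("ordinal_distribution_event", "ordinal_distribution_nonevent"):
            if spec.get(key) is not None:
                spec[key] = tuple(spec[key])
        features[name] = FeatureSpec(**spec)
    return CohortConfig(n_events=int(data["n_events"]),
                        n_nonevents=int(data["n_nonevents"]),
                        features=features, seed=int(data.get("seed", 0)))
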
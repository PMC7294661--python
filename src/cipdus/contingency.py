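"""2x2 contingency tables linking a binary predictor to the ulcer outcome.

Odds ratios use the Haldane-Anscombe continuity correction (+0.5 to every
cell) when a zero cell would otherwise make the OR undefined — this is the
rule that reproduces the published history-of-ulcers row (OR 36.2, CI
2.1-626.9) from its sensitivity/specificity. Confidence intervals are Woolf
log-normal intervals; p-values are two-sided Fisher exact tests on the
uncorrected counts (sum of hypergeometric probabilities not exceeding the
observed table's).

``reconstruct_table`` inverts a printed (sensitivity, specificity, group
sizes) summary back into integer counts, rounding half away from zero —
the convention under which every published OR is recovered to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .cohort import MISSING

__all__ = [
    "ContingencyTable",
    "OREstimate",
    "from_predictions",
    "odds_ratio",
    "sens_spec",
    "reconstruct_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: tp = feature-positive events, fn = feature-negative events,
    fp = feature-positive non-events, tn = feature-negative non-events."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for cell in (self.tp, self.fn, self.fp, self.tn):
            if not isinstance(cell, (int, np.integer)) or cell < 0:
                raise ValueError(f"cells must be non-negative integers, got {cell!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fn, self.fp, self.tn)

    @property
    def n(self) -> int:
        return sum(self.cells)


@dataclass(frozen=True)
class OREstimate:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def from_predictions(outcomes: Iterable[int], predictor: Iterable[object]) -> ContingencyTable:
    """Cross-tabulate outcome against a binary predictor, complete-case.

    Pairs whose predictor is missing (``MISSING`` or NaN) are excluded;
    a predictor missing for every patient is unusable and raises.
    """
    tp = fn = fp = tn = 0
    n_used = 0
    for y, x in zip(outcomes, predictor, strict=True):
        if x is MISSING or (isinstance(x, float) and math.isnan(x)):
            continue
        n_used += 1
        x = int(x)
        if x not in (0, 1):
            raise ValueError(f"predictor values must be binary, got {x!r}")
        if y == 1:
            tp, fn = (tp + 1, fn) if x else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if x else (fp, tn + 1)
    if n_used == 0:
        raise ValueError("predictor is missing for every patient")
    return ContingencyTable(tp, fn, fp, tn)


Correction = Literal["none", "haldane_if_zero", "haldane_always"]


def odds_ratio(table: ContingencyTable,
               correction: Correction = "haldane_if_zero") -> OREstimate:
    """Odds ratio with Woolf 95% CI and two-sided Fisher exact p-value."""
    has_zero = 0 in table.cells
    if correction == "none" and has_zero:
        raise ZeroDivisionError(
            "odds ratio undefined for a table with a zero cell; "
            "use a Haldane-Anscombe correction")
    apply = correction == "haldane_always" or (
        correction == "haldane_if_zero" and has_zero)
    a, b, c, d = ((cell + 0.5 for cell in table.cells) if apply else table.cells)
    a, b, c, d = float(a), float(b), float(c), float(d)
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(or_value) - 1.96 * se)
    ci_high = math.exp(math.log(or_value) + 1.96 * se)
    # p-value always on the uncorrected counts
    _, p = stats.fisher_exact([[table.tp, table.fn], [table.fp, table.tn]],
                              alternative="two-sided")
    return OREstimate(or_value=or_value, ci_low=ci_low, ci_high=ci_high,
                      p_value=float(min(p, 1.0)), corrected=apply)


def sens_spec(table: ContingencyTable) -> tuple[float, float]:
    """(sensitivity, specificity) = (tp/(tp+fn), tn/(fp+tn))."""
    if table.tp + table.fn < 1 or table.fp + table.tn < 1:
        raise ValueError("sensitivity/specificity undefined on an empty margin")
    return table.tp / (table.tp + table.fn), table.tn / (table.fp + table.tn)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_table(sensitivity: float, specificity: float,
                      n_events: int, n_nonevents: int) -> ContingencyTable:
    """Rebuild integer counts from a printed (se, sp, group sizes) summary."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if n_events < 1 or n_nonevents < 1:
        raise ValueError("group sizes must be >= 1")
    tp = _round_half_away(sensitivity * n_events)
    tn = _round_half_away(specificity * n_nonevents)
    return ContingencyTable(tp=tp, fn=n_events - tp, fp=n_nonevents - tn, tn=tn)
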
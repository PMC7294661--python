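"""Score every patient under the published instrument (full and imaging-free).

The full scheme sums 16 possible points over nine components; the reduced
scheme drops the FOI and Doppler-ultrasound items (max 14). Patients at
>= 10 points are classified at risk of new digital ulcers. Writes
results/scores_full.csv and results/scores_reduced.csv.
"""

from pathlib import Path

from cipdus import canonical_weights, read_cohort, score_cohort
from cipdus.published import SCORE_CUTOFF

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_cohort(RESULTS / "cohort.csv")
    for label, imaging in (("full", True), ("reduced", False)):
        scheme = canonical_weights(includes_imaging=imaging)
        scored = score_cohort(records, scheme, cutoff=SCORE_CUTOFF)
        scored.to_csv(RESULTS / f"scores_{label}.csv", index=False)
        by_outcome = scored.groupby("outcome")["score"]
        pos = scored["predicted_positive"]
        y = scored["outcome"].astype(bool)
        sens = (pos & y).sum() / y.sum()
        spec = (~pos & ~y).sum() / (~y).sum()
        print(f"{label} scheme (max {scheme.max_score} points):")
        print(f"  median score events={by_outcome.median()[1]:.0f} "
              f"non-events={by_outcome.median()[0]:.0f}")
        print(f"  at cutoff >={SCORE_CUTOFF}: sensitivity {sens:.2f}, "
              f"specificity {spec:.2f} "
              f"(published full-score: 1.00 / 0.74)")


if __name__ == "__main__":
    main()
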
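"""Published summary statistics of the CIP-DUS derivation cohort.

The score was derived on 76 systemic-sclerosis patients (22 developed new
digital ulcers within ~12 months, 54 did not). Patient-level data were never
deposited, but the publication prints, for every candidate predictor, its
sensitivity, specificity, odds ratio with 95% CI, apparent and
cross-validated AUC, and the integer weight it received in the score. Those
summaries are collected here: they parameterise the synthetic cohort
generator and serve as the reference values for the in-silico verification
table (:func:`cipdus.pipeline.verify_published_values`).

Two features were not assessed on the full cohort: capillary density was
readable in 19/22 events and 45/54 non-events, and fluorescence optical
imaging (FOI) in 16/22 and 44/54. Those denominators are forced by the
printed sensitivity/specificity/OR triples and drive the generator's
missingness rates.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PublishedFeature",
    "PUBLISHED_FEATURES",
    "N_EVENTS",
    "N_NONEVENTS",
    "NC_PATTERN_LEVELS",
    "NC_PATTERN_SPECIFICITY",
    "NC_PATTERN_CV_AUC",
    "NC_PATTERN_WEIGHTS",
    "SCORE_CUTOFF",
    "DIFFUSE_DU_COUNTS",
    "LIMITED_DU_COUNTS",
    "RECLASSIFICATION_COUNTS",
]

#: Realized outcome split of the derivation cohort.
N_EVENTS = 22
N_NONEVENTS = 54

#: Nailfold-capillaroscopy pattern grades (Cutolo classification), in score order.
NC_PATTERN_LEVELS = ("normal", "early", "active", "late")

#: Published cut-off: a patient is flagged at risk when the score is >= 10 points.
SCORE_CUTOFF = 10


@dataclass(frozen=True)
class PublishedFeature:
    """One binary predictor row of the published derivation table."""

    name: str
    sensitivity: float
    specificity: float
    n_events: int          # event-group denominator (22 unless data were missing)
    n_nonevents: int       # non-event-group denominator
    or_printed: float
    ci_printed: tuple[float, float]
    auc_printed: float
    cv_auc_printed: float
    weight_printed: int


#: Binary score components, in the order they appear in the publication.
PUBLISHED_FEATURES: tuple[PublishedFeature, ...] = (
    PublishedFeature("diffuse_subtype", 0.591, 0.741, 22, 54,
                     4.1, (1.5, 11.7), 0.67, 0.65, 1),
    PublishedFeature("mrss_gt8", 0.682, 0.815, 22, 54,
                     9.4, (3.0, 29.2), 0.75, 0.73, 2),
    PublishedFeature("pah", 0.273, 0.926, 22, 54,
                     4.7, (1.2, 18.7), 0.56, 0.54, 1),
    PublishedFeature("present_du_ps", 0.909, 0.611, 22, 54,
                     15.7, (3.3, 74.3), 0.76, 0.76, 3),
    PublishedFeature("history_du_ps", 1.0, 0.444, 22, 54,
                     36.2, (2.1, 626.9), 0.78, 0.77, 3),
    PublishedFeature("nc_density_reduced", 0.947, 0.333, 19, 45,
                     9.0, (1.1, 73.6), 0.62, 0.61, 1),
    PublishedFeature("foi_missing_enhancement", 0.563, 0.750, 16, 44,
                     3.9, (1.2, 12.8), 0.63, 0.61, 1),
    PublishedFeature("cdus_pathologic_gt35", 0.682, 0.667, 22, 54,
                     4.3, (1.5, 12.4), 0.67, 0.64, 1),
)

#: NC pattern: any scleroderma pattern (early/active/late) had 100% sensitivity
#: for new digital ulcers; 28.9% of non-events showed a normal pattern.
NC_PATTERN_SPECIFICITY = 0.289

#: Published per-grade cross-validated AUCs for the NC pattern.
NC_PATTERN_CV_AUC = {"early": 0.55, "active": 0.67, "late": 0.76}

#: Published per-grade points ("three points to late, two to active, one to early").
NC_PATTERN_WEIGHTS = {"normal": 0, "early": 1, "active": 2, "late": 3}

#: New-ulcer counts by cutaneous subtype: 13 of 27 diffuse (48.1%), 9 of 49 limited (18.4%).
DIFFUSE_DU_COUNTS = (13, 27)
LIMITED_DU_COUNTS = (9, 49)

#: Reclassification of predicted probabilities when the imaging components
#: (FOI + Doppler ultrasound) are added to the reduced score: among the 22
#: events 14 moved up and 4 down; among the 54 non-events 18 moved down and
#: 9 up. These counts give NRI = 62.1 on the x100 scale.
RECLASSIFICATION_COUNTS = {
    "events_up": 14, "events_down": 4, "n_events": 22,
    "nonevents_up": 9, "nonevents_down": 18, "n_nonevents": 54,
}
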
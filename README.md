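# cipdus

Construction and evaluation of an additive clinical risk score for **new
digital ulcers (DU) in systemic sclerosis (SSc)**, combining clinical data,
imaging and patient history (the CIP-DUS instrument).

Digital ulcers are a painful ischemic complication of SSc. The score was
derived on a 76-patient cohort (22 developed new DU within ~12 months): each
candidate predictor — diffuse cutaneous subtype, modified Rodnan skin score
(mRSS) > 8, pulmonary arterial hypertension, present and historical
DU/pitting scars, the nailfold-capillaroscopy (NC) pattern and capillary
density, fluorescence-optical-imaging (FOI) and colour-Doppler (CDUS)
findings — was assessed by univariate logistic regression and 10-fold
cross-validated AUC, and received integer points by banding:

```
cvAUC <= 0.60          excluded
0.60 < cvAUC <= 0.65   1 point
0.65 < cvAUC <= 0.70   2 points
0.70 < cvAUC           3 points
```

A patient's score is the sum of points over positive features (the NC
pattern contributes 0/1/2/3 for normal/early/active/late); patients scoring
**>= 10 of 16 points** are classified at risk. An imaging-free variant (max
14 points) drops the FOI and CDUS items.

The package is written for biostatisticians and rheumatology researchers who
want to reproduce, stress-test or extend this kind of points-based score. No
patient-level data were ever deposited, so the package ships a synthetic
cohort generator whose outcome-conditional feature prevalences equal the
published sensitivities and specificities — every pipeline stage is testable
without any download — plus an in-silico verification path that reconstructs
the published 2x2 tables from printed summaries alone.

## What's inside

| module | contents |
|---|---|
| `cipdus.cohort` | synthetic cohorts stratified by outcome; `published_cohort_config()` |
| `cipdus.contingency` | 2x2 tables, odds ratios (Haldane–Anscombe correction, Woolf CI, Fisher exact p), table reconstruction from printed se/sp |
| `cipdus.univariate` | Newton/IRLS logistic fits with separation handling, pooled out-of-fold cvAUC |
| `cipdus.roc` | ROC curves, tie-aware Mann–Whitney AUC, Youden cut-off, DeLong test |
| `cipdus.score` | the cvAUC→weight rule, canonical weight schemes, per-patient scoring |
| `cipdus.evaluate` | Hosmer–Lemeshow calibration, continuous NRI, IDI, full-vs-reduced comparison |
| `cipdus.pipeline`, `cipdus.cli` | end-to-end study report, published-value verification, `cipdus` CLI |

The numbered scripts under `analysis/` run the study replication as a
narrative: simulate → assess → score → evaluate → verify.

## Worked example

```python
from cipdus import (published_cohort_config, generate_cohort,
                    run_full_analysis, verify_published_values)

cohort = generate_cohort(published_cohort_config(seed=0))
report = run_full_analysis(cohort, seed=0)
print(round(report.full_score.auc, 3), report.full_score.best_cutoff)
```

On this seed the full score reaches an apparent AUC of **0.946** with the
Youden-optimal cut-off at **>= 10 points** (sensitivity 0.86, specificity
0.89), the imaging-free score 0.930, and adding the imaging items gives
IDI = 5.0 (p = 0.017) — the same qualitative picture as the derivation
study (cvAUC 0.83 vs 0.81, cut-off >= 10, IDI 9.7). The absolute AUC runs
high because the generator draws features independently given the outcome;
see `docs/methods.md`.

`verify_published_values()` needs no data at all and recomputes 16 printed
quantities; 15 reproduce exactly at their printed rounding (the one
exception is the quasi-separated history-of-ulcers odds ratio, where the
Haldane reconstruction gives 36.15 against a printed 36.2):

```
$ cipdus replicate
... # computed-vs-printed table, e.g. or_mrss_gt8  9.4286  9.4  True
# 15/16 quantities match at printed rounding
```

The CLI mirrors the pipeline: `cipdus simulate|assess|score|evaluate|replicate`
(see `--help` for options; all randomness flows from `--seed`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a published-structure cohort from the given seed, runs the
complete pipeline (feature assessment, both score variants, DeLong/NRI/IDI
comparison, calibration) and the printed-value verification, writing the
study report and verification table next to the requested output path.
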
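# Methods

## The instrument being modelled

The score predicts new digital ulcers (DU) in systemic sclerosis over a
~12-month horizon as an integer sum of weighted binary findings plus an
ordinal capillaroscopy term. Derivation was univariate throughout: each
candidate feature was related to the outcome by its own logistic model, its
predictive value summarised by a 10-fold cross-validated AUC, and an
integer weight assigned by banding (excluded at cvAUC <= 0.6, then 1/2/3
points for (0.6, 0.65] / (0.65, 0.7] / (0.7, 1]). There is no multivariable
fit anywhere; the additivity *is* the model.

Two published weights contradict the banding rule: the skin-score item
carries 2 points despite cvAUC 0.73 (rule: 3) and pulmonary arterial
hypertension is retained at 1 point despite cvAUC 0.54 (rule: exclude). We
treat the printed weights as the instrument (`canonical_weights`) and keep
the rule (`weight_from_cvauc`) as a separate, reusable path; whether those
two rows are deliberate clinical overrides is not stated in the source, so
both paths are first-class. The early capillaroscopy pattern likewise keeps
1 point (cvAUC 0.55) because the instrument explicitly assigns 1/2/3 to
early/active/late.

## Synthetic cohort generator

The generator states a world and stays there. Defaults
(`published_cohort_config`):

* **Outcome counts are fixed**: exactly 22 events / 54 non-events per
  cohort (stratified generation), mirroring the realized derivation cohort
  rather than sampling prevalence. This makes in-silico reconstructions of
  the published arithmetic exact.
* **Binary features** are independent Bernoulli draws given the outcome,
  with P(feature | event) = published sensitivity and
  P(feature | non-event) = 1 − published specificity.
* **Missingness** is modelled only where the published denominators force
  it: capillary density (3/22 events, 9/54 non-events missing; expected
  denominators 19 and 45) and FOI (6/22 and 10/54; expected 16 and 44).
  Draws are Bernoulli, so realized denominators fluctuate around those
  values. The outcome is never missing.
* **Capillaroscopy pattern**: events put zero mass on "normal" (the
  any-scleroderma-pattern finding had 100% sensitivity); non-events put
  0.289 on "normal" (the published specificity). The split across
  early/active/late is uniform in both groups — a synthetic-only choice,
  the source does not report it.
* **Reproducibility**: one integer seed; each feature draws from a
  substream keyed on (seed, crc32(feature name)), so adding or removing a
  feature never perturbs another feature's values.
* The cutaneous-subtype counts follow the published 2x2 row (27 diffuse /
  49 limited implied by se 59.1% / sp 74.1%), not the supplementary
  baseline table (which lists 43 limited + 19 diffuse = 62, the female
  count); the two are irreconcilable and the 2x2 row is what the score
  derivation used.

**What a green test does not establish.** Features are conditionally
independent given the outcome. Real SSc features are strongly correlated
(subtype with skin score, present with historical ulcers), which *lowers* a
composite's incremental discrimination; synthetic cohorts therefore yield
composite AUCs around 0.93–0.95 where the study reported 0.83. Tests on
synthetic cohorts validate the estimators and the pipeline plumbing, not
the published composite performance, which is unreproducible without the
original patient-level data. Published-value acceptance checks instead go
through the deterministic reconstruction path, which does not involve the
generator.

## Contingency statistics

Odds ratios are (tp·tn)/(fn·fp) with the Haldane–Anscombe correction (+0.5
to all four cells) applied only when a zero cell exists — the rule that
reproduces the published history-of-ulcers row (OR 36.15 vs printed 36.2,
CI lower bound 2.1) from its summary statistics. CIs are Woolf log-normal
intervals (±1.96 SE on the log scale, SE from the reciprocal cell sums,
corrected cells when the correction applied); these reproduce every
reconstructable printed bound. The p-value is always the two-sided Fisher
exact test on the *uncorrected* counts, with the usual convention (sum of
hypergeometric probabilities not exceeding the observed table's, with a
1 + 1e-7 relative tolerance — scipy's convention, verified against
brute-force enumeration in the tests).

`reconstruct_table` rounds half away from zero. Banker's rounding would
break the skin-score row (0.682 × 22 = 15.004 survives either way, but
0.5 × 5 cases differ); the chosen convention recovers all eight published
ORs to one decimal.

## Logistic fits, separation, cvAUC

Fits are two-parameter Newton/IRLS, converged when the log-likelihood
changes by < 1e-10. Quasi-complete separation (a zero cell) sends the
slope to ±∞; the fit stops once |slope| > 15, flags
`separation_detected`, and clamps the slope. exp(15) ≈ 3.3e6, far beyond
any interpretable odds ratio at these sample sizes, so the cap changes no
reported probability ranking. For separated features the reported OR is the
corrected contingency OR, never the clamped slope.

cvAUC uses outcome-stratified folds (shuffle each class, deal round-robin)
and computes one AUC on the pooled out-of-fold predictions: with 22 events
and k = 10, per-fold AUCs would rest on ~2 events and be degenerate.
A training fold containing a single outcome class raises; nothing is
silently skipped. Fold assignment is the only seed-dependent step in the
assessment path.

## ROC and DeLong

Positivity is "score >= threshold" (the instrument's ">= 10 points"
phrasing); thresholds are the observed score values. AUC is computed two
independent ways — tie-corrected rank statistic and trapezoid under the
empirical staircase — asserted equal to 1e-12. The Youden-optimal cut-off
breaks ties toward higher sensitivity (a screening instrument should not
miss events), then toward the lower threshold.

The DeLong test uses placement values; the two-model comparison is
reported as (ΔAUC)²/var(Δ) against chi-square with 1 df, matching the
source's reporting style. Identical score vectors have zero difference
variance and are reported as non-comparable (statistic 0, p = 1).

## Calibration, NRI, IDI

Hosmer–Lemeshow groups patients into (by default 10) probability-quantile
bins with ties kept together; the statistic is Σ (O−E)²/(E(1−E/n)). The
default df is groups − 2 (the convention for model-fitted probabilities)
and is configurable: when the tested probabilities are *true* rather than
fitted — as in the null simulations used for validation — the statistic
carries g df, and the tests pass df = g explicitly. (The source's printed
calibration "chi-square = 12.3, p = 0.58" is itself inconsistent with
df = 8, which would give p ≈ 0.14; its df is unstated.) When fewer than 3
distinct probabilities exist, value-based binning is impossible and the
implementation falls back to equal-size positional groups rather than
refusing, so degenerate single-value inputs still return a finite
statistic.

NRI is the continuous ("any movement") flavor: up/down means a strictly
higher/lower predicted probability under the new model — the definition
under which the published movement counts (14/4 of 22 events, 18/9 of 54
non-events) give exactly 62.1 on the ×100 scale. Its p-value is the
standard asymptotic z-test with SE² = (up_e+down_e)/n_e² +
(up_n+down_n)/n_n² (the source does not state its test). IDI is the change
in discrimination slope, ×100, with an unpaired two-group z-test on the
per-patient probability changes. Both statistics are exactly antisymmetric
under swapping the models.

`compare_models` maps each integer score to a probability through its own
univariate logistic fit on the cohort (the source's logistic framing); an
empirical score→event-rate mapping is available behind
`prob_mapping="empirical"`.

## Known limitations

* No between-feature correlation in the generator (see above): composite
  performance on synthetic cohorts is optimistic.
* The published per-feature AUCs for PAH (0.56), history of ulcers (0.78),
  NC density (0.62) and FOI (0.63) do not satisfy the binary-predictor
  identity AUC = (se+sp)/2 implied by their own rows; the package asserts
  the identity internally and makes no attempt to match those four printed
  values.
* Only univariate models: no multivariable refitting, penalisation or
  recalibration of weights beyond the banding rule.
* The ordinal early/active/late split among scleroderma patterns is a free
  generator parameter (uniform by default) with no published counterpart.
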
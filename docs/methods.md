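# Methods

## The problem

Large ageing cohorts cannot send every participant to a clinician, so
case ascertainment for dementia and mild cognitive impairment is often done
by a *psychometric algorithm*: a deterministic rule set that maps
neuropsychological scores, self-report screeners and an informant interview
onto published diagnostic criteria. `ncdalgo` implements such an algorithm
for four nosologies — DSM-5 major neurocognitive disorder (NCD), DSM-5 mild
NCD, DSM-IV dementia, and IWG mild cognitive impairment (MCI) — together
with the statistics used to evaluate one diagnostic system against another
(Cohen's kappa with bootstrap CIs, criteria-based logistic ROC, predictive
values, overlap percentages) and a synthetic-cohort simulator so the whole
pipeline can be exercised and tested without access to any real cohort.

## Standardization and norms

Raw test scores are converted to z scores against *internal* norms: the mean
and sample SD of the whole cohort at the later wave (wave 4), stratified by
sex and education band (low < 10 years, medium 10–14, high 15+; the band
edges are half-open, and fewer than five years clamps to low). Timed tests
(Trail Making, reaction time, Stroop) are negated after standardization so
that z ≤ −2.0 always reads "severely impaired" regardless of scale
direction. A domain score is the arithmetic mean of its available member-test
z scores (minimum one member by default); a domain with no observed member is
*missing*, never zero.

Longitudinal decline is standardized the same way against the cohort
distribution of raw (wave 4 − wave 3) change scores, restricted to the nine
decline-eligible tests (word-list learning immediate/delayed, digits
backward, symbol–digit substitution, pegboard, letter fluency, Trails B, and
simple/choice reaction time). The decline thresholds are then applied to
this change z exactly as to the level z. The alternative reading — applying
the threshold to the wave-4 level after decline — is not used: the change-z
reading keeps "decline" a property of the trajectory rather than the
endpoint, and makes decline-only diagnoses possible, which the criteria
tables permit.

Because norms are internal, z scores are exact within stratum (mean 0, SD 1
to 1e−9 by construction) but relative: a cohort-wide shift in true ability is
invisible. This mirrors how population studies without external norms
operate.

## Cutoffs

Severe impairment is z ≤ −2.0 (inclusive; the criteria tables print "≤" even
though surrounding prose says "<", and the tables are the operationalization).
Mild impairment is a half-open band below normal and above severe, with two
variants: (−2.0, −1.0] (the default, `sd1_0`) and (−2.0, −1.5] (`sd1_5`).
The 1.5 SD band is nested inside the 1.0 SD band, so mild diagnoses under
`sd1_5` are a subset of those under `sd1_0` on any cohort — a structural
invariant the tests enforce. The MCI objective-impairment clause (2a) is
printed with a closed lower bound, so it additionally admits exactly −2.0.

## Screening

Screen 1 triages the cohort before full evaluation. A participant is
selected when they have a prior study diagnosis (MCI-like or dementia), or
*both* objective evidence (any test z ≤ −1.5, the normal-quantile rendering
of the 6.7th percentile, or MMSE ≤ 24 at wave 4) *and* subjective evidence
(MAC-Q > 24, an MMSE drop of more than 3 points between waves, or MMSE ≤ 24
at both waves). The sentence defining the rule is ambiguous about operator
precedence; we read it as `prior ∨ (objective ∧ subjective)`, which matches
the narrative that selection required impairment plus decline evidence with
a prior diagnosis as an independent route. `ScreenResult.reasons` lists the
satisfied arms only when the participant is selected: a lone subjective
complaint does not select and is therefore not reported as a selection
reason (this resolves a tension between "enumerate every satisfied arm" and
"selected iff reasons non-empty" in favour of the latter).

Screen-negative participants are classified normal without evaluating the
nosologies (full-cohort classification is available via a flag).

## The criteria engine

Each nosology is a conjunction of criteria; each criterion is a Boolean
formula over thresholded scale values, informant endorsements and domain
grades. Shared clauses:

* **Concern (A1)** — MAC-Q > 24, IQCODE > 3.31, a recent doctor's
  consultation about cognition, or informant-reported worsening.
* **Interference (major/dementia B)** — self-reported memory-related IADL
  problems, need for household/personal care help, or Bayer IADL > 3.12.
* **No-delirium (C)** — symptom onset ≥ 6 months ago, or delirium signs
  present for strictly less time than the cognitive change.
* **Not-better-explained (D)** — PHQ-9 < 10 and no history of psychosis.

Nosology-specific structure: DSM-5 major requires any of the six domains (or
any decline test) at z ≤ −2.0; DSM-IV dementia requires the learning-and-
memory domain at z ≤ −2.0 *plus* a second disturbance (executive or language
domain severe, ideomotor-praxis test severe, gnosis — naming test severe
with letter fluency preserved above −2.0 — or a severe decline); DSM-5 mild
requires a mild-band domain or decline and *non*-interference (its B is the
negation of the major-NCD interference clause); IWG MCI requires not being
demented with at least one domain at z ≤ −1.0, either concern plus a
mild-band non-social domain (2a) or a mild-band decline (2b), and preserved
IADLs (no difficulty on Bayer items 2/4/11, or no care need, or
Bayer < 3.12). Social cognition is excluded from the MCI domain list. When
the *only* severe domain is social cognition (major NCD) or the only second
disturbance is praxis/gnosis (dementia), the interference clause must be
corroborated by the matching informant endorsements (DEX-Q items 9/11/13/20
at "sometimes"-or-more, i.e. ≥ 2 on the 0–4 frequency scale, or the listed
behaviour flags); for DSM-5 mild the social caveat is inverted.

Precedence: major NCD suppresses mild NCD; MCI's own criterion 1 excludes
dementia and major NCD. A record meeting nothing is labelled `normal`.

### Missing data

Criteria are evaluated in Kleene three-valued logic (met / not met /
unknown), so unknowns propagate honestly through AND/OR/NOT. The policy then
resolves unknowns at the criterion level:

* `permissive` (default): unknown inclusion criteria (A1, A2, B) → not met;
  unknown exclusion criteria (C, D) → met. This is what lets case files with
  no informant interview still be screened — the exclusionary clauses, which
  only an informant can speak to, default to non-exclusion.
* `strict`: every unknown → not met.

One consequence of transcribing the printed no-delirium rule literally: a
participant with *no* delirium signs but unknown onset leaves C unknown,
which `permissive` resolves to met and `strict` to not met. The rule as
printed has no "no delirium at all" arm, and we did not add one.

The engine is verified against an independent brute-force oracle that
re-transcribes every clause and resolves unknowns by possible-worlds
enumeration (each unknown leaf expanded to both truth values); the two agree
on thousands of random records across both policies and both cutoff
variants.

## Evaluation statistics

* **Cohen's kappa** uses the marginal-product expected agreement; it is
  undefined (an error, not a NaN) when expected agreement is 1. The 95% CI
  is a percentile bootstrap over case resamples (1000 by default, seeded);
  resamples with degenerate marginals are skipped and counted, and the
  bootstrap SD is reported as the SE.
* **Criteria-based ROC**: the binary criteria of a nosology all enter an
  additive logistic model of the expert label ("equally weighted" meaning no
  a-priori differential weighting; coefficients are still estimated by
  maximum likelihood). AUC of the predicted probabilities is computed by the
  rank (Mann–Whitney) estimator with average-rank tie correction; its CI is
  a 2000-resample percentile bootstrap, chosen for symmetry with the kappa
  procedure since no analytic method is prescribed. On perfect separation or
  non-convergence the fit falls back to L2-penalized logistic regression and
  the result is flagged.
* **Predictive values**: PPV = TP/(TP+FP), NPV = TN/(TN+FN); empty
  denominators yield an explicit `None`, never a silent NaN.
* **Overlap**: for a reference nosology vs a DSM-5 category,
  `pct_of_ref_captured` = 100·n_yy/ref-positives and `pct_increase` =
  100·(cmp-positives − ref-positives)/ref-positives.
* **Group contrasts**: per-domain means compared with Welch's
  unequal-variance t test.

## The synthetic cohort

The generator emulates the record structure of a community cohort aged
72–78. Each participant draws a latent class from the prevalence (defaults
normal 0.84 / mild 0.12 / major 0.04, matching the expert-diagnosis rates of
the motivating cohort: roughly 4.3% dementia-level and 11.9% mild-level
among 1644). Class-specific mean shifts (defaults: major −2.8 in
learning/memory and −2.4 elsewhere; mild −1.5 and −1.2) are applied to
equicorrelated latent domain scores (correlation 0.5) at wave 4, with 30% of
the shift already present at wave 3 so decline paths are exercised. Raw test
scores add per-test measurement noise (SD 0.35 z units) and live on
arbitrary fixed raw scales with sex and education offsets, so the norming
stratification does real work. MMSE, MAC-Q, PHQ-9, IQCODE, Bayer IADL,
DEX-Q, the behaviour flags and care-need items are monotone (linear or
logistic) transforms of the realized latent severity plus noise, calibrated
so that normal participants rarely cross the complaint/interference
thresholds while major cases usually do and mild cases genuinely straddle
them. The informant block is masked completely for 9.5% of participants
(the missing-informant rate of the motivating study). The "expert" is the
true class passed through a row-stochastic 3×3 confusion matrix (identity by
default).

What the generator does **not** model: etiological subtypes, practice
effects, attrition, item-level questionnaire structure, non-monotone
symptom–severity relationships, and measurement invariance violations
across strata. Passing tests therefore demonstrate the internal coherence
of the rules and statistics, not clinical validity on real data.

`recovery_scenario()` packages the parameter-recovery conditions used in
testing: major shifted −3.5 in every domain, mild −0.8, no informant
missingness. Under it, with a noise-free expert, algorithm-vs-expert kappa
for the major category exceeds 0.9 at n = 2000 and degrades monotonically
as expert confusion noise rises.

## Numerical and design choices

* Sample SDs everywhere (ddof = 1); norm cells require ≥ 10 observations
  (configurable) and positive variance, else a named error.
* The 6.7th percentile is implemented as the normal quantile z ≤ −1.5 on the
  stratified norms rather than as an empirical within-sample rank, for
  consistency with the z-based engine.
* Education bands resolve the overlapping printed edges (10 and 15 appear in
  two bands) as half-open intervals.
* Delirium clause uses strict inequality (duration < onset).
* Bootstrap and simulator randomness all flow from `numpy.random.default_rng`
  with explicit integer seeds; every stochastic output is bit-reproducible
  given the seed.
* Problem sizes used in the shipped tests and the acceptance script —
  cohorts of 300–2000, an overlap-table population of 368, 1000-record
  oracle sweeps, exhaustive kappa verification over all 2×2 tables with
  total ≤ 50 — are the package's chosen balance of statistical resolution
  against quick iteration; all complete in well under a minute each.

## Known limitations

* The full screening rule of the motivating study lives in unpublished
  supplementary material; only the main-text summary is implemented.
* Real-cohort accuracy figures (e.g. AUC ≈ 0.95 for major NCD against expert
  diagnosis) cannot be reproduced without the original data, which has no
  public accession; the synthetic pipeline reports analogous quantities
  under simulated conditions instead.
* The age-associated memory impairment / cognitive decline categories and
  DSM-IV mild NCD are not operationalized (no published rule to transcribe),
  and etiological specifiers are expert judgements outside an algorithm's
  reach.
* A diagnosable record can in principle be screen-negative when its only
  concern evidence is informant-reported (the screen's subjective arms are
  self-report and MMSE based); in the shipped pipeline this cannot surface
  because screen-negatives are never evaluated.
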
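# Methods

## The estimation problem

A population-based aging study observes three nested cohorts: a clinical
cohort with consensus diagnoses (cognitively unimpaired, CU; mild cognitive
impairment, MCI; dementia, subclassified into clinically probable Alzheimer
disease and other etiologies), a subset with amyloid PET, and a subset of
that with tau PET. Dementia among sampled nonparticipants is found by passive
medical-record review. The target quantities are population prevalences, by
integer age 60–90 and sex, of three biomarker-defined entities — Alzheimer
continuum (A+), Alzheimer pathologic change (A+T−), biologically defined
Alzheimer disease (A+T+) — and of the clinical entities (CU, MCI, dementia,
probable AD, MCI-or-dementia). A−T+ profiles belong to none of the biomarker
entities and are not estimated.

Because the cohorts shrink sharply at each imaging stage and participation is
selective, prevalence is estimated **in stages** and recombined by the law of
total probability (README shows the formulas). Biomarker positivity is
defined by SUVR thresholds: amyloid ≥ 1.48 (centiloid ≈ 22), tau ≥ 1.25 on
the temporal meta-ROI. A value exactly at the cut point counts as abnormal;
the boundary rule is configurable (`CutpointConfig.abnormal_if_equal`)
because thresholds are conventionally quoted without a boundary convention.

## Stage models

* **Clinical model.** Weighted multinomial logit of the four clinical
  categories on `z + z² + male + z·male`, with `z = (age − 75)/10`. The
  quadratic-with-interaction form is the simplest that produces smooth,
  possibly sex-crossing curves; it is configurable (`clinical_terms`).
  Probable AD is a category of this model rather than a separate conditional
  fit, which keeps the staged structure uniform and guarantees
  dementia ≥ probable AD pointwise.
* **Conditional biomarker models.** Per broad clinical group (CU, MCI,
  dementia), weighted logistic fits of A+ on `z + male` (amyloid cohort) and
  of T+ among A+ on `z + male` (tau cohort). The dementia group is pooled to
  a weighted intercept across ages and sexes: dementia imaging samples are
  too small for stable slopes, and the two dementia subcategories share the
  pooled group estimate in the combination. Groups below a configurable
  minimum size (default 25) fall back to flagged intercept-only fits;
  all-positive/all-negative outcomes yield flagged constants.
* Intercept-only fits of either family are computed in closed form (weighted
  proportions), so degenerate cases are exact rather than
  optimizer-dependent. The multinomial is fitted by scikit-learn's
  unpenalized multinomial logistic regression with per-record weights; binary
  stages use statsmodels GLM.

## Weights

Each analysis weight is `stratum weight × Π 1/p̂_stage`. Stratum weights are
the inverse sampling fractions of the 10-year age × sex strata (the design
samples equal numbers of women and men per band). Participation at each stage
(enrollment among everyone contacted; amyloid PET among the enrolled; tau PET
among amyloid participants) is modelled by logistic regression on
`z + z² + male + education` — sex, age and education being the known
determinants of participation. Education enters as the four attained
categories (<12, 12, 13–16, >16 years) with 13–16 as reference.

Weights are truncated at the 99th percentile by default (configurable,
including off) and the truncation is recorded in the sample metadata.
Truncation trades a small attenuation bias for variance: in the default
synthetic scenario it costs roughly half a percentage point of A+ prevalence
at the oldest ages, which is why the package reports truncation metadata
rather than hiding it.

**Dementia and passive surveillance.** When passive review of nonparticipant
records is treated as complete (the default whenever passive records are
present, `passive_complete`), every dementia case in the sampled strata is
observed through one route or the other. Dementia records therefore carry the
stratum weight only — including *actively* enrolled dementia cases — in the
clinical-status model. Weighting active dementia cases by 1/p̂ as well would
count the nonparticipant dementia mass twice: once through the inverse
weight, and again through the passive cases themselves. With incomplete
passive sensitivity the estimator is conservative for dementia (it misses a
fraction of nonparticipant cases); this is a documented limitation rather
than a correction the data could identify. Passive cases never enter the
imaging-stage models or their participation fits.

## Uncertainty

The delete-a-group jackknife (default G = 10 random, seeded groups) re-fits
the whole pipeline — participation models, weights, stage models, combination
— per left-out group; variance is `(G−1)/G · Σ (θ₍g₎ − θ̄)²`. Groups are
assigned once on the full observed frame so the nested subcohorts inherit
membership and nesting is preserved in every replicate. With G = n this
reduces to the classical delete-1 jackknife (exact `s²/n` for a mean).
Intervals are formed on the logit scale and back-transformed so they respect
[0, 1]; at estimates of exactly 0 or 1 the interval falls back to the linear
scale with clipping, flagged in the curve provenance. Because the SE carries
only ≈ G−1 degrees of freedom, interval quantiles come from a Student
t(G−1), not a normal — with the normal quantile, empirical coverage at the
study's scaled-down replicate size is ≈ 92–93% instead of 95%.

Two curves are compared by a scalar summary: the average pointwise difference
over the age grid, weighted by the estimated population age distribution
(from the weighted clinical sample), studentized by its jackknife SE. The
reference distribution is normal by default and t(G−1) when the caller passes
`df` (the pipeline does); the summary statistic itself is this package's
concretization of a curve-level test — the underlying study design reports
curve P values without printing a formula.

## Sensitivity analyses

* **Alternative tau ROIs** (entorhinal, inferior temporal, lateral parietal):
  no published per-ROI cut points exist, so each alternative channel's cut is
  the empirical quantile matching the primary channel's abnormal fraction
  among IPW-weighted CU tau-PET participants (specificity matching — the
  least-assumption choice; recorded in the output table).
* **Cut-point recalibration**: the amyloid and tau cuts are moved to the
  weighted CU quantile at which 10 points more (or fewer) CU participants are
  abnormal, and the pipeline is re-run. Recalibration is per modality; if a
  shifted target is not a probability (e.g. CU tau abnormality below 10%
  under −10), that modality keeps its primary cut with a warning. The
  returned cut is the nearest achievable empirical fraction, ties resolved
  toward the higher cut, which makes the cut monotone non-increasing in the
  shift.

## The synthetic population generator

The generator is the ground truth against which all estimation is tested. It
emulates, in order: an enumerated population aged 60–90 with an
exponentially declining age pyramid (rate 0.055/year) and a mildly
age-declining male fraction; education from a fixed four-category
distribution (12/30/38/20%); clinical status from a multinomial logit in
`z, z², sex, education`; latent A ~ Bernoulli(logit(status, z, sex, edu));
latent T ~ Bernoulli(logit(status, z)) among A+; SUVR channels as log-normal
mixtures conditional on the latent state (strictly positive and right-skewed,
like real SUVR), with the four tau ROI channels sharing one latent T state
through a Gaussian copula (pairwise correlation 0.9) on the log scale;
stratified sampling (default: 75% of the smaller sex per 10-year band, both
sexes equally); three logistic participation stages in `z, sex, education`;
and passive detection of dementia among sampled nonparticipants with
sensitivity 1 by default.

Under the default *separated* setting the SUVR mixture components are
truncated at the generating cut points (amyloid 1.48, tau 1.25), so
thresholding reproduces the latent states exactly and estimator error can be
attributed entirely to sampling, participation and model form;
`separated=False` gives overlapping components (≈ 0.5–2% misclassification)
for tests that need disagreeing channels.

`true_prevalence` evaluates every target entity in closed form by summing the
generating probabilities over clinical strata and the education distribution;
A+T− + A+T+ = A+ holds exactly by construction.

**Default scenario.** The defaults were calibrated once to make unweighted
estimation visibly biased — participation falls with age and sharply with low
education (enrollment logit −1.5 for <12 years vs reference), while low
education raises both impairment (clinical logits +1.5 to +1.7) and amyloid
positivity (+1.8) — so that the naive participants-only A+ estimate at age 75
is ~4–6 percentage points too low while the IPW estimate is within a point
or two. Intercepts put marginal rates near field-typical values: P(A+|CU) ≈
0.30 at 75, dementia prevalence ≈ 1–2% at 70 rising to ≈ 15–18% at 85,
pooled P(A+|dementia) ≈ 0.75, enrollment ≈ 55%, amyloid PET ≈ 35% of the
enrolled, tau PET ≈ 40% of the amyloid cohort (matching the published cohort
ratios 1524/4660 and 576/1524). Education effects on amyloid given status
stand in for whatever unmeasured health factors correlate participation with
biomarker status in real cohorts; the point is a known, adversarial-but-
correctable selection mechanism, not a causal claim about education.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: measurement error in SUVR relative to the latent state
(default is perfectly separated), longitudinal visits and within-person
drift, birth-cohort effects, terminal illness and mortality between stages,
diagnosis misclassification by the consensus process, participation driven
directly by cognition conditional on covariates (which IPW on demographics
could *not* fix), and finite-population spatial structure. Tests demonstrate
internal consistency of the estimator under its own assumptions, plus
robustness to the modelled selection mechanism.

## The bookkeeping fixture

`make_table1_fixture` generates person-level records reproducing the
published cohort tables cell-for-cell. Each clinical group is decomposed into
three blocks (tau-PET / amyloid-only / clinical-only); each block receives
the *difference* of the printed cohort-level counts for sex, education and
APOE ε4, so nesting and every printed marginal are exact simultaneously.
Ages are drawn uniformly within each block's printed interquartile range
(clipped to the printed range); SUVR values and the probable-AD share of
dementia (configurable fraction, default 0.7) are synthetic — the published
tables print no dementia-etiology split. The fixture asserts counts, never
distributions. The enrollment-flow frame (5643 nonparticipants, 770
administrative exclusions, 12 unclassifiable participants) is appended so the
screening flowchart is reproducible; cross-tabulations not printed (e.g.
sex × education within a block) are arbitrary but seeded.

## Numerical choices and problem sizes

Optimizer tolerances are set so the saturated-model and weighted-proportion
identities hold to 1e-8 (lbfgs tol 1e-12 for the multinomial; IRLS tol 1e-10
for GLMs). Coefficients above 30 in absolute value flag probable separation.
Missing education is treated as the reference category in design matrices and
preserved as missing in the data. All randomness flows from explicit seeds;
no global RNG state is used.

The simulation studies use: n = 200 000 fully observed for oracle
equivalence; n = 100 000 for the bias-correction and cut-point analyses;
500 replicates of n = 5 000 for CI coverage; 200 replicates of n = 2 500 for
the null calibration of the curve-comparison test. These sizes give
Monte-Carlo error comfortably below the tolerances being asserted (≈ 0.3–1
percentage point at the cohort sizes involved) while keeping the full suite
runnable on a single CPU.

## Known limitations

* The estimator assumes participation is ignorable given sex, age and
  education; violations (direct selection on cognition or biomarker status)
  bias it in ways no reweighting on these covariates can repair.
* Weight truncation introduces a small attenuation bias where weights are
  largest (old, low-education strata).
* The pooled dementia biomarker estimate ignores age trends within dementia;
  at the oldest ages this contributes up to ~1 point of A+ error.
* With passive sensitivity < 1 the dementia prevalence is underestimated by
  the undetected fraction among nonparticipants.
* Jackknife inference treats the G groups as exchangeable; very small
  cohorts (< a few hundred) make G = 10 replicates unstable, and the
  pipeline flags (and with > 20% failures, refuses) such runs.
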
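# adprev

Staged, participation-weighted estimation of the age- and sex-specific
population prevalence of **biologically defined Alzheimer spectrum entities** —
Alzheimer continuum (A+), Alzheimer pathologic change (A+T−), and biologically
defined Alzheimer disease (A+T+), per the NIA-AA research framework — alongside
the **clinically defined entities** (MCI, dementia, clinically defined probable
AD), from three nested cohorts with differential participation.

It is written for epidemiologists and biostatisticians working with
population-based aging cohorts in which clinical assessment, amyloid PET and
tau PET are available for nested subsets of decreasing size, participation is
selective, and dementia among nonparticipants is ascertained passively from
medical records.

## The estimator

Let `x = (age, sex)`. Prevalence is estimated in stages on the three nested
cohorts and combined by the law of total probability:

```
P(A+ | x)    = Σ_c  P(c | x) · P(A+ | c, x)
P(A+T+ | x)  = Σ_c  P(c | x) · P(A+ | c, x) · P(T+ | A+, c, x)
P(A+T− | x)  = P(A+ | x) − P(A+T+ | x)
```

where `c` ranges over the clinical categories (cognitively unimpaired, MCI,
dementia due to probable AD, dementia of other etiology):

* `P(c | x)` — weighted multinomial logit on the clinical cohort
  (quadratic age, sex, age×sex);
* `P(A+ | c, x)` — weighted logistic per broad clinical group on the amyloid
  PET cohort, with A+ defined as SUVR ≥ 1.48 (centiloid ≈ 22);
* `P(T+ | A+, c, x)` — weighted logistic on the A+ members of the tau PET
  cohort, T+ as temporal meta-ROI SUVR ≥ 1.25; the dementia group is pooled
  to an intercept-only estimate.

Each stage is weighted by the product of the stratum sampling weight (inverse
sampling fraction of the 10-year age × sex stratum) and inverse probabilities
of participation, from per-stage logistic models of participation on sex, age
and education. Confidence bands come from a delete-a-group jackknife (G = 10)
that re-fits the *entire* pipeline per replicate; curve differences are tested
by an age-distribution-weighted summary studentized against its jackknife SE.

Because no person-level cohort data are distributable, the package ships a
**synthetic population generator** with a fully known closed-form prevalence
oracle (`true_prevalence`) and a seeded **bookkeeping fixture** that
reproduces the published cohort tables exactly; both are first-class, tested
modules.

## Worked example

```python
import numpy as np
from adprev import (default_params, generate_population, simulate_observation,
                    fit_staged, PipelineConfig, true_prevalence, report_table)

params = default_params()                        # biased-participation scenario
pop = generate_population(params, 100_000, seed=0)
obs = simulate_observation(pop, params, seed=1)  # sampling + participation
fit = fit_staged(obs, PipelineConfig())          # IPW + stage models
naive = fit_staged(obs, PipelineConfig(use_ipw=False))

age = np.array([75])
truth = 0.5 * sum(true_prevalence(params, "A_plus", s, age)[0] for s in ("female", "male"))
ipw = 0.5 * sum(fit.curve("A_plus", s, age).estimates[0] for s in ("female", "male"))
unw = 0.5 * sum(naive.curve("A_plus", s, age).estimates[0] for s in ("female", "male"))
print(f"A+ at 75 — truth {truth:.3f}, IPW {ipw:.3f}, naive {unw:.3f}")
```

prints

```
A+ at 75 — truth 0.338, IPW 0.333, naive 0.286
```

i.e. ignoring selective participation understates Alzheimer-continuum
prevalence at age 75 by ≈ 5 percentage points (participants are younger and
better educated, and education is associated with both participation and
amyloid status in the scenario), while the weighted staged estimate lands
within half a point of the generating value.

The numbered drivers under `analysis/` tell the full story end to end —
`01_cohort_bookkeeping.py` (published cohort tables reproduced from the
fixture), `02_simulate_cohort.py` (who gets observed), `03_fit_prevalence.py`
(IPW vs naive vs truth), `04_uncertainty.py` (jackknife bands and sex
comparisons), `05_sensitivity.py` (tau ROI and cut-point variants) — writing
their tables to `results/`.

There is also a CLI:

```bash
adprev fixture --out table1.csv --seed 0      # bookkeeping fixture
adprev validate table1.csv
adprev run --out out/ --seed 1                # simulate + fit + jackknife + sensitivity
adprev report --prevalence out/prevalence.csv --ages 70,85
```

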
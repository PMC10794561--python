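# Methods

`metacvd` implements a genomic risk-prediction analysis for cardiovascular
disease (CVD) among type 2 diabetes (T2D) patients: a *meta polygenic risk
score* (meta-PRS) combining per-subtype scores for coronary artery disease
(CAD), ischemic stroke (IS) and heart failure (HF), evaluated with survival
statistics on a hospital-episode-derived cohort, stratified by T2D onset
age. Because the biobank data such analyses run on is access-restricted,
the package ships a synthetic study generator whose output has the
statistical structure the analysis assumes; all tests run against it.

## The meta-PRS combination

Each subtype PRS is the usual weighted allele-dosage sum
`score_i = sum_j w_j d_ij`. Given the three standardized subtype scores
`Z_i1, Z_i2, Z_i3`, the meta score is

    meta_i = (b1 Z_i1 + b2 Z_i2 + b3 Z_i3) / D
    D^2    = b1^2 + b2^2 + b3^2
             + 2 b1 b2 r12 + 2 b1 b3 r13 + 2 b2 b3 r23

where `b` are Cox log-hazard coefficients of the standardized scores for
CVD occurrence among T2D patients and `r` is the Pearson correlation
matrix of the standardized scores. `D` is exactly the standard deviation
of the numerator under `r`, so the meta score has unit variance on the
population that supplied `b` and `r` (a property the tests verify by
Monte Carlo at n = 10,000, tolerance 0.03).

Training is two-stage:

1. **Candidate selection.** Per subtype, several candidate weight sets
   (clumping+thresholding at a ladder of p-value cut-offs by default;
   externally produced weight files are accepted with a method tag) are
   scored on a CVD-record-free population whose cases are
   self-reported-only disease histories; the candidate with the highest
   AUC wins (ties broken by candidate order).
2. **Five-fold combination.** On the T2D cohort, a seeded fold assignment
   stratified on the event indicator guarantees events in every fold. For
   each fold the components are standardized on the 4/5 training split,
   one *joint* Cox model of the three standardized components yields `b`,
   and `r` is computed on the same split. The stored model keeps the
   per-fold values; `b`, `r`, the standardization constants and `D` are
   their across-fold means.

The source description is ambiguous between a joint fit and three marginal
fits for `b`. The joint fit is the default because `D` is then exactly
the SD of the joint linear predictor; a marginal mode is available
(`MetaPRSModel(..., mode="marginal")`).

## Cohort ascertainment

Disease onsets come from coded episode records (ICD9/ICD10 diagnoses,
OPCS4 procedures): the onset of a disease is the earliest episode whose
code matches a configured prefix (matching is dot-stripped and
case-insensitive); composite CVD onset is the earliest across CAD/IS/HF.
Follow-up starts at T2D onset; a CVD event counts only if at least one
day later (incident-case rule); persons with CVD on or before T2D onset
are prevalent cases and excluded; censoring is at the earliest of death
and the administrative date (default 2021-02-05). Death on or before T2D
onset is treated as corrupt input and raises rather than being silently
dropped. A minimum-follow-up filter (`min_follow_up_days`, default 1)
reproduces the "longer than 30 days" sensitivity analysis at 31. The
shipped code lists are configuration defaults, not a transcription of any
registry's official list.

## Survival kernels

* **Cox model** — Newton–Raphson on the Breslow partial likelihood
  (covariates standardized internally; convergence when the
  information-scaled step is below 1e-8 in max-norm, at most 50
  iterations; step halving on non-improvement). Standard errors come from
  the inverse observed information; CIs are Wald on the log scale. Ties
  are handled by Breslow only — with day-resolution times ties are common
  and Breslow is the simplest defensible choice; Efron is not
  implemented. A coefficient passing 15 on the standardized scale (or a
  vanishing information with a large coefficient) raises a separation
  error naming the covariate; constant covariates are rejected up front.
* **Collinear fallback** — when the component correlation matrix has
  condition number above 1e6, the information matrix is solved by
  spectral truncation (pseudo-inverse, relative cut-off 1e-9) rather than
  a plain solve. An absolute ridge of 1e-8 cannot damp the noise
  amplification that machine-precision collinearity produces in the null
  direction; truncation yields the minimum-norm Newton step, which leaves
  the fitted meta score invariant (the collinear-limit test asserts the
  meta score equals the common standardized component).
* **AUC** — Mann–Whitney with ties counted one half; the 95% CI uses
  DeLong's variance from the structural components of the U-statistic
  (the source analysis does not name its CI method; a seeded bootstrap is
  available). AUCs for survival data are computed on the binary event
  indicator over full follow-up — the analysis reports single AUCs, not
  time-dependent ones; this is a documented limitation, not an oversight.
* **Kaplan–Meier** — lifelines' product-limit estimator.
* **Quantile incidence** — equal-size score bins (stable-order ties),
  cumulative events / bin size, top/bottom fold ratio (infinite when the
  bottom bin has no events). Incidence is cumulative over follow-up, not
  per person-year (person-year rates were considered and rejected to
  match the baseline-table convention).

## Evaluation

All headline numbers are arithmetic means of the per-fold values computed
on the five held-out test folds (HRs averaged on the HR scale, CI bounds
bound-wise); per-fold arrays are stored so the invariant is assertable.
Association models are adjusted for age at T2D onset, sex and ten genetic
principal components. "PRS + baseline" AUCs score the linear predictor of
a Cox model refit on the training fold with the score plus those
covariates. The clinical risk model uses age at onset, sex, BMI, smoking,
hypertension, TC, LDL-C, HDL-C, TG, lipid-lowering medication and glucose
— the overlap of the classic CVD risk equations' variable lists with what
a T2D biobank cohort records, plus glycemia. Calibration converts the
fitted Cox model to absolute risk `1 - exp(-H0(t*) e^lp)` with the
Breslow baseline at the median follow-up (capped at the last event time
with a warning) and reports a logistic recalibration slope.

The onset-age stratification splits at 55 years and defines high-risk
groups as the top 20% of each score on the full cohort (the top-20%
definition is used for the risk-group proportions, the top/bottom decile
for the incidence contrast — both appear in the source analysis and both
are configurable). The absolute risk reduction (ARR) is reported as the
absolute early-late incidence difference within the high-PRS group and
within the remainder, plus their ratio; the sign convention is not stated
in the source, so the absolute value is used.

## The synthetic study generator

The generator's defaults describe a single stated world, fixed once:

| quantity | default | basis |
| --- | --- | --- |
| cohort size | 21,092 | published T2D cohort size |
| variants | 2,000 | desk-scale stand-in for ~3M (configurable) |
| liability h² (CAD, IS, HF) | 0.50, 0.28, 0.30 | midpoints of the reported heritability ranges |
| genetic correlations | 0.5–0.6 | "strong genetic correlation" among subtypes |
| GWAS sizes | 550k, 520k, 977k | the cited subtype GWAS scales |
| T2D onset age | N(60, 8) truncated to [30, 80] | 17% of the cohort has onset ≤ 55 |
| genetic log-HR per SD | log 1.3 | the recovery target the acceptance criteria name |
| clinical hazard effects | baseline-table HRs (sex 1.53, hypertension 1.37, smoking 1.27, BMI 1.02/unit, glucose 1.03, lipid-med 1.24, age 1.04/yr) | the internally coherent rows of the published baseline table |
| baseline hazard | 0.0055 /person-year per subtype | yields ~19% cumulative CVD incidence, matching 4,015/21,092 |
| death rate | 0.015 /person-year | plausible T2D cohort mortality |
| censor date | 2021-02-05 | the administrative extract date |
| birth dates | uniform 1935–1960 | places onsets inside the 1994–2021 episode window |
| self-report-only fraction | 0.15 | emulates interview-only disease histories for stage-1 labels |

Variants are independent biallelic loci, dosages Binomial(2, EAF) with
EAF ~ Uniform(maf range); an optional block mode (blocks of size B with
pairwise correlation r via a shared latent haplotype indicator) exists
solely to exercise clumping. True effects are drawn per variant from a
trivariate normal with the genetic correlation matrix and rescaled so
each subtype's polygenic liability variance equals h² exactly; observed
GWAS betas add noise with the standard `1/(2 N p (1-p))` sampling
variance (no case-control ascertainment modelling — sufficient for the
rank/selection behaviour the pipeline needs). Principal components are
standard-normal noise columns: the analysis only uses them as adjustment
covariates. Event times are exponential proportional-hazards given the
standardized genetic score (optionally with an extra
`genetic_onset_interaction` log-HR per decade of onset age below 55) and
centered clinical covariates; each diagnosis is emitted as a coded
episode; records dated after the censor date or after death are not
emitted, since an administrative extract cannot contain them. Two
published lipid rows are clinically transposed in the source's baseline
table (HDL 3.93 / LDL 1.21 mmol/L); the generator uses the coherent
assignment (HDL 1.21, LDL 3.93), and the lipid-fraction hazard effects
are zero because the published HR/p values for them are internally
inconsistent.

What the generator does *not* emulate: realistic LD maps, ascertainment
bias, relatedness, genotyping error, population structure, competing-risk
dependence between death and CVD, or primary-care/cancer-registry
sources. A green end-to-end test therefore establishes that the pipeline
recovers the structure it assumes — not that it would be well-calibrated
on real biobank data.

## The parameter-recovery world

The recovery criterion ("cross-validated HR per SD covers 1.3") fixes
only the scale (n = 20,000, m = 2,000) and the target. The configuration
is the identifiable case, chosen a priori:

* genetic correlations all 1 and equal h², so the three subtype
  liabilities coincide and the combined-CVD hazard (the minimum of three
  exponential subtype times) is itself proportional-hazards in the single
  genetic score with HR exactly 1.3 per SD — with distinct liabilities the
  "true" combined HR is not 1.3 and the criterion would be ill-posed;
* clinical hazard effects zero — omitting independent prognostic
  covariates from the adjusted Cox model attenuates the marginal HR
  (non-collapsibility), and the criterion would measure that artefact
  rather than recovery;
* components scored with the generator's true effect sizes — noisy GWAS
  weights attenuate the coefficient by the weight-score correlation.

This world also exercises the collinear fallback path, since the three
component scores are numerically identical. Coverage is assessed with the
report's averaged fold CI (20 seeded replicates, ≥17 must cover), which
is conservative because the averaged estimator has smaller variance than
a single fold.

The qualitative-reproduction world uses the full defaults plus a
genetic-by-onset-age interaction of 0.158 per decade younger, derived
from the published stratified HRs (1.51 at mean early-onset age ~50 vs
1.23 at ~63) before any test was run.

## Known limitations

* Breslow ties only; heavy ties bias HRs slightly toward the null (the
  recovery replicates show ~1% attenuation at day resolution).
* AUCs ignore censoring time (binary event indicator); no time-dependent
  ROC, competing risks, or net-reclassification measures.
* Stage-1 self-report labels are a simulation device; with
  `self_report_frac > 0` a fraction of true events is invisible to the
  main cohort, mimicking (and sharing the biases of) record-based
  ascertainment.
* Follow-up may begin before enrollment-style dates; immortal-time
  concerns are reproduced as-is from the source design.
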
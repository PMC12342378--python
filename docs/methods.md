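# Methods

`mrpscene` implements the statistical pipeline of a developmental
massive-report-paradigm (MRP) study of brief natural-scene perception, plus
a generative model of the behavioural data it consumes. This note documents
the models, the defaults and the numerical choices, and what the synthetic
generator does and does not emulate.

## Response encoding and exclusions

Each probe response is one of four options, encoded as a signed
decision-x-confidence value D x C in {+3, +1, -1, -3} ("absolutely present"
... "absolutely absent"). Participants pass through three sequential
filters: practice accuracy (fewer than 5 correct practice probes excludes),
session completeness (all 30 trials required), and catch-question accuracy
(performance *below* 70% excludes — a rate of exactly 70% is retained, the
literal reading of the criterion). Each excluded participant is counted
under the first criterion failed, in that order, which makes the exclusion
report's columns additive the way recruitment tables are usually printed.
A participant with zero catch questions has an undefined catch rate; we
exclude them under the catch criterion with an explicit flag rather than
guessing a rate. The practice denominator varies by session (practice
trials mixed probe types), so the filter takes an already-computed
`practice_correct` count with a parameterized threshold (default 5).

## Type 1 and Type 2 AUC

Type 1 (objective discrimination) treats original and present probes as
signal and absent probes as noise; modified probes enter neither class.
Hit and false-alarm proportions are accumulated at the three D x C criteria
(>= +3, >= +1, >= -1) and the AUC is the trapezoidal area over the polyline
anchored at (0,0) and (1,1). The trapezoid is the standard nonparametric
estimator and equals the tie-corrected concordance probability
P(dxc_signal > dxc_noise) + 0.5 P(tie); the test suite verifies this
identity exactly on random response multisets. Parametric d'/meta-d' are
deliberately not offered: they are inappropriate for the strongly
asymmetric ROC curves rating data of this kind produce.

Type 2 (metacognitive accuracy) conditions confidence on correctness:
h2 = P(|dxc| = 3 | correct), f2 = P(|dxc| = 3 | incorrect), and the
single-criterion area is (1 + h2 - f2)/2. Modified probes are excluded by
default symmetrically with Type 1; `include_modified=True` scores them with
"absent" as the accurate report. Participants with no correct or no
incorrect responses get an undefined marker and are dropped from slope fits
with a logged count.

Age groups (5–6, 7–9, 10–12, adult) are coded 0..3 in recruitment order;
the age effect is the OLS slope of per-participant AUC on that code, in AUC
units per age-group step. This coding makes the study's stated group-mean
models correspond to slopes of exactly one mean-step per group.

## Simulation-based Bayes factor

The hypothesis test compares two fixed generative models of AUC: an
age-effect model and a no-age-effect model, each giving four group means
with a common SD of 0.1. The preset age-effect models are
0.800/0.833/0.867/0.900 (slope 0.033, group sizes 25/35/30/32),
0.791/0.824/0.857/0.891 (slope 0.033) and 0.716/0.741/0.765/0.790
(slope 0.025), the latter two at the registered minimum of 35 per group
(realized sizes 45/59/52/49 are an alternative preset). The no-age-effect
counterpart of each model places all groups at its adult mean, following
the explicit construction of the first experiment's null model.

Each model is simulated R = 10,000 times; a replicate draws n_g values per
group from Normal(mu_g, 0.1) and fits the OLS age slope. Draws are *not*
clipped to [0, 1]: plain normal sampling is the stated model, and clipping
would bias the slope distribution (a `clip_unit` helper exists for
sensitivity checks). The observed slope's likelihood under each model uses,
by default, a normal density with the simulated distribution's moments —
exact up to Monte-Carlo error, because the OLS slope of group-wise normal
data is itself normal with mean sum(w_i mu_i) and SD sigma sqrt(sum w_i^2),
w_i = (g_i - gbar)/Sxx. A Gaussian-KDE likelihood is available as a
robustness check; with R = 10,000 the two agree within a few percent at the
mode. BF10 is the likelihood ratio; BF10 > 10 supports the age-effect
model, BF10 < 1/10 the null, anything else is inconclusive.

Reduction of "the data" to the scalar OLS slope is a design choice: the
slope is the only quantity the simulation distributes, so it is the
statistic whose likelihood is well defined under both models.

Seeding: one master seed; each model's simulation uses an independently
derived stream, and draws fill row-major so growing R extends a sample
without perturbing earlier replicates.

## Congruence statistics

For each image pair, `delta_dxc` is the mean D x C of the original probe
minus the mean D x C of the modified probe, separately per congruency
condition of the initial image; `ddxc` is the congruent minus the
incongruent `delta_dxc` (positive = better original/modified discrimination
under a congruent scene). Participant-level `delta_dxc` values feed the
per-image one-sample t-tests and the two-way (age x condition)
between-subjects ANOVA; cell means feed the `ddxc` table. The ANOVA is the
classical pooled-variance two-way fit with cell sizes logged; interaction
p-values are corrected across images by Bonferroni, Benjamini–Hochberg and
Holm. Cells with fewer than two participants are marked undefined, never
silently dropped into pooled statistics.

Covariate correlations are plain Pearson r of per-image `delta_dxc` against
a per-image covariate (log object size, knowledge rating) within each age
group x condition; undefined below 3 images or at zero variance.

The hierarchical comparison for an age-by-image interaction fits
`ddxc ~ age + (age | image)` against `ddxc ~ age + (1 | image)` as
maximum-likelihood linear mixed models (age numeric 0..3) and compares
BIC-based Laplace approximations to the log marginal likelihood,
`log p(y|M) ~= llf - (k/2) log n`. This is an approximation: the reference
procedure for such comparisons is MCMC plus bridge sampling, and every
`ModelComparison` report carries that caveat. The optimizer falls back from
L-BFGS to Powell to Nelder–Mead; a fit that never converges is flagged,
never silently replaced.

## Synthetic cohort generator

The generator emulates the statistical structure of an MRP session under
equal-variance Gaussian signal detection:

* **Design.** 30 trials x 6 scored probes (1 original, 1 modified,
  1 present, 3 absent) in random order; per trial all locations come from
  one of the two location sets {1,3,5,7,9} / {2,4,6,8}; original and
  modified probes share the critical-object location; the 90 absent patches
  per session are drawn without replacement from a 7,044-patch pool; half
  the initial images are congruent; catch questions (chance 1/4) are
  appended to 8–12 random trials.
* **Evidence.** x ~ Normal(mu, 1) with mu = 0 (absent), d' (original and
  present, plus `beta_size` times the centred log object size when image
  covariates are supplied), and d_modified shifted by -/+ kappa_cong/2
  under a congruent/incongruent initial image (default d_modified = d'/2, a
  partial content match). The decision compares x with criterion c (default
  unbiased, d'/2); confidence compares x plus independent Normal(0,
  sigma_meta) noise with c -/+ 0.8. The two-stage read-out (default
  sigma_meta = 0.6) lets Type 1 and Type 2 accuracy vary separately, which
  a one-stage model cannot do; per-age-group overrides of any generator
  field are supported for patterns like an age effect on discrimination
  without one on metacognition.
* **Calibration.** The population trapezoid Type 1 AUC of this observer has
  a closed form via bivariate-normal orthant probabilities; `calibrate_dprime`
  root-finds d' for a target AUC (tolerance 1e-3), and cohorts use a cached
  monotone interpolation of the same map. In the sigma_meta = 0 limit the
  continuous-ROC identity AUC = Phi(d'/sqrt(2)) bounds the calibrated d'
  from below, since the three-point trapezoid under-covers the smooth curve.
* **Cohorts.** Per participant a latent Type 1 AUC is drawn Normal(mu_g,
  0.1), censored to [0.5005, 0.9995] (an AUC of 1 is unattainable for a
  finite observer), inverted to d', and a full session is simulated.
  Censoring compresses near-ceiling group means by up to ~0.007;
  `censored_group_mean` gives the closed form of the mean the generator
  actually realizes, which is the correct oracle for end-to-end parameter
  recovery. Exclusion profiles append participants engineered to fail
  practice (summary counts only — practice-probe composition is not modelled
  probe-by-probe), completeness (truncated sessions) or the catch filter;
  retained participants' catch scores are floored at the 70% threshold so a
  profile-built cohort reproduces its recruitment table exactly rather than
  stochastically.

What the generator does **not** emulate: real image content and its
item-level difficulty structure, probe-order effects within a trial,
response times (a lognormal placeholder column only), practice-trial
dynamics, or any dependence between knowledge ratings and responses.
Passing tests therefore certify the pipeline's statistical machinery on
data satisfying the stated generative assumptions, not conclusions about
any real cohort.

## Problem sizes and numerical choices

Slope simulations default to R = 10,000 replicates. The replicate-cohort
decision studies in the test suite use 100 cohorts of 4 x 35 participants
per condition, where the analytic power of the BF > 10 decision at the
age-effect model is ~0.9. The null-congruence screen is calibrated on a
205-participant cohort (45/59/52/49). Tolerances: calibration 1e-3 in AUC;
AUC identity checks exact to 1e-12; statistical checks use 2–4
standard-error bands computed from the data or closed forms, plus the
two-decimal precision of printed model slopes where those are the
reference. Ties in D x C cumulative counts need no special handling beyond
the concordance-equivalent trapezoid; degenerate inputs (empty response
classes, single age groups, one-condition images, zero catch questions)
return explicit undefined markers or raise typed errors.
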
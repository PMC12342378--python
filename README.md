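# mrpscene

Analysis toolkit for **massive-report-paradigm (MRP)** studies of brief
natural-scene perception across development. In this paradigm a natural
scene is flashed for one or two hundred milliseconds, after which the
participant judges, patch by patch, whether small image fragments were part
of the scene, reporting presence or absence with two confidence levels.
Probes include the scene's actual content ("original", "present" patches),
a subtly altered version of the critical object ("modified"), and patches
from other scenes ("absent"). The package is aimed at researchers analysing
such confidence-rating data — or planning studies with simulated versions
of it — across age groups from preschool to adulthood.

## What it computes

Responses are encoded as a signed **decision x confidence** value,
D x C in {+3, +1, -1, -3}. From these the package derives, per participant:

* **Type 1 AUC** — objective discrimination. Cumulative hit / false-alarm
  proportions of signal (original + present) versus noise (absent) probes
  at the criteria D x C >= +3, >= +1, >= -1 give a three-point ROC; its
  trapezoidal area equals the tie-corrected concordance probability
  P(dxc_s > dxc_n) + 0.5 P(tie).
* **Type 2 AUC** — metacognitive accuracy. With h2 = P(|D x C| = 3 |
  correct) and f2 = P(|D x C| = 3 | incorrect), the area is
  (1 + h2 - f2) / 2.

Age effects are tested by a **simulation-based Bayes factor**: the observed
OLS slope of AUC on age-group index (0..3) is compared between an
age-effect model and a no-age-effect model of group means (common SD 0.1),
each simulated 10,000 times; BF10 > 10 supports an age effect, < 1/10 its
absence. Congruence effects are quantified per image pair by
ΔD×C = mean D×C(original) − mean D×C(modified) and
ΔΔD×C = ΔD×C(congruent) − ΔD×C(incongruent), with per-image t-test/ANOVA
screens (Bonferroni/BH/Holm corrected), covariate correlations, and an
approximate hierarchical model comparison for age-by-image interactions.

A synthetic-cohort generator built on equal-variance Gaussian signal
detection produces full sessions (probe schedules, graded responses, catch
questions, participant exclusion profiles) so every stage of the pipeline
can be exercised and power-checked without behavioural data. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from mrpscene import (GroupModelSpec, simulate_cohort, apply_exclusions,
                      cohort_auc_table, fit_age_slope, bayes_factor)
from mrpscene import presets

cohort = simulate_cohort(presets.EXP2_H1_MEANS, sd=0.1,
                         ns=presets.EXP2_REALIZED_NS, seed=7,
                         exclusion_profile=presets.EXP2_EXCLUSION_PROFILE)
retained, report = apply_exclusions(cohort)
print(f"recruited {report.n_total}, retained {report.n_final}")

table = cohort_auc_table(retained, "type1")
print(table.groupby("age_group", sort=False)["auc"].mean().round(3))

fit = fit_age_slope(table)
spec_alt = GroupModelSpec(presets.EXP2_H1_MEANS, 0.1, presets.EXP2_PLANNED_NS)
spec_null = GroupModelSpec(presets.EXP2_H1_NULL_MEANS, 0.1,
                           presets.EXP2_PLANNED_NS, label="null")
result = bayes_factor(fit.slope, spec_alt, spec_null, R=10_000, seed=7)
print(f"slope {fit.slope:.4f}, BF10 {result.bf10:.1f} -> {result.decision}")
```

Output:

```
recruited 292, retained 205
age_group
5-6      0.746
7-9      0.809
10-12    0.835
adult    0.867
Name: auc, dtype: float64
slope 0.0384, BF10 350644.9 -> support_age
```

292 simulated participants are recruited with the study's exclusion
profile; the three filters (practice, completeness, catch) remove 87,
leaving 205. Group-mean Type 1 AUC rises from 0.75 in 5–6-year-olds to
0.87 in adults; the fitted age slope of 0.038 AUC per age-group step is
vastly more likely under the age-effect model than under the null
(BF10 ≈ 3.5 × 10^5, far beyond the cutoff of 10), so the test supports a
developmental effect — as it should, since the cohort was generated from
the age-effect model.

The same stages are scriptable from the shell:

```
mrpscene simulate --preset exp2 --seed 7 --out cohort_out
mrpscene run --preset exp2 --seed 7 --out run_out
```

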
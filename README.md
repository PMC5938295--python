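# chplanimetry

Capitohamate (CH) planimetry is a quantitative method for paediatric
bone-age assessment (BAA): on a posterior-anterior hand radiograph, the
projected areas of the capitate and the hamate — the two carpal bones
that ossify first — are measured by drawing regions of interest, and
their sum (the *CH area*, mm²) serves as a maturity index. Because the
CH area grows nearly linearly with chronological age through childhood,
a sex-specific linear model

```
area = a + b · age        (age in months, area in mm²)
```

can be fitted per hand and bone, and bone age estimated by inverting it:
`age = (area − a) / b`. The approach is an objective alternative to
atlas-matching methods such as Greulich-Pyle (GP), whose subjectivity
limits inter-observer reproducibility.

This package implements the full analysis pipeline for radiologists and
medical-imaging researchers who want to apply or validate the method:

- **planimetry engine** — shoelace polygon areas from ROI vertex lists,
  mm-per-pixel calibration from a coin fiducial, the CH score, and the
  two-reviewer consensus rule (differences >10 % of the pair mean
  trigger re-measurement; smaller ones are averaged);
- **growth models** — `BoneAgeLinearModel`, a scikit-learn-style
  estimator (`fit`/`predict`, fitted attributes, HC1-robust coefficient
  CIs) with bone-age inversion, plus Pearson r with Fisher-z CIs, the
  z-test for comparing correlations, and the weak/moderate/strong
  categorisation;
- **reference standard** — cohort inclusion filters and selection of
  the 50th-percentile subgroup (children whose height brackets the
  growth-chart median for their age: ±1 month under 3 years, ±6 months
  above), whose chronological age stands in for skeletal age;
- **agreement suite** — accuracy and precision percentages, paired t,
  Bland-Altman 95 % limits of agreement (LOA), Lin's concordance
  correlation coefficient, and Deming regression with jackknife SEs;
- **synthetic cohort generator** — seeded simulation of subjects,
  latent bone areas, two reviewers and a GP-like noisy rater with the
  statistical structure of a real paediatric emergency cohort, so the
  entire pipeline is testable without patient data.

## Worked example

```python
import chplanimetry as ch

cfg = ch.PipelineConfig(simulation=ch.SimulationConfig(seed=7, n_subjects=391))
out = ch.run_pipeline(cfg, "ch_demo")   # simulate → measure → fit → estimate → agree → report
print((out / "report.md").read_text())
```

or, equivalently, from the shell: `chplanimetry run --seed 7 --out ch_demo`
(the simulation size then defaults to the same 391-subject cohort).

The fitted left-hand CH models for this seed (from `models.json`):

```
male   CH: a=-12.8697 b=3.0629 r=0.9700 n=185
female CH: a= -5.7376 b=2.5263 r=0.9721 n=122
```

— close to the generating coefficients (male a=−13.89, b=3.0571;
female a=−10.29, b=2.5855), with the strong age-area correlation the
method relies on. The agreement report on the 159-child
50th-percentile subgroup reads (abridged):

```
## CH_planimetry
- precision: 2.15 % ± 1.72 %
- Bland-Altman: mean diff 0.15 months, 95 % LOA -4.4 to 4.7 months
- Lin's rho_c: 0.9988 (almost perfect)

## GP_method
- precision: 30.37 % ± 41.80 %
- Bland-Altman: mean diff 0.10 months, 95 % LOA -25.9 to 26.1 months
- Lin's rho_c: 0.9584 (substantial)

- Deming GP_on_CH[R1|GP1]: slope 0.9694 (SE 0.0418), intercept -3.5681 (SE 2.3237)
- paired t CH_planimetry_vs_chronological[R1]: t = 0.165, df = 158, p = 0.8694
- paired t GP_method_vs_chronological[GP1]:   t = -7.619, df = 158, p = 0.0000
```

Read: the two planimetry reviewers agree far more tightly than the two
GP-like raters (narrower LOA, smaller precision percentage, higher
concordance); the Deming line between methods is compatible with the
identity (slope CI covers 1, intercept CI covers 0); CH bone ages are
statistically indistinguishable from chronological age while the
GP-like rater is biased low — the qualitative pattern expected when a
calibrated quantitative measurement is compared against a noisier
subjective one.

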
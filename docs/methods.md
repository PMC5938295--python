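# Methods

## The measurement model

A region of interest (ROI) around a carpal bone is an ordered, simple
polygon in continuous pixel coordinates, implicitly closed. Its area is
the absolute shoelace sum, computed after centring the vertices to limit
cancellation error; validity (≥3 vertices, no repeated consecutive
vertices, non-self-intersection) is checked with shapely before any
area is computed. Physical calibration follows the standard fiducial
procedure: an object of known diameter (default a 26.51 mm coin) imaged
under the same source-to-detector geometry yields the scale
`mm/px = true_diameter / measured_diameter_px`, and areas transform by
the square of the scale. When the fiducial's diameter is also read off
the workstation in mm, the relative error `100·|measured − true|/true`
(reported to 2 decimals) quantifies the chain's accuracy.

The CH score for one hand is the exact sum of the capitate and hamate
areas. Two independent reviewers measure every ROI; a pair differing by
more than 10 % of the pair mean is flagged for consensus
re-measurement, otherwise the mean is reported. Design choices the
protocol leaves open: the 10 % denominator is the two-reviewer mean
(symmetric), exactly 10 % counts as negligible, and a consensus
replaces the discordant pair (replacement of only one value is
available behind the same interface). In the simulated pipeline —
where reviewer errors are unbiased by construction — the consensus
re-measurement is emulated by the pair mean, with the discordance count
carried through to the outputs.

## Growth models and bone-age inversion

Per sex, hand, and target (capitate, hamate, CH) the model is ordinary
least squares of area on age in months. The fitted object exposes
intercept (mm²), slope (mm²/month), residual SD (n−2 denominator),
Pearson r with a 95 % Fisher-z interval, and both classical and HC1
(sandwich) coefficient standard errors. The robust SEs are the default
for coefficient confidence intervals because area variability grows
with bone size, so the errors are heteroscedastic by nature and the
classical OLS intervals under-cover (we measured 12–22 misses per 100
simulated cohorts for the slope at n≈3000, versus 3–6 with HC1). Point
estimates are plain OLS throughout.

Bone age is the model inverse `(area − a)/b`, clamped to [0, 216]
months with an explicit flag; the left-hand model is the default (BAA
convention). By linearity of least squares, the CH fit equals the sum
of the per-bone fits coefficient-by-coefficient; the package always
derives CH coefficients from data rather than summing published
per-bone values, because published roundings need not be additive (the
bundled male reference equations indeed have an intercept mismatch of
0.55 mm², while their slopes are additive to the printed precision).

Correlation utilities: Fisher-z CIs (`tanh(atanh r ± 1.96/√(n−3))`),
the independent-samples z-test for two correlations, and the
conventional categorisation (≤0.3 weak, ≤0.7 moderate, >0.7 strong).
The z-test treats the two samples as independent; for left-vs-right
correlations measured on the same children this ignores the pairing and
is therefore conservative in neither direction — a dependent-correlation
test would be more appropriate and is deliberately out of scope, as the
method validated here reports the independent form.

## Reference standard

Since no gold standard for skeletal age exists, validation uses
children whose stature tracks the growth-chart median: a child of age
*a* qualifies if their height lies between the median height at *a−Δ*
and *a+Δ* (Δ = 1 month under 36 months, 6 months at or above; bounds
inclusive; window edges clamped at the chart domain). Their
chronological age is then used as the bone-age ground truth. The
shipped chart is synthetic — a strictly increasing
exponential-saturation-plus-linear median curve per sex spanning 1–216
months with adult heights near 169/160 cm — and is a stand-in for a
national reference chart, which can be supplied as a CSV with the same
interface. Inclusion filters (both hands radiographed, age 1–180
months, no excluded diagnosis, majority ethnicity) run before
selection and log every exclusion with its reason in input order.

## Agreement statistics

* **Accuracy** per subject: `100·(1 − |BA − CA|/CA)` against
  chronological age — 100 at perfect agreement, unbounded below. This
  form was chosen among the "difference percentage" readings because it
  equals 100 at perfect agreement and yields values in the mid-80s
  (percent) under realistic rater noise.
* **Precision** per subject: `100·|a − b| / mean(a, b)` between two
  reviewers; pairs with zero mean are excluded with a warning. Note the
  percentage is sensitive to the age composition of the subgroup: the
  same absolute disagreement in months is a much larger percentage in a
  young child, so precision values are only comparable across methods
  on the same subjects.
* **Paired t**: `t = mean(d)/(sd(d)/√n)`, df = n−1, two-sided p.
* **Bland-Altman**: mean difference and `mean ± 1.96·sd` (sample SD)
  limits of agreement; no small-sample t correction, matching standard
  practice.
* **Lin's ρ_c**: `2 s_ab / (s_a² + s_b² + (ā − b̄)²)` with population
  (n-denominator) moments — the original definition; sample-moment
  variants differ at small n. Categories: <0.90 poor, ≤0.95 moderate,
  ≤0.99 substantial, >0.99 almost perfect.
* **Deming regression**: errors-in-variables slope
  `[s_yy − λ s_xx + √((s_yy − λ s_xx)² + 4 λ s_xy²)]/(2 s_xy)` with the
  error-variance ratio λ defaulting to 1 (both axes are bone ages in
  months with comparable error); standard errors by leave-one-out
  jackknife, CIs as estimate ± 1.96 SE. As λ → ∞ the fit approaches OLS
  of y on x.
* No multiple-testing correction is applied anywhere; all p-values are
  raw, and reports say so by construction (every contrast is listed).

## The synthetic cohort generator

The generator emulates the study conditions the pipeline is meant for:

* **Cohort structure** — 391 subjects by default, 62 % male, ages drawn
  from 12-month bins (1–180 months) with weights matching a paediatric
  emergency series heavily skewed toward infancy; ages uniform within a
  bin. Heights are the synthetic chart median plus N(0, 3 cm) noise.
* **Latent areas** — per bone, mean `max(a + b·age, 0.5 mm²)` using the
  bundled left-hand reference coefficients; the floor reflects that the
  printed line undershoots in early infancy (its negative values there
  are an extrapolation artifact) while an ossified nucleus always has a
  small positive projected area. Noise is proportional:
  SD = `floor + cv·mean` with defaults floor = 0, cv = 0.20. The cv was
  derived analytically from the calibration requirement that the
  cohort-wide age-CH correlation land near the 0.96–0.97 reported for
  this method, and verified by simulation (r = 0.969–0.979 over 100
  seeds, both sexes). Proportional noise also keeps the positivity
  constraint from ever binding, so OLS parameter recovery is unbiased —
  an additive heteroscedastic SD large enough to hit the same r would
  truncate the area distribution at young ages and bias fitted slopes
  by more than one standard error at n = 5000.
* **Left/right** — bivariate Normal with correlation 0.95 and equal
  means (no systematic left-right difference), so paired left-right
  contrasts are non-degenerate. The value is a stand-in; no published
  estimate exists.
* **Ossification** — onset per (subject, hand, bone) uniform on
  0–3 months (capitate) and 0.5–3.5 months (hamate); a bone is absent
  below its onset. Under the default age distribution this reproduces a
  sub-1 % cohort absence rate concentrated in the first month of life.
* **Reviewers** — multiplicative error `(1 + δ)`, δ ~ N(0, cv) with
  cv = 3 % per reviewer (a stand-in; area errors scale with bone size),
  independent across reviewers and ROIs; non-positive draws resampled.
* **GP-like rater** — estimate = age + bias + N(0, SD), truncated at 0
  with a flag; defaults bias = −5.6 months, SD = 9.1 months, derived
  from the reported inter-rater limits of agreement (width/3.92/√2) and
  mean underestimation of the atlas method. Two raters draw
  independently, giving inter-rater LOA ≈ ±25 months.
* **Determinism** — every stage derives its own substream from the
  single config seed (CRC-based stage hashing), so identical configs
  give byte-identical outputs and stages can be re-run in isolation.

What the generator does *not* emulate: radiographic texture or anatomy
(fixture images are convex blobs plus a circular fiducial, with the
exact boundary polygons returned as ground truth), reviewer bias or
drift, age-dependent rater difficulty, and real national growth-chart
values. Consequently, passing tests demonstrate the correctness and
calibration of the computational pipeline — not the clinical validity
of the method on real radiographs.

Because the synthetic 50th-percentile subgroup inherits the cohort's
young age skew (the study's real subgroup averaged ~9.4 years),
percentage-based precision and accuracy values are not comparable to
the published point values; the pipeline's validation claims are the
qualitative orderings (CH narrower LOA and smaller precision percentage
than GP) and the parameter-recovery coverage, which are what the
acceptance checks assert.

## Numerical and policy details

* Areas are carried at full precision internally and written to 2
  decimals; the pipeline re-reads what it writes so in-memory and
  from-file runs agree exactly. Truth areas below 0.5 mm² are treated
  as invisible (absent).
* Polygon area is computed after mean-centring; reversal/rotation/
  translation invariance is tested to 1e-9.
* Inverted bone ages clamp to [0, 216] months with a flag.
* Degenerate inputs raise rather than return NaN: constant age vectors,
  |r| = 1 CIs (returned as the point with a warning), zero difference
  variance in the paired t, both-constant vectors in ρ_c, zero
  covariance in Deming.
* Problem sizes in the shipped checks — cohorts of 5000 for
  correlation/recovery (100 seeds) and 391 for the agreement
  comparison (100 seeds) — were chosen so the full suite completes in
  well under a minute each while leaving Monte-Carlo margins far from
  the asserted thresholds.
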
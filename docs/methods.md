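# Methods

## Scope and data model

The package analyses subject-level survey data on low back pain (LBP)
and psychological distress: demographics (age, sex, body mass, height,
BMI), two binary diagnosis flags (medically diagnosed mental illness;
lumbar pathology), a 6-week LBP episode count, and item-level responses
to three instruments — ODI, DASS-21 and PCS-D. The unit of analysis is
one respondent; cohorts travel as plain CSV with one row per subject
and item blocks expanded to columns (`odi_q1..10`, `dass_q1..21`,
`pcs_q1..14`; a blank ODI cell is a skipped item).

## Instrument scoring

* **ODI**: percentage `100·Σanswered/(5·n_answered)`; skipped items
  reduce the denominator, at least one answered item is required.
  Severity bands on the percentage: ≤20 minimal, ≤40 moderate, ≤60
  severe, ≤80 disabled, ≤100 bedridden. Bands are integer interval
  tables applied with an upper-bound rule (first band whose upper bound
  is ≥ the score), which also gives fractional percentages a unique
  band.
* **DASS-21**: three 7-item subscales (standard DASS-21 item
  partition), each scored as twice the item sum so scores live on the
  42-point scale of the long form. Cut points per subscale on the
  doubled scale; the severe depression band is 21–27. DASS and PCS
  responses must be complete — only the ODI formula defines behaviour
  under missingness.
* **PCS-D**: plain item sum, 0–56.

## Synthetic cohort generator

Raw cohorts of this kind are rarely shareable, so the generator is part
of the package proper, not a test fixture. It emulates a young-adult
online-survey cohort: n = 1021, 73% female, ages 18–35 (mean 24.68),
height mean 167.9 cm, mass mean 65.8 kg. Dispersions are set to
realistic values (age SD 4 y, height SD 8 cm, mass SD 12 kg) because
survey reports often quote standard errors where SDs are meant; the
anchor means are used as printed.

Each subject carries a distress latent `D ~ N(0,1)` and a physical
latent `V = ρD + √(1−ρ²)ε` (default ρ = 0.6). Observables:

* **Items** via a graded-threshold model: an item equals the number of
  ascending thresholds exceeded by `latent + N(0, σ_item)` (σ_item = 1).
  DASS and PCS items load on `D`, ODI items on `(V+D)/2`. Threshold
  tables per scale were calibrated once so the default cohort's medians
  sit where young-adult LBP surveys put them (ODI ≈ 8–10%, doubled
  stress ≈ 10, anxiety ≈ 6, depression ≈ 8, PCS-D ≈ 1–2) and were not
  revisited afterwards.
* **Counts**: 6-week LBP episodes are negative binomial with
  `log μ = 1.386 + 0.35·V` and dispersion 2 — overdispersed, matching
  the skewed IQRs such counts show.
* **Diagnoses**: Bernoulli with logistic models, lumbar pathology on
  `V`, mental illness on `D` (intercepts −1.5/−1.8, slopes 0.9).
* **Observation noise**: continuous measurements get N(0, 0.05·SD)
  noise (σ_obs = 0.05 in standardized units); BMI is computed from the
  noisy mass and height so it stays internally consistent.

A fraction π = 0.25 of subjects is **anomalous**: their latents are
shifted by δ = +1 SD and, with decoupling on, each questionnaire block
is generated from its own fresh independent latent (centred at the
shifted severity) with 1.5× item noise. Anomalous subjects are thus
severe *and* internally inconsistent — high stress need not come with
high catastrophizing — which is the signature a structure-learning
reconstructor should flag. The hidden `truth_anomalous` label is kept
out of CSV output unless explicitly requested.

All draws flow from one seeded generator in a fixed order
(demographics, anomaly flags, latents, decoupling latents, observation
noise, counts, diagnoses, item blocks), so config + seed reproduces a
cohort byte-identically.

What the generator does **not** emulate: item-level factor structure
within an instrument beyond a single latent, response styles
(acquiescence, careless responding), demographic–severity correlations
(age and BMI are independent of the latents), and missingness. Passing
tests therefore demonstrate that the pipeline recovers the structure
this model plants, not that it would behave identically on real survey
data.

## Network and training

Architecture: `n_in → 20 tanh → 20 logsig → n_out linear`, used
auto-associatively (`target = input`, 10 features, 850 weights).
Features are z-scored with the constants retained for inversion;
near-constant columns (SD below a relative 1e-12 tolerance) are mapped
to zero with SD recorded as 0.

Training is Levenberg–Marquardt on `F = β·E_D + α·E_W` with the
analytic Jacobian of all outputs w.r.t. all 850 weights (validated
against central finite differences). Per epoch, one accepted step:
solve `(2βJᵀJ + (2α+μ)I)Δ = −g`, growing μ ×10 until F decreases and
shrinking it ×0.1 on success (μ₀ = 0.005, stop when μ > 1e10). After
each accepted step the evidence-framework updates run:
`γ = N_w − 2α·tr(H⁻¹)`, `α ← γ/2E_W`, `β ← (n_resid−γ)/2E_D`, starting
from α = 0, β = 1. γ is evaluated through the spectral identity
`γ = Σ hᵢ/(hᵢ+2α)` over the eigenvalues `hᵢ` of `2βJᵀJ` — algebraically
the same quantity, but well defined when the Gauss–Newton Hessian is
rank-deficient (more weights than residuals) and in the α → 0 limit,
where the trace formula would return `N_w` instead of `rank(J)` and
drive the β update negative. β's numerator is floored at a small
positive value for the same overparameterized edge case.

Stopping: training MSE (standardized units, train split) ≤ 0.001,
1000 epochs, or μ exhaustion. On the default cohort LM typically stops
at the MSE goal within 10–40 epochs (≈ 0.4 s/epoch on one CPU). The
80/20 split, initialization (Nguyen–Widrow hidden layers,
uniform(−0.1, 0.1) output layer) and all randomness are seeded;
identical seeds give identical reports.

## Stratification and group statistics

Per subject, the actual feature vector is regressed on its
reconstruction (OLS, target on output); R is the signed Pearson
correlation, with constant reconstructions scored R = 0. Percentiles
use linear interpolation of order statistics (index `q·(n−1)`); groups
are `R < P25` → 1, `R > P75` → 3, boundary values inclusive to group 2.
A binary change flag marks group 1 (2 = altered profile). With 1021
distinct R values the groups split 255/511/255.

The comparison grid covers 12 variables (3 binary, compared on their
0/1 codes with the same rank tests). Kruskal–Wallis uses the tie
correction `1 − Σ(t³−t)/(N³−N)` and a χ² reference on k−1 df, with the
all-tied sample defined as H = 0, p = 1. Mann–Whitney U reports
`U = min(U_a, U_b)`; for two untied samples of at most 8 the two-sided
p is exact by full enumeration of rank assignments
(`p = P(min(U_a,U_b) ≤ U_obs)`, which already sums both tails);
otherwise a normal approximation with tie-corrected variance and 0.5
continuity correction. Both tests' null rejection rates are verified to
sit in [0.03, 0.07] at nominal α = 0.05. Bonferroni adjustment uses
m = 3 (the three pairwise comparisons within a variable). Cohen's d is
the magnitude of the mean difference over the (n−1)-weighted pooled SD.
Multiplication factors are group mean over grand mean, undefined (and
reported as NaN in the grid) when the grand mean is zero.

## Known limitations

* **Auto-association has no bottleneck here.** With 20-unit hidden
  layers over 10 features, the identity map is representable, and on a
  low-noise cohort LM reaches it almost exactly (pooled R ≈ 0.999,
  per-subject reconstruction errors of order 0.03 SD). Anomalous
  subjects still reconstruct measurably worse (≈ 2.6× the per-subject
  squared error), but the per-subject R — a Pearson correlation over
  only 10 points, whose denominator is the subject's own feature
  spread — retains little of that signal. Group 1 is enriched in
  planted anomalies (roughly 1.3–1.5× the base rate at default
  conditions) rather than dominated by them, and the group-contrast
  pattern is seed-dependent. An experiment with an oracle reconstructor
  (each feature predicted from the other nine by least squares, fit on
  truth-typical subjects only) bounds what any reconstruction method
  can do on this feature set: about 42% of the bottom-quartile group is
  truly anomalous, because half the features are latent-free
  demographics and a 10-point correlation is intrinsically noisy. The
  corresponding acceptance checks are left failing rather than widened;
  stronger anomaly scores (per-subject reconstruction MSE, a genuine
  bottleneck) are deliberate non-goals of this design.
* The evidence-framework β update assumes more residuals than effective
  parameters; the floor applied in the overparameterized regime is a
  pragmatic guard, not part of the original derivation.
* Exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and restricted to
  n ≤ 8 per sample; ties always fall back to the asymptotic path.
* The generator's calibration targets order-of-magnitude realism, not a
  fit to any particular cohort.
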
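# lbpanomaly

Reconstruction-based anomaly detection for low back pain survey cohorts.

Low back pain and psychological distress are tightly coupled: stress,
anxiety, depression and pain catastrophizing track disability and the
frequency of pain episodes. `lbpanomaly` implements an analysis pipeline
that makes this coupling measurable at the level of the individual
respondent and flags the subpopulation whose profile *breaks* it:

1. **Instrument scoring.** Item-level responses to the Oswestry
   Disability Index (ODI, 10 items, percentage score with five severity
   bands), the 21-item Depression Anxiety Stress Scales (DASS-21, three
   doubled 0–42 subscales with subscale-specific cut points) and the
   daily Pain Catastrophizing Scale (PCS-D, 14 items, total 0–56).
2. **Auto-associative network.** A feed-forward network
   (10 inputs → 20 tanh → 20 logistic sigmoid → 10 linear outputs) is
   trained to reproduce each subject's standardized feature vector —
   age, sex, body mass, height, BMI, ODI %, the three DASS subscales and
   the PCS-D total. Training is Levenberg–Marquardt with Bayesian
   regularization: the objective `F = β·E_D + α·E_W` is minimized while
   `α` and `β` are re-estimated each epoch from the evidence framework,
   `γ = N_w − 2α·tr(H⁻¹)`, `α ← γ/2E_W`, `β ← (n−γ)/2E_D`, on an 80/20
   train/test split.
3. **Per-subject fit and stratification.** Each subject's actual
   profile is regressed on its reconstruction; the correlation
   coefficient R measures conformity to the population structure.
   Subjects are split at the 25th/75th percentiles of R into group 1
   (altered profile), group 2 and group 3.
4. **Group profiling.** Per variable: median (IQR), Kruskal–Wallis
   omnibus test, pairwise Mann–Whitney U with Bonferroni adjustment
   (m = 3), Cohen's d, and each group's multiplication factor
   MF = group mean / grand mean.

Because raw survey data of this kind are typically not shareable, the
package ships a first-class synthetic-cohort generator: a latent-factor
model with correlated distress and physical-severity latents driving
graded-threshold ordinal items, negative-binomial pain-event counts and
logistic diagnosis flags — plus a planted anomalous subpopulation with
elevated, mutually decoupled severities, so every downstream stage is
testable end to end.

## Worked example

```bash
lbpanomaly run --seed 1 --out example_run
```

simulates the default cohort (n = 1021, 73% female, ages 18–35, 25%
planted anomalies), scores it, trains the network, stratifies and
profiles the groups, and prints:

```
run complete: 1021 subjects, R test 0.9995, group sizes {1: 255, 2: 511, 3: 255}; artifacts in example_run
```

The manifest records the run in detail: training stopped after 11
epochs at the MSE goal (training MSE 0.00095 on standardized units,
effective parameters γ ≈ 674 of 850), with pooled Pearson R of
0.9996 / 0.9995 / 0.9996 on the train / test / all samples. In
`comparison.csv`, the group 1 vs group 3 row for DASS stress reads
median (IQR) 14 (18) vs 12 (15), Bonferroni-adjusted p = 0.042 — the
altered-profile group carries more psychological load — and `mf.csv`
shows group 1's depression mean at 1.26× the cohort mean (13.5 vs 10.7
score points) against 1.08× for group 3.

Every stage is also callable on its own (`simulate`, `score`, `train`,
`stratify`, `compare`), re-reading the previous stage's CSV artifacts,
and the whole pipeline is importable as a library
(`lbpanomaly.pipeline.run_pipeline`). Identical config + seed
reproduces every artifact byte-identically.

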
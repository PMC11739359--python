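# Methods

This note documents the models, defaults and numerical choices behind
`sepsisratio`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

The generator emulates a multicentre septic-shock discovery cohort sampled
at two early timepoints. Defaults, chosen to match the cohort design the
pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_patients` / `n_genes` | 100 / 5000 | cohort and panel size (gene-level, not probe-level) |
| `mortality_rate` | 0.31 | ICU mortality; outcomes assigned exactly (`round(n·rate)` deaths) |
| `n_both / n_d1_only / n_d23_only` | 80 / 4 / 16 | timepoint availability → 180 samples |
| `n_batches` | 3 | recruitment cohorts; each patient's samples share a batch |
| `n_up_stable / n_down_stable` | 39 / 2 | planted stable signature, ±1.5 log₂ in non-survivors at both timepoints |
| `n_d1_only_degs / n_d23_only_degs` | 62 / 134 | timepoint-specific effects, ±1.0 log₂, alternating sign |
| `within_group_sd` | 0.7 | log₂ residual SD, typical for whole-blood arrays |
| `batch_shift_sd / batch_scale_sd` | 0.5 / 0.1 | gene-specific additive shift and log-scale factor per batch |
| lactate log-normal (μ, σ) | survivors (0.4, 0.5); non-survivors (1.0, 0.5) | mmol/L; gives ≈28% vs ≈73% above the 2 mmol/L cutoff |
| `hazard_nonsurvivor / hazard_survivor` | 0.12 / 0.004 per day | exponential event rates; censoring at day 30 |
| `qpcr_slope / qpcr_noise_sd` | −3.3219 / 0.15 | ideal-efficiency standard-curve slope; replicate Cq noise |

Expression follows the ComBat generative model exactly —
`x = μ_g + γ_gb + δ_gb·ε + effect` — with effects added outside the batch
scaling so the planted log₂FC is exact by construction. The timepoint-
specific DEG counts were set so that per-timepoint DEG totals
(signature + specific ≈ 103 at day 1, ≈ 175 at days 2–3) sit at the scale a
two-timepoint discovery analysis of this kind reports; their overlap
structure beyond the counts is not modelled. Non-survivor event times are
rejection-sampled to fall inside the 30-day window, since ICU mortality is
the outcome definition; survivor discharge-alive times are censored
observations. Lactate is conditionally independent of expression given
outcome (a coupling flag exists for stress tests); the real joint
distribution is unknown and not claimed.

qPCR plates hold up to 40 unknown samples (triplicate wells), a triplicate
inter-run calibrator (IRC) per plate, and — on the first plate — quadruplicate
standards at five ten-fold dilutions per gene. Cq is linear in log₁₀ relative
copies with a per-plate run offset shared by all wells, so IRC division
removes the offset exactly in expectation. The IRC is a pooled sample with
identical log₂ abundance (8.0) for every assayed gene, which makes the
calibrated up/down ratio equal the array-scale ratio exactly at zero noise.
Fluorescence curves and Cq calling are out of scope; Cq values are ingested.

**What passing tests do not show about real data:** planted effects are
homoscedastic, symmetric and large relative to noise; there are no probe
effects, no missing values, no comorbidity covariates, and batch effects
follow exactly the model the adjustment assumes. Recovery of the planted
signature therefore validates the pipeline's arithmetic and thresholds, not
its power on weaker, messier real cohorts.

## Preprocessing

Quantile normalization maps each sample to the mean empirical distribution;
ties receive the mean of the reference values at their tied ranks (so a
column's mean can shift slightly when ties are present — the exact
equal-distribution property holds for tie-free data).

Batch adjustment is the parametric empirical-Bayes location/scale model:
standardize per gene against the size-weighted grand mean and pooled
residual variance; estimate per-batch means/variances; shrink toward a
normal / inverse-gamma prior fitted across genes by method of moments
(prior variance of the batch means taken with ddof = 0, matching the
widely used Python port, which this implementation reproduces to ~1e-6);
solve the coupled posterior equations by fixed-point iteration
(relative-change tolerance 1e-8). Covariate protection (outcome in the
design, removed before standardization and restored after) is available and
off by default, because protecting outcome is an analysis choice the user
should make explicitly; on balanced synthetic designs the unprotected adjustment attenuates
planted effects by well under 10%.

Two properties often attributed to batch adjustment hold only without EB
shrinkage: exact removal of a pure per-gene location shift, and exact
idempotence. Shrinkage leaves a `(1−w)(γ̂−γ̄)` residual by design. The
package therefore exposes `shrink=False` (plain location/scale adjustment,
ddof = 0 scale), which has both exact properties; the EB default is tested
for the honest versions (>95% of batch-mean spread removed, strong
contraction on re-adjustment, batch F-statistic decrease).

## Differential expression

The moderated statistics follow the standard empirical-Bayes two-group
workflow, validated term-by-term against Bioconductor limma in the test
suite: method-of-moments fit of `(d₀, s₀²)` on `log s²_g` via the digamma/
trigamma identities (Newton inversion of trigamma); posterior variance
`(d₀s₀² + d_g s²_g)/(d₀+d_g)`; p-values on `min(d₀+d_g, Σd_g)` df; B
statistic from the log-odds kernel with the effect-variance prior estimated
by the top-proportion method at `p_DE = 0.01` (search limits 0.01–16 scaled
by `s₀²`; normal kernel when `d₀ > 10⁶`). When the spread of `log s²_g` is
no larger than sampling noise alone, `d₀ = ∞` and the prior scale is the
arithmetic mean of the variances. Zero-variance genes are floored at 1e-12
with a warning. `log₂FC` is always the raw difference of group means;
samples are treated as unpaired within each timepoint (no longitudinal
model — none is claimed by the workflow this implements).

"q-value" is Benjamini–Hochberg step-up FDR; the B filter "≥ 75%" is
interpreted on the posterior-probability scale, `exp(B)/(1+exp(B)) ≥ 0.75`,
since B itself is a log-odds.

## Thresholds and tie-breaks

- DEG call: strict inequalities (`|log₂FC| > 0.6`, `q < 0.1`).
- Cascade filters: non-strict (`posterior ≥ 0.75`, `linear FC ≥ 1.5`). The
  linear-FC filter is nearly redundant with the DEG call (2^0.6 = 1.516 >
  1.5) and is kept so the cascade's four filters stay independently
  configurable.
- Hub ranking: weighted degree within the candidate-induced subgraph
  (global-degree mode by flag); consensus = mean rank across networks, genes
  absent from a network scoring 0 there; ties break lexicographically.
  The down-gene partner for the ratio is chosen by the higher mean
  two-timepoint AUROC, ties lexicographic.
- Youden threshold: scan midpoints between consecutive sorted unique scores
  plus outer sentinels; rule `score ≥ t ⇒ non-survivor`; among J-ties the
  smallest threshold wins (tolerance 1e-12).
- Bootstrap CI: percentile 2.5/97.5 over class-stratified resamples
  (n = 2000 by default), seeded.
- Risk cutoffs inclusive (`lactate ≥ 2`, `ratio ≥ threshold`); patients
  without lactate are excluded, not errors. Mortality percentages round
  half away from zero. The headline association p is always the Pearson
  chi-square (the statistic clinical tables of this kind report); when an expected count
  is < 5 an exact companion p (Fisher for 2×2, else a seeded Monte-Carlo
  chi-square with 10 000 permutations) is attached and flagged, because no
  installed library provides an r×c Fisher test.
- Log-rank: observed-minus-expected with hypergeometric variance,
  `df = k−1`, pseudo-inverse for degenerate variance matrices; pairwise
  tests unadjusted. Follow-up truncated at `min(day 30, discharge)`,
  discharge treated as censoring.

## Platform transfer

The efficiency-corrected path (default) fits each gene's standard curve by
least squares, takes `E = 10^(−1/slope)` (flagging E outside 1.8–2.2), and
inverts the curve for relative quantities before IRC division; the
`2^−ΔΔCq` path fixes E = 2 and needs no standards. Technical replicates are
averaged on the Cq scale, with replicate SD > 0.5 Cq flagged for QC. The
discovery threshold is recomputed on the qPCR scale by Youden (the
transfer behaviour); a frozen threshold can be supplied instead for
external validation use.

## Problem sizes in tests

Unit and property tests run on cohorts of 300–800 genes and 30–100
patients; the acceptance checks use the full default design (5000 genes,
180 samples) across five seeds, which completes in a few seconds per seed.
Oracle comparisons (limma, scanpy ComBat, pROC DeLong, lifelines KM and
log-rank, scikit-learn AUROC, statsmodels BH) run on small fixtures chosen
to exercise ties, censoring and degenerate cases.

## Known limitations

- Gene-level simulation and normalization only; probe-level effects (gcRMA
  background, probe affinity) are out of scope.
- The hub-selection consensus rule (mean rank) is a design choice;
  commercial/curated interaction databases are not redistributed — users
  supply their own edge lists, and results depend on which they choose.
- Degree is the only centrality; betweenness/eigenvector variants would
  need a flag extension.
- The intermediate-risk tier pools both discordant biomarker patterns;
  no distinction is made between them.
- Survival times are exponential within outcome groups — adequate for
  testing the estimator plumbing, not a clinical hazard model.
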
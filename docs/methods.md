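# Methods

## The model and its assumptions

The package estimates the joint effect of a chemical mixture (blood Pb, Hg,
Cd; urinary As; µg/L) on a binary outcome by quantile g-computation. Each
exposure is mapped to an integer quantile score (default quartiles, q = 4);
a logistic model linear in the scores and the covariates is fit by maximum
likelihood; and the mixture effect is read out in two forms:

* **Conditional:** ψ_cond = Σβ_j, the log-odds change per simultaneous
  one-quantile increase in every exposure, holding covariates fixed.
* **Marginal:** for each joint level s ∈ {0,…,q−1}, every subject's mixture
  scores are set to s and the fitted probabilities averaged (g-computation
  standardization); a log-linear marginal structural model (MSM) regressed
  on s yields ψ_marg, and PR = exp(ψ_marg) is the primary effect measure —
  the factor by which standardized outcome prevalence changes per joint
  quantile increase.

The causal reading of the PR requires the usual g-computation assumptions
(no unmeasured confounding given the adjustment set, correct outcome-model
specification, positivity across quantile levels). The package makes no
attempt to verify these; it reports the estimator's output.

Directional weights follow the convention that within each sign class the
weight of chemical k is β_k divided by the class's coefficient sum, so
magnitudes sum to 1 per direction. The single-ratio definition
w_k = β_k/Σβ_j is only coherent when all coefficients share a sign; the
per-direction partition is the form that remains interpretable (and
reportable as left/right-pointing bars) under mixed signs, and is what the
package enforces on every fit. The exponentiated within-class coefficient
sums are reported as the positive and negative "partial effects"; they are
conditional (odds-scale) quantities, and ψ_cond equals the sum of the two
class sums exactly.

## Inference

The PR confidence interval is a subject-level resampling bootstrap:
each replicate redraws n subjects with replacement and reruns the entire
pipeline — re-quantization on the resampled empirical distribution,
logistic refit, standardization, MSM slope. Percentile intervals are the
default (B = 1000; a log-scale normal-approximation interval is available).
Replicates that fail to converge, show apparent separation (|β| > 30), or
produce a degenerate standardized probability are dropped and counted; more
than 20% failures flags the interval unreliable. Identical seeds give
bit-identical intervals. Significance is two-sided at α = 0.05 with no
multiplicity correction across the five outcome domains — a deliberate
mirror of common practice in this literature, and a caveat for
interpretation.

Stepwise covariate selection is forward–backward: starting from the
exposure-only model, the single add-or-drop move that most improves the
criterion (AIC = deviance + 2k, or deviance with a user-stated penalty) is
taken until no move improves it; candidates are covariate groups (a
categorical enters or leaves with all its dummies) and ties resolve by
candidate order. The greedy path is logged step by step.

## Numerical choices

* Quantile definition: linear interpolation of the empirical CDF (numpy's
  default). Ties at a cut point go to the **lower** bin. Fewer distinct
  values than q collapses bins with a warning; scores stay valid.
* Aliased design columns are removed by a leftmost-wins Gram–Schmidt rank
  screen before fitting, and logged.
* The MSM line is ordinary least squares of log standardized probability on
  level; a standardized probability of exactly 0 or 1 makes the log-RR
  undefined and raises.
* The median's 95% CI in descriptive tables uses the distribution-free
  binomial order-statistic method.
* Percent change is (1 − PR)·100 for PR < 1 and (PR − 1)·100 otherwise;
  tables round it to one decimal, the JSON serialization keeps full
  precision and round-trips exactly.
* Percentages in dichotomization summaries are computed from exact counts
  and rounded to one decimal; where published tables disagree with the
  arithmetic of their own printed counts (e.g. 261/310 = 84.2), the
  computed value is reported.

## The synthetic cohort generator

The generator exists so every stage is testable with known truth and no
subject-level data.

* **Exposures:** Gaussian copula with log-normal marginals. Marginals are
  parameterized from (P25, median, P75) targets — defaults follow the
  study population this package models (Pb median 27.2, Hg 1.2, Cd 0.2,
  As 8.3 µg/L); σ averages the two implied log-scale spreads. The copula
  correlation is set from the target Spearman matrix via
  ρ = 2 sin(πρ_s/6), so rank correlations are matched exactly in
  distribution. The default inter-metal rank correlation of 0.3 is an
  assumption: co-exposure in mining settings is qualitatively documented
  but no correlation matrix is published. The published Cd quartiles are
  internally inconsistent after rounding (P25 0.21 vs median 0.20), so the
  Cd default P25 is the log-symmetric 0.15.
* **Covariates:** independent marginals matched to the study's baseline
  table (47.3% girls; age 43.9 ± 3.4 months; 19.7% mothers without formal
  education; SES high/moderate/low 68/21/11% with integer wealth scores
  drawn within each category's range). Birth weight, not tabulated in the
  source, defaults to 3.1 ± 0.5 kg clipped to [1.5, 5].
* **Outcomes:** Bernoulli draws around a linear predictor in the quantized
  exposures and encoded covariates. Two links are offered. The logit link
  matches the analysis model, so the fitted conditional ψ recovers ψ_true.
  The log link makes probability = exp(η): then the standardized prevalence
  is exactly log-linear in the joint level with slope ψ_true, i.e.
  **exp(ψ_true) is the marginal PR estimand itself**. PR-calibration
  experiments (recovery, CI coverage) use the log link for this reason —
  under a logit-link truth at 20–35% prevalence the marginal log-RR slope
  is attenuated by roughly a factor (1 − p̄) relative to ψ_true
  (noncollapsibility), so exp(ψ_true) would not be the quantity a PR
  interval targets. Outcome noise is purely the Bernoulli draw; no additive
  residual exists on the probability scale. Log-link probabilities are
  clipped at 1 with a warning; default intercepts are chosen so the clip
  never binds (baseline risk 0.35 for negative ψ, 0.15 otherwise).
* **Assessment items:** a logistic item-response model per domain — 34
  items, difficulties spread over [−3, 1], shared latent ability per child
  (standard normal), discrimination 1.3, a small positive age slope. The
  discrimination default puts simulated scale reliability (Cronbach α) in
  the 0.85–0.95 band typical of validated developmental instruments. The
  synthetic norm table marks an item age-expected when its model-implied
  marginal pass rate (Gauss–Hermite integration over ability) is ≥ 90% at
  the age-band midpoint; user-supplied norm CSVs are accepted in the same
  schema.

What the generator does **not** emulate: laboratory measurement error,
limits of detection/censoring, exposure–covariate dependence (covariates
are independent of exposures, so "adjusted vs unadjusted" differences in
simulations reflect efficiency, not confounding), within-household
clustering, and any real MDAT normative content. Passing tests therefore
demonstrate estimator correctness and calibration under the assumed
structure, not robustness to those real-data features.

## Scoring rules

A child is impaired in a domain when they fail **more than two** items the
age-referenced norm expects (≥ 90% reference pass rate); one or two failures
is usual. Global impairment is the exact union of the four domain flags.
Wealth scores partition as > 9 high, 6–9 moderate, < 6 low — the only
non-overlapping reading of the instrument's published cut points, which
elsewhere describe "≥ 9" as high; a `high_at_nine` switch provides that
alternative convention. Cronbach's α uses unbiased variances and raises
explicitly when the total-score variance is zero.

## Problem sizes in the shipped experiments

Parameter-recovery runs use 20 replicates of n = 5000 per effect size
(ψ ∈ {−0.4, −0.2, 0, +0.2}); the CI-coverage experiment uses 200 cohorts of
n = 500 with B = 200 bootstrap resamples, with the binomial Monte-Carlo
error of a 200-replicate coverage estimate (±1.5% SE) as the acceptance
band's scale. These sizes were chosen so each experiment is decisive at the
tolerance it asserts while remaining a desk-scale computation.

## Known limitations

* The weight decomposition is descriptive, not variance-aware: no CI is
  attached to individual weights (the bootstrap could be extended to do so).
* The bootstrap treats the quantile cut points as re-estimated per
  replicate, which is the honest propagation of quantization uncertainty
  but means replicate scores are not nested in the original bins.
* Stepwise AIC selection inherits the usual instability of greedy selection;
  the full step log is emitted so users can audit the path.
* The SPSS reader is a thin optional shim; complete-case exclusion is the
  only missing-data policy, with dropped counts logged.
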
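# qgcmix

Quantile g-computation for the joint effect of a heavy-metal mixture —
blood lead (Pb), mercury (Hg), cadmium (Cd) and urinary arsenic (As) — on
binary child-neurodevelopment outcomes, together with everything needed to
exercise the pipeline end to end without access to subject-level data: a
synthetic cohort generator, developmental-assessment (MDAT) scoring,
household-wealth SES classification, bootstrap inference and report
rendering.

The intended users are environmental-epidemiology analysts who want a
transparent, testable implementation of the mixture estimator their study
design calls for, and methodologists who want to probe its calibration on
cohorts with known truth.

## The estimator

Each exposure \(X_j\) is scored into quantile categories
\(X_j^q \in \{0,\dots,q-1\}\) (default quartiles, \(q=4\)) and a logistic
model is fit jointly:

\[
\operatorname{logit} \Pr(Y=1 \mid X, Z)
  = \beta_0 + \sum_{j=1}^{d} \beta_j X_j^q + \gamma^\top Z .
\]

The mixture is summarized by

* \(\psi_{\text{cond}} = \sum_j \beta_j\): the conditional log-odds change
  per simultaneous one-quantile increase in all exposures;
* **directional weights** \(w_k = \beta_k / \sum_{j \in S} \beta_j\) within
  each sign class \(S\) (positive or negative coefficients), so the weight
  magnitudes sum to 1 per direction;
* the **prevalence ratio**: g-computation standardization sets every
  subject's mixture scores to a common level \(s\), averages the fitted
  probabilities into \(\bar p(s)\), and the marginal structural model
  \(\log \bar p(s) = \alpha + \psi_{\text{marg}} s\) gives
  \(\mathrm{PR} = e^{\psi_{\text{marg}}}\);
* a subject-resampling bootstrap (percentile, default \(B=1000\)) for the
  PR confidence interval; the whole pipeline — quantization, fit,
  standardization — is refit per replicate.

Chemical-specific models are the \(d=1\) special case of the same pipeline,
and forward–backward stepwise AIC selection chooses the covariate
adjustment set (default: child sex, birth weight, maternal education, child
age, household SES).

## Worked example

```python
import numpy as np
import qgcmix as qm

truth = qm.MixtureTruth.from_psi_weights(
    beta0=float(np.log(0.35)), psi=-0.2,
    weights={"pb": 0.61, "as": 0.036, "cd": 0.131, "hg": 0.223},
    link="log",
)
cohort = qm.generate_cohort(2000, truths={"imp_language": truth}, seed=21)
fit = qm.fit_mixture_model(cohort, "imp_language", B=500, seed=22)
```

Running `examples/04_mixture_fit.py` (the script version of the above)
prints:

```
joint effect: PR = 0.845 (95% CI 0.737, 0.960)  [truth exp(-0.2) = 0.819]
percent change = 15.5%  psi_conditional = -0.209 (log-odds scale)
directional weights (|w| sums to 1 per direction):
  pb   -0.448
  hg   -0.307
  as   -0.215
  cd   -0.029
```

The PR of 0.845 says a simultaneous one-quartile increase in all four
metals multiplies the standardized prevalence of language impairment by
0.845 (a 15.5% reduction in this simulation, where impairment is coded so
that the truth is protective at −0.2 on the log scale); the interval covers
the generating truth exp(−0.2) = 0.819. All four weights are negative —
every chemical contributes in the same direction, Pb most strongly — and
their magnitudes sum to 1.

The other scripts in `examples/` walk the remaining capabilities: cohort
simulation and calibration (`01`), exposure preparation and descriptive
tables (`02`), MDAT item scoring and reliability (`03`), stepwise selection
and report rendering (`05`). A thin CLI (`qgcmix simulate|prep|score|fit|
report`) composes the same pipeline from the shell.

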
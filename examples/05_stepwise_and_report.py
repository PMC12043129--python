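"""Covariate selection and report rendering.

Runs forward-backward stepwise AIC selection over candidate covariates, fits
adjusted and unadjusted mixture models, and renders the model table plus the
weight-bar and MSM-curve data any plotting layer can consume.
"""

import numpy as np

import qgcmix as qm

truth = qm.MixtureTruth.from_psi_weights(
    beta0=float(np.log(0.3)), psi=-0.25, link="log")
cohort = qm.generate_cohort(2500, truths={"imp_gross_motor": truth}, seed=31)

sel = qm.stepwise_select(cohort, "imp_gross_motor")
print("stepwise-retained covariates:", sel.retained or "(none)")
print(sel.log_frame().to_string(index=False))

fits = [
    qm.fit_mixture_model(cohort, "imp_gross_motor", adjusted=False,
                         B=200, seed=32),
    qm.fit_mixture_model(cohort, "imp_gross_motor", adjusted=True,
                         covariates=sel.retained or None, B=200, seed=32),
]
table = qm.render_model_table(fits)
print("\nmodel table (psi1 rows):")
psi = table[table["term"] == "psi1"]
print(psi[["model", "estimate", "ci_low", "ci_high", "percent_change"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

curve = qm.export_msm_curve(fits[1])
print("\nMSM curve (adjusted):")
print(curve.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nThe standardized probabilities fall roughly geometrically across")
print("joint quartile levels; the msm_fit column is the fitted log-linear")
print("line whose slope, anti-logged, is the reported PR.")
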
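"""Fit the mixed autoregressive ordinal model for one sign and forecast.

The fitted model carries population persistence coefficients, ordered-logit
cut-offs, the random-intercept SD, and per-patient empirical-Bayes
intercepts; a forecast is a full probability distribution over tomorrow's
score 0..4 given today's.
"""

import numpy as np

import adforecast as af

ds, truth = af.generate_cohort(af.GeneratorConfig(n_patients=40, n_days=150, seed=2))
pairs = af.extract_transition_pairs(ds, "itching")
model = af.fit_sign_model(pairs, af.ModelSpec("itching"))

print("beta (prev score 0..3):", np.round(model.beta, 2), " truth:", truth["beta"])
print("cutpoints:", np.round(model.cutpoints.cutpoints, 2))
print(f"sigma_alpha: {model.sigma_alpha:.2f}  (truth {truth['sigma_alpha']})")

patient = ds.patients[0]
for s_today in (0, 2, 4):
    pmf = af.predict_forecast(model, patient, s_today)
    print(f"today={s_today} -> tomorrow pmf {np.round(pmf, 3)}")
# the forecast mass tracks today's score: the model has learnt persistence.
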
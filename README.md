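# adforecast

Short-term forecasting of daily atopic-dermatitis (AD) severity, and a
principled test of whether environmental exposures add predictive value.

AD severity is commonly tracked as six daily sign scores — dryness, oedema,
itching, oozing, redness and sleep disturbance — each on an ordinal 0 (none)
to 4 (severe) scale. The scores fluctuate day to day, are strongly
persistent, differ markedly in baseline between patients, and are often
claimed (for instance by consumer symptom-tracking apps) to be predictable
from weather and air quality. This package is for biostatisticians and
epidemiologists who want to evaluate such claims properly: with a dynamic
patient-level model, rolling-origin validation, and proper scoring rules.

## The model

For each sign, tomorrow's score for patient *k* follows an ordered-logistic
distribution whose location is an autoregressive mixed-effects linear
predictor:

```
s_k(t+1) ~ OrderedLogistic( α_k + Σ_{i=0..3} β_i · 1{s_k(t) = i} + γ'x(t) ,  c )
```

* `α_k ~ N(0, σ_α²)` — patient random intercept (baseline severity);
* `β_0..β_3` — coefficients of previous-score indicators (score 4 is the
  reference), carrying the day-to-day persistence;
* `γ` — optional covariate effects (temperature, relative humidity,
  rainfall, diurnal temperature range, PM10, NO2, O3, topical
  corticosteroid use), entering at day *t* to predict day *t+1*;
* `c = (c₁ < c₂ < c₃ < c₄)` — cut-offs of the ordered-logistic distribution.

The random intercept is integrated out by adaptive Gauss–Hermite quadrature
and all parameters are estimated by maximum marginal likelihood. Forecasts
are full probability distributions over tomorrow's score; they are scored
with the ranked probability score (RPS, normalized to [0, 1]) against a
uniform benchmark and a patient-historical-frequency benchmark, in a
forward-chaining design (train on days before *T*, test on day *T*, for
every *T*). Six sign forecasts combine — treating the signs as independent —
into an exact probability for a binary AD symptom state (itching + sleep
≥ 2 and at least two of the four skin signs non-zero), scored by Brier.

Because the motivating cohort (177 paediatric patients followed daily for
about 17 months, with 18.9 % of sign scores missing) is not publicly
deposited, the package ships a calibrated synthetic cohort generator with
the same statistical structure and known ground truth; every stage of the
pipeline is tested against it.

## Worked example

```python
import adforecast as af

ds, _ = af.generate_cohort(af.GeneratorConfig(n_patients=25, n_days=80, seed=3))
specs = [af.ModelSpec(s) for s in af.SIGNS]
table = af.forward_chaining(ds, specs, refit_stride=7, min_train_days=14)
print(table.records.groupby(["sign", "model_variant"])["score_value"].mean()
      .round(4).unstack())
```

prints

```
model_variant  historical  no-covariate  uniform
sign
dryness            0.1163        0.0864   0.1843
itching            0.1194        0.0886   0.1855
oedema             0.0135        0.0114   0.2933
oozing             0.0494        0.0367   0.2697
redness            0.0976        0.0738   0.2206
sleep              0.0919        0.0693   0.2315
state              0.1748        0.1504   0.4702
```

Each number is a mean score over all one-day-ahead forecasts (RPS for the
six signs, Brier for the derived binary state; lower is better). The fitted
autoregressive model beats the patient-historical benchmark for every sign,
which in turn beats the uniform forecast; oedema is nearly trivial to
predict because its score is 0 about 90 % of the time. Adding an
environmental covariate to the model (see `examples/04_covariate_ablation.py`)
leaves the RPS statistically unchanged when the generator's true covariate
effect is zero — the package's re-creation of the finding that short-term
environmental data do not improve next-day AD severity prediction.

The `examples/` directory walks through each capability; the `adforecast`
CLI (`simulate`, `validate`, `report`) runs the same pipeline end-to-end
from a YAML config.

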
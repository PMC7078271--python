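# sleepcog

Does self-reported sleep quality predict cognitive performance in healthy
young adults? `sleepcog` implements the full analysis pipeline for this
question as a tested, reusable Python library: questionnaire scoring,
procedural-learning indices from the Alternating Serial Reaction Time
(ASRT) task, a PCA sleep-disturbance composite, random-intercept linear
mixed models with cluster-bootstrap inference, and BIC-approximation Bayes
factors that quantify evidence *for* the null — plus a synthetic cohort
generator with known ground truth, so every statistical claim the pipeline
makes can be checked by simulation.

It is aimed at researchers in sleep and memory who want to run or audit
pooled multi-study analyses of questionnaire-based sleep quality (PSQI,
AIS, GSQS, sleep diary) against working-memory, executive-function and
sequence-learning outcomes.

## The model

For each cognitive outcome *y* and sleep predictor *x* (all z-scored,
gender effect-coded, with age, gender and morningness as covariates):

```
y_ij = β x_ij + γ' c_ij + u_j + ε_ij ,   u_j ~ N(0, τ²),  ε_ij ~ N(0, σ²)
```

with a random intercept *u_j* per study, fitted by full maximum
likelihood. Inference on the standardized β uses a nonparametric cluster
bootstrap (case resampling stratified by study; percentile 95% CI;
two-sided sign-based p-value). Evidence for the null comes from the BIC
approximation to the Bayes factor,

```
BF01 = exp((BIC_full − BIC_null) / 2)
```

where the null model keeps the covariates and the random intercept but
drops the sleep predictor. BF01 between 3 and 10 is substantial evidence
for no association.

The sleep-disturbance predictor itself is the first principal component of
the standardized PSQI and AIS totals (eigenvalue `1 + r` for two scales
with correlation `r`), oriented so higher = more disturbed sleep.

ASRT learning indices follow the standard triplet logic: a trial's triplet
(positions at trials *n−2, n−1, n*) is **high-frequency** when the final
position is the pattern-successor of the first. Triplet learning = low −
high RT (high − low accuracy); higher-order sequence learning = random-high
− pattern-high; statistical learning = random-low − random-high within
random-ending triplets; general skill = first-epoch − last-epoch RT. Trills
(X–Y–X) and repetitions (X–X–X) are excluded; RT cells use correct trials
only.

## Worked example

```python
from sleepcog import (CohortConfig, generate_cohort, fit_composite,
                      ModelSpec, fit_model, bootstrap_inference,
                      bf01_interpretation)

table, truth = generate_cohort(CohortConfig(), seed=7)   # 235 participants, true beta = 0
comp = fit_composite(table["psqi"].to_numpy(float), table["ais"].to_numpy(float))
table["sleep_disturbance"] = comp.scores
print(f"first eigenvalue {comp.eigenvalue_first:.2f}, "
      f"variance explained {comp.variance_explained:.1%}")

fit = fit_model(ModelSpec(outcome="counting_span"), table)
(lo, hi), p, _ = bootstrap_inference(ModelSpec(outcome="counting_span"),
                                     table, B=1000, seed=7)
print(f"beta = {fit.beta_std:.3f} [{lo:.2f}, {hi:.2f}], p = {p:.2f}, "
      f"BF01 = {fit.bf01:.2f} ({bf01_interpretation(fit.bf01)})")
```

prints

```
first eigenvalue 1.55, variance explained 77.3%
beta = 0.109 [-0.03, 0.23], p = 0.10, BF01 = 3.76 (substantial evidence for H0)
```

The composite captures ~77% of the two scales' variance; the working-memory
outcome shows a small standardized association whose bootstrap CI spans
zero, and the Bayes factor says the data are ~4 times more likely under
"no association" than under an association — the expected behaviour for a
null cohort (this seed happens to draw a mildly positive sample estimate;
across seeds the median BF01 is ~12).

Short narrative scripts, one per capability, live in `examples/`. The same
pipeline runs from the shell:

```
sleepcog all --out results --seed 7 --bootstrap-b 1000
sleepcog report --data participants.csv --out results
```

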
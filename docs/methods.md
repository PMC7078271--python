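# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `sleepcog`.

## Scope and data model

The package analyses a pooled cohort of healthy young adults drawn from
three studies (default sizes 47/103/85, N = 235). Each participant carries
demographics (age, gender, morningness/MEQ total), sleep-scale totals —
PSQI as a three-component 0–9 sum, AIS 0–24 in all studies; GSQS 0–14 and
a 0–12 sleep-diary composite in Study 2 only — and twelve cognitive
outcomes: ten ASRT-derived indices plus counting span (working memory) and
WCST perseverative errors (executive function). Scale totals are consumed
as given; item-level scoring is out of scope except for an optional helper
that sums three named 0–3 PSQI components. Which three components compose
the short PSQI total is not fixed by the data format, so the component
names are configurable (defaulting to subjective quality, latency,
disturbances); likewise the diary composite is consumed as a precomputed
nightly average because its item-level construction is not specified.

Sleeper categories use the published band boundaries (PSQI 0–1 / 2–4 /
5+; AIS 0–2 / 3–6 / 7+; GSQS 0–1 / 2–7 / 8+; diary 0–1 good, 2+ moderate
with no poor band). Published bands top out at the observed maxima; we
extend the top band to each scale's obtainable maximum so the bands
partition the full range — the tests assert this by enumeration. Extreme
groups are PSQI ≤ 1 (good) vs PSQI ≥ 5 (poor).

## ASRT engine

Blocks default to 85 trials: 5 random warmup trials, then 80 strictly
alternating pattern/random trials (10 cycles of the 8-element alternating
sequence, pattern first, restarting each block). These counts follow the
standard task structure in the ASRT literature and are configurable; they
are conventions, not estimates.

A trial *n* is classifiable when it and both of its two within-block
predecessors are non-warmup trials; its triplet is high-frequency iff
`position[n] == succ(position[n-2])` under the pattern-successor map. The
first two classifiable trials of each block therefore remain unclassified.
Exhaustively, 16 of the 64 triplet types are high-frequency; in a long
stream ~62.5% of classifiable trials are high-frequency (all pattern
trials plus ¼ of random trials) and each specific high-frequency triplet
occurs ~5× as often as each specific low-frequency one. Trills (X–Y–X)
and repetitions (X–X–X) — which can never be high-frequency, because the
successor map has no fixed points — are excluded from all learning-index
cells, the standard convention; the exclusion list is configurable.

Index definitions (signs oriented so positive = learning):

| index | RT | ACC |
|---|---|---|
| triplet | low − high | high − low |
| higher-order sequence | random-high − pattern-high | pattern-high − random-high |
| statistical | random-low − random-high | random-high − random-low |
| general skill | first − last epoch | last − first epoch |

RT cells use correct trials only; ACC cells use all included classifiable
trials (both configurable). Epochs default to 5 blocks. No RT outlier
trimming is applied by default; an optional min/max window exists. An
empty cell raises an explicit "insufficient trials" error rather than
propagating NaN. The accuracy general-skill sign is configurable
(`acc_skill_first_minus_last`) because both orientations appear in
published summaries; the default keeps positive = improvement.

Note an identity that constrains interpretation: triplet learning is a
weighted combination of the two pure contrasts. With default task
structure the high pool is ~4/5 pattern trials, so
`triplet ≈ statistical + 0.8 × higher-order` in expectation.

## Sleep-disturbance composite

PSQI and AIS totals are z-scored (sample SD) and the 2×2 correlation
matrix eigendecomposed. The first eigenvalue is exactly `1 + r`; scores
are the first component rescaled to unit variance — equivalently
`(z_PSQI + z_AIS) / sqrt(2(1+r))` — and oriented so both loadings are
positive (higher = more disturbed sleep). Variance explained is reported
as eigenvalue/2, the only value consistent with a two-variable PCA; some
published summaries report a higher figure for the same eigenvalue, which
cannot arise from eigenvalue/2 and is not reproduced. Bartlett's test of
sphericity is the closed form `−(n − 1 − (2p+5)/6)·ln det(R)` with
`df = p(p−1)/2`; a singular correlation matrix raises an error.

## Association models

One model per outcome × predictor. The outcome and all continuous
regressors are z-scored; gender is effect-coded (M = +1, F = −1); rows
with any missing value are dropped per model (listwise deletion), so
outcomes with missing data (e.g. six missing executive-function scores)
run on fewer rows. Residual df is reported as `n_used − #fixed effects`
(intercept included); other df conventions exist in the literature and
are not matched.

The pooled analysis is a random-intercept-by-study LMM fitted by **full
ML, never REML**, because the Bayes factor compares BICs of models with
different fixed-effect structures, which REML likelihoods do not support.
The fitter profiles the likelihood to one dimension (the variance ratio
τ²/σ²): given the ratio, the GLS coefficients and the residual variance
are closed-form via per-group Sherman–Morrison identities, and the scalar
profile is maximised by bounded search on a log grid (tolerance 1e-6,
range e±14). The boundary τ² = 0 is compared explicitly and yields the
OLS limit with a flag, never an error. The entire fit runs off sufficient
statistics (X'X, group sums), ~0.4 ms per fit, which makes 10⁵ bootstrap
refits tractable; statsmodels `MixedLM(reml=False)` is the independent
oracle in the test suite (agreement to ≤1e-5 in log-likelihood).

Bootstrap inference: nonparametric case resampling stratified by study
(cluster bootstrap), B = 1000 by default; percentile 95% CI; two-sided
p-value `2·min(#{β* ≤ 0}, #{β* ≥ 0})/B`, floored at 1/B and capped at 1.
Resample sufficient statistics are computed in one batched pass. More than
10% failed refits aborts with a diagnostic. A residual/parametric
bootstrap is not currently offered; case resampling is the default and
only mode.

Bayes factors: `BF01 = exp((BIC_full − BIC_null)/2)` with
`BIC = −2ℓ + k ln n`, `k` counting fixed effects plus two variance
parameters and `n` the number of observations (not groups). Both fits use
identical rows by construction. The uninformative-predictor limit is
`BF01 = √n`; reciprocity `BF01(a,b)·BF01(b,a) = 1` holds exactly. Under a
true null the likelihood-ratio is ~χ²₁, so at n = 235 the predicted
median BF01 is `exp((ln 235 − 0.455)/2) ≈ 12.2` with `P(BF01 > 3) ≈ 0.93`
— the simulation tests reproduce both.

Study-2-only predictors (diary, GSQS) use Huber M-estimation
(statsmodels RLM, HuberT) without random effects, with the same
standardization, covariates and bootstrap. Their BF01 uses the
Gaussian-likelihood BIC of the equivalent OLS fits — an approximation,
since the Huber objective is not a likelihood; with no gross outliers the
two coincide. The extreme-group comparison reports Welch t, Cohen's d and
a BIC-based BF01 for the group factor with covariates retained; groups
smaller than 3 are refused.

## Synthetic cohort generator

The generator defines the study conditions for all simulation-based
checks. Demographics and morningness are drawn per study from the
published means/SDs (e.g. age 21.38 ± 1.79 in Study 1; M:F 10/37, 30/73,
23/62; MEQ ≈ 34 ± 6.3). Sleep scores come from a correlated latent
Gaussian: a latent disturbance factor *f* ~ N(0,1) on which PSQI and AIS
load √r each (default r = 0.55, inferred from the published composite
eigenvalue, not a directly reported quantity), discretized by
rounding and clipping to the obtainable ranges with marginals targeting
the published means/SDs (PSQI 2.99/1.57, AIS 3.98/2.66, GSQS 2.86/2.87,
diary 1.38/1.22). Rounding and clipping attenuate the score-scale
correlation to ~0.52 and shift strongly skewed marginals (GSQS, diary)
upward by ~0.1–0.25 points; we document rather than compensate this, so
`latent_r` means exactly what it says. The copula is not identifiable
from marginal summaries; the latent-Gaussian choice is the simplest
consistent one.

Outcomes are generated on the z-scale as
`y = u_study + β·f + covariate effects + ε`, with `u_study ~ N(0, τ)`
(default τ = 0.2), β the *true* standardized effect of latent disturbance
(default 0 — the evidence-for-null condition), and residual SD chosen so
the outcome variance is ~1; each outcome is then rescaled to its published
mean/SD. Because the observed predictor is the PSQI+AIS composite — a
noisy indicator correlating ~0.84 with *f* — a true β = 0.3 yields fitted
standardized coefficients centred near 0.25; recovery tests account for
this attenuation, which is a property of the measurement design, not a
bug. Six executive-function scores are set missing by default, mirroring
the technical data loss in the real cohort. Every dataset carries a truth
sidecar (realized intercepts, β, residual SDs, latent factor).

The ASRT simulator writes a deterministic RT surface — base RT, linear
skill drift (total default 39.4 ms across the session), a high-frequency
advantage (default 16.7 ms) and an extra pattern advantage (default
12.2 ms) — recentred so the included-trial mean sits at `base_rt`, then
multiplies by mean-preserving lognormal noise `exp(N(−σ²/2, σ²))`
(σ = 0.11, giving ~40 ms RT SD at 360 ms and right-skewed RTs; the
mean-preserving form keeps cell means exactly equal to the deterministic
structure, so injected effects are recovered without bias). Accuracy is
Bernoulli with logit shifts parametrized on the probability scale at the
low-frequency baseline (default 0.87, +0.035 high-frequency, +0.01
pattern, +0.02 skill drift). Defaults were calibrated once to the
published pooled means — RT triplet ≈ 26.5 ms, statistical ≈ 16.7 ms,
average RT ≈ 360 ms, ACC triplet ≈ 0.04 — under the identity
`triplet = statistical + 0.8 × higher-order`; the published triplet and
higher-order means cannot both be hit under that identity, and the
triplet/statistical anchors were preferred.

What the generator does **not** emulate: item-level questionnaire
responses, time-of-day/circadian structure, heavy-tailed or floor-effect
outcome distributions, participant-level heterogeneity in ASRT learning
rates, and any real dependence between sleep and cognition beyond the
injected linear effect. Passing simulation tests therefore establishes
that the *pipeline* is correct and calibrated under its assumed data
model — not that the substantive null result generalises to real data.

## Problem sizes and tolerances

Simulation checks run at the cohort's own size (n = 235, 3 studies):
200 replications for Bayes-factor behaviour and recovery, 500 for
bootstrap calibration with B = 200 resamples, ~10⁴ trials per participant
for ASRT recovery, ≥10⁵ classifiable trials for triplet combinatorics.
Closed-form checks (eigenvalue, BF limit, Bartlett) use machine-precision
or 1e-6 tolerances; stochastic checks use tolerances derived from their
Monte-Carlo standard errors. Random-intercept SD recovery is only checked
within ±50%: three groups carry very little information about τ, and ML
shrinks it further — reporting this honestly is preferable to widening
the model.

## Known limitations

- Three clusters is the minimum credible setting for a random intercept;
  τ² estimates are noisy and often at the boundary. The fitter handles
  the boundary cleanly but the between-study variance itself should not
  be interpreted.
- The bootstrap p-value is sign-based and floored at 1/B; with B = 200
  its resolution is 0.01 and it is mildly anticonservative in the tails.
- The Huber-model Bayes factor inherits the OLS-BIC approximation.
- The generator's scale marginals are normal-latent discretizations; for
  strongly skewed scales the realized means sit slightly above target.
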
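"""Association models: sleep predictors vs. cognitive outcomes.

For each cognitive outcome and sleep predictor the package fits a linear
mixed model with a random intercept by study (the pooled three-study
analysis), or a Huber robust regression without random effects (the
Study-2-only diary/GSQS analyses). The reported quantities per model are:

* ``beta_std`` — the standardized coefficient of the sleep predictor
  (outcome and continuous predictors z-scored before fitting, gender
  effect-coded ±1), controlled for age, gender and morningness;
* a nonparametric cluster (study-stratified) bootstrap percentile 95% CI
  and two-sided bootstrap p-value;
* ``bf01`` — the Bayes factor in favour of the null, from the BIC
  approximation ``BF01 = exp((BIC_full − BIC_null) / 2)``, where the null
  model contains the confounders (and the random intercept) only. Both
  models are fitted by full ML on identical rows. BF01 between 3 and 10 is
  conventionally read as substantial evidence for the null.

Listwise deletion is applied per model, so outcomes with missing values
(e.g. executive-function scores) are analysed on fewer rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lmm import LMMFit, RandomInterceptSuffStats, fit_random_intercept_ml

__all__ = [
    "OUTCOMES",
    "ModelSpec",
    "AssociationResult",
    "ModelFitError",
    "fit_model",
    "bootstrap_inference",
    "bf01_from_bic",
    "bf01_interpretation",
    "robust_regression",
    "compare_extreme_groups",
    "associate",
]

#: The twelve cognitive outcome metrics, in reporting order.
OUTCOMES: tuple[str, ...] = (
    "acc_higher_order",
    "acc_statistical",
    "acc_triplet",
    "rt_higher_order",
    "rt_statistical",
    "rt_triplet",
    "acc_general_skill",
    "acc_average",
    "rt_average",
    "rt_general_skill",
    "counting_span",
    "wcst_persev_err",
)

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "gender", "meq")


class ModelFitError(RuntimeError):
    """A model could not be fitted (degenerate design or data)."""


@dataclass(frozen=True)
class ModelSpec:
    """One outcome × one sleep predictor, with the fixed confounder set."""

    outcome: str
    predictor: str = "sleep_disturbance"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    grouping: str = "study"
    estimator: str = "lmm_ml"  # "lmm_ml" | "robust_lm"


@dataclass
class AssociationResult:
    """Standardized association of one sleep predictor with one outcome."""

    outcome: str
    predictor: str
    beta_std: float
    ci_low: float
    ci_high: float
    df: int
    p_boot: float
    bf01: float
    n_used: int
    estimator: str = "lmm_ml"
    t: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "beta_std": self.beta_std,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "df": self.df,
            "p": self.p_boot,
            "bf01": self.bf01,
            "n_used": self.n_used,
            "estimator": self.estimator,
        }


@dataclass
class _Design:
    """Standardized design built from one model spec (post listwise deletion)."""

    y: np.ndarray
    X: np.ndarray  # columns: intercept, predictor, covariates...
    groups: np.ndarray  # integer codes 0..g-1
    names: list[str]
    n_used: int
    row_index: pd.Index
    group_levels: np.ndarray = field(default=None)


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ModelFitError(f"zero variance in {what}: cannot standardize")
    return (x - x.mean()) / sd


def build_design(spec: ModelSpec, data: pd.DataFrame) -> _Design:
    """Standardize and assemble the model design with listwise deletion.

    The outcome and all continuous regressors are z-scored (sample SD);
    gender is effect-coded (M = +1, F = −1), so the predictor coefficient
    is a standardized partial regression coefficient.
    """
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    needed = cols + ([spec.grouping] if spec.estimator == "lmm_ml" else [])
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ModelFitError(f"missing columns: {missing}")
    sub = data[needed].dropna()
    n = len(sub)
    if n < len(cols) + 2:
        raise ModelFitError(f"too few complete rows ({n}) for {spec.outcome}")

    def column(name: str) -> np.ndarray:
        col = sub[name]
        if name == "gender" or col.dtype == object:
            vals = col.astype(str).str.upper()
            bad = set(vals.unique()) - {"M", "F"}
            if bad:
                raise ModelFitError(f"gender must be coded M/F, got {sorted(bad)}")
            return np.where(vals == "M", 1.0, -1.0)
        return _zscore(col.to_numpy(dtype=float), name)

    y = _zscore(sub[spec.outcome].to_numpy(dtype=float), spec.outcome)
    X = np.column_stack(
        [np.ones(n), column(spec.predictor)] + [column(c) for c in spec.covariates]
    )
    if spec.estimator == "lmm_ml":
        levels, groups = np.unique(sub[spec.grouping].to_numpy(), return_inverse=True)
    else:
        levels, groups = np.array([0]), np.zeros(n, dtype=int)
    return _Design(
        y=y,
        X=X,
        groups=groups,
        names=["intercept", spec.predictor, *spec.covariates],
        n_used=n,
        row_index=sub.index,
        group_levels=levels,
    )


@dataclass
class ModelFitResult:
    """Full and null ML fits of one association model, on identical rows."""

    spec: ModelSpec
    design: _Design
    full: LMMFit
    null: LMMFit
    beta_std: float
    bf01: float

    @property
    def df_resid(self) -> int:
        return self.full.df_resid

    @property
    def n_used(self) -> int:
        return self.design.n_used


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFitResult:
    """Fit the full (with predictor) and null (confounders-only) models.

    Both are fitted by full ML on the same listwise-deleted rows, so their
    BICs are comparable; ``bf01`` is computed from the BIC difference.
    Zero between-study variance is handled by the boundary (OLS-limit) fit,
    never by a crash.
    """
    d = build_design(spec, data)
    stats_full = RandomInterceptSuffStats.from_arrays(d.X, d.y, d.groups)
    full = fit_random_intercept_ml(stats=stats_full)
    null = fit_random_intercept_ml(stats=stats_full.drop_column(1))
    return ModelFitResult(
        spec=spec,
        design=d,
        full=full,
        null=null,
        beta_std=float(full.beta[1]),
        bf01=bf01_from_bic(full.bic, null.bic),
    )


def bf01_from_bic(bic_full: float, bic_null: float) -> float:
    """Bayes factor for the null from the BIC approximation.

    ``BF01 = exp((BIC_full − BIC_null) / 2)``; values above 1 favour the
    confounders-only model. Requires both BICs computed by ML on identical
    rows (enforced by the callers in this module).
    """
    return float(math.exp((bic_full - bic_null) / 2.0))


def bf01_interpretation(bf01: float) -> str:
    """Conventional evidence bands for BF01."""
    if bf01 <= 0:
        raise ValueError("BF01 must be positive")
    bands = [
        (1 / 100, "extreme evidence for H1"),
        (1 / 30, "very strong evidence for H1"),
        (1 / 10, "strong evidence for H1"),
        (1 / 3, "substantial evidence for H1"),
        (1.0, "anecdotal evidence for H1"),
        (3.0, "anecdotal evidence for H0"),
        (10.0, "substantial evidence for H0"),
    ]
    for upper, label in bands:
        if bf01 < upper:
            return label
    return "strong evidence for H0"


def _stratified_indices(
    groups: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B × n resample index matrix, resampling rows within each group."""
    chunks = []
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        chunks.append(rows[rng.integers(0, rows.size, size=(B, rows.size))])
    return np.concatenate(chunks, axis=1)


def _bootstrap_betas_lmm(d: _Design, B: int, rng: np.random.Generator) -> np.ndarray:
    """Predictor coefficients over B stratified cluster resamples.

    Sufficient statistics of all resamples are computed in one batched
    pass; each resample then needs only the 1-D likelihood profile.
    """
    idx = _stratified_indices(d.groups, B, rng)
    Xb = d.X[idx]  # B x n x p
    yb = d.y[idx]  # B x n
    gb = d.groups[idx[0]]  # stratified: group layout identical across resamples
    XtX = np.einsum("bni,bnj->bij", Xb, Xb, optimize=True)
    Xty = np.einsum("bni,bn->bi", Xb, yb, optimize=True)
    yty = np.einsum("bn,bn->b", yb, yb)
    g_levels = np.unique(gb)
    slices = [np.flatnonzero(gb == g) for g in g_levels]
    Sx = np.stack([Xb[:, s, :].sum(axis=1) for s in slices], axis=1)  # B x g x p
    sy = np.stack([yb[:, s].sum(axis=1) for s in slices], axis=1)  # B x g
    sizes = np.array([s.size for s in slices], dtype=float)

    betas = np.empty(B)
    n_failed = 0
    for b in range(B):
        stats = RandomInterceptSuffStats(
            XtX=XtX[b], Xty=Xty[b], yty=float(yty[b]),
            Sx=Sx[b], sy=sy[b], sizes=sizes, n=d.X.shape[0],
        )
        try:
            betas[b] = fit_random_intercept_ml(stats=stats).beta[1]
        except np.linalg.LinAlgError:
            betas[b] = np.nan
            n_failed += 1
    if n_failed > 0.1 * B:
        raise ModelFitError(
            f"bootstrap unstable: {n_failed}/{B} resample refits failed"
        )
    return betas[np.isfinite(betas)]


def _percentile_ci_p(betas: np.ndarray, B: int) -> tuple[float, float, float]:
    ci_low, ci_high = np.percentile(betas, [2.5, 97.5])
    n_le = int((betas <= 0).sum())
    n_ge = int((betas >= 0).sum())
    p = 2.0 * min(n_le, n_ge) / betas.size
    p = min(max(p, 1.0 / B), 1.0)
    return float(ci_low), float(ci_high), float(p)


def bootstrap_inference(
    spec: ModelSpec,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[tuple[float, float], float, np.ndarray]:
    """Cluster-bootstrap CI and p-value for the predictor coefficient.

    Nonparametric case resampling stratified by study; percentile 95% CI;
    two-sided sign-based p-value ``2·min(#{β* ≤ 0}, #{β* ≥ 0})/B`` floored
    at ``1/B``. Deterministic for a fixed seed.

    Returns ``((ci_low, ci_high), p_boot, beta_samples)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = build_design(spec, data)
    if spec.estimator == "robust_lm":
        betas = _bootstrap_betas_robust(d, B, rng)
    else:
        betas = _bootstrap_betas_lmm(d, B, rng)
    ci_low, ci_high, p = _percentile_ci_p(betas, B)
    return (ci_low, ci_high), p, betas


def _huber_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT())
    return np.asarray(model.fit().params)


def _bootstrap_betas_robust(d: _Design, B: int, rng: np.random.Generator) -> np.ndarray:
    idx = _stratified_indices(d.groups, B, rng)
    betas = np.empty(B)
    n_failed = 0
    for b in range(B):
        try:
            betas[b] = _huber_fit(d.X[idx[b]], d.y[idx[b]])[1]
        except (np.linalg.LinAlgError, ValueError):
            betas[b] = np.nan
            n_failed += 1
    if n_failed > 0.1 * B:
        raise ModelFitError(
            f"bootstrap unstable: {n_failed}/{B} resample refits failed"
        )
    return betas[np.isfinite(betas)]


def _ols_bic(X: np.ndarray, y: np.ndarray) -> float:
    """Gaussian ML BIC of an OLS fit, k = p + 1 (residual variance counted)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return -2.0 * ll + (p + 1) * math.log(n)


def robust_regression(
    spec: ModelSpec,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AssociationResult:
    """Huber M-estimated regression without random effects (Study-2 scales).

    Standardization, covariates and the bootstrap mirror the mixed-model
    pipeline. The Bayes factor uses the Gaussian-likelihood BIC of the
    equivalent OLS fits (full vs. confounders-only) — an approximation,
    since the Huber likelihood is not Gaussian; documented as such.
    """
    spec = ModelSpec(
        outcome=spec.outcome, predictor=spec.predictor,
        covariates=spec.covariates, grouping=spec.grouping, estimator="robust_lm",
    )
    d = build_design(spec, data)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = _huber_fit(d.X, d.y)
    beta = float(params[1])
    rlm_fit = sm.RLM(d.y, d.X, M=sm.robust.norms.HuberT()).fit()
    t = float(rlm_fit.params[1] / rlm_fit.bse[1])
    bf01 = bf01_from_bic(_ols_bic(d.X, d.y), _ols_bic(np.delete(d.X, 1, axis=1), d.y))
    betas = _bootstrap_betas_robust(d, B, rng)
    ci_low, ci_high, p = _percentile_ci_p(betas, B)
    return AssociationResult(
        outcome=spec.outcome,
        predictor=spec.predictor,
        beta_std=beta,
        ci_low=ci_low,
        ci_high=ci_high,
        df=d.n_used - d.X.shape[1],
        p_boot=p,
        bf01=bf01,
        n_used=d.n_used,
        estimator="robust_lm",
        t=t,
    )


def compare_extreme_groups(
    data: pd.DataFrame,
    good: pd.Index,
    poor: pd.Index,
    outcomes: Sequence[str] = OUTCOMES,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Compare good vs. poor sleepers (extreme PSQI groups) on each outcome.

    Per outcome: Welch two-sample t-test, Cohen's d (pooled SD), and a BF01
    from the BIC of OLS models with/without the group factor, retaining the
    confounders. Requires at least 3 participants per group.
    """
    if len(good) < 3 or len(poor) < 3:
        raise ModelFitError(
            f"extreme groups too small (good={len(good)}, poor={len(poor)}); "
            "need at least 3 per group"
        )
    from scipy import stats as sps

    rows = []
    grp = pd.concat(
        [data.loc[good].assign(_grp=-1.0), data.loc[poor].assign(_grp=1.0)]
    )
    for outcome in outcomes:
        cols = [outcome, "_grp", *covariates]
        sub = grp[cols].dropna()
        g0 = sub.loc[sub["_grp"] < 0, outcome].to_numpy(dtype=float)
        g1 = sub.loc[sub["_grp"] > 0, outcome].to_numpy(dtype=float)
        if g0.size < 3 or g1.size < 3:
            raise ModelFitError(f"extreme groups too small for {outcome}")
        t, p = sps.ttest_ind(g1, g0, equal_var=False)
        sp = math.sqrt(
            ((g0.size - 1) * g0.var(ddof=1) + (g1.size - 1) * g1.var(ddof=1))
            / (g0.size + g1.size - 2)
        )
        d_eff = (g1.mean() - g0.mean()) / sp if sp > 0 else 0.0

        spec = ModelSpec(outcome=outcome, predictor="_grp", estimator="robust_lm",
                         covariates=tuple(covariates))
        dsg = build_design(spec, sub)
        bf01 = bf01_from_bic(
            _ols_bic(dsg.X, dsg.y), _ols_bic(np.delete(dsg.X, 1, axis=1), dsg.y)
        )
        rows.append(
            {
                "outcome": outcome,
                "mean_good": float(g0.mean()),
                "mean_poor": float(g1.mean()),
                "difference": float(g1.mean() - g0.mean()),
                "cohens_d": float(d_eff),
                "t_welch": float(t),
                "p_welch": float(p),
                "bf01": bf01,
                "n_good": int(g0.size),
                "n_poor": int(g1.size),
            }
        )
    return pd.DataFrame(rows)


def associate(
    data: pd.DataFrame,
    predictor: str = "sleep_disturbance",
    outcomes: Sequence[str] = OUTCOMES,
    estimator: str = "lmm_ml",
    B: int = 1000,
    seed: int = 0,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Fit one association model per outcome; returns a results table.

    Each outcome gets an independent bootstrap stream derived from ``seed``,
    so the table is reproducible and insensitive to outcome order.
    """
    rows = []
    base = np.random.SeedSequence(seed)
    for outcome, child in zip(outcomes, base.spawn(len(outcomes))):
        spec = ModelSpec(
            outcome=outcome, predictor=predictor,
            covariates=tuple(covariates), estimator=estimator,
        )
        rng = np.random.default_rng(child)
        if estimator == "robust_lm":
            res = robust_regression(spec, data, B=B, seed=rng)
        else:
            fit = fit_model(spec, data)
            (ci_low, ci_high), p, _ = bootstrap_inference(spec, data, B=B, seed=rng)
            res = AssociationResult(
                outcome=outcome,
                predictor=predictor,
                beta_std=fit.beta_std,
                ci_low=ci_low,
                ci_high=ci_high,
                df=fit.df_resid,
                p_boot=p,
                bf01=fit.bf01,
                n_used=fit.n_used,
                estimator="lmm_ml",
                t=float(fit.full.beta[1] / fit.full.se[1]),
            )
        rows.append(res.as_dict())
    return pd.DataFrame(rows)
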
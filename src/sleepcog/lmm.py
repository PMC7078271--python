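"""Maximum-likelihood linear mixed model with a single random intercept.

The model is ``y = X b + u_g + e`` with ``u_g ~ N(0, tau2)`` per group and
``e ~ N(0, sigma2)``. Writing ``lambda = tau2 / sigma2``, the marginal
covariance is ``sigma2 * (I + lambda Z Z')`` with Z the group-membership
indicator, so for fixed ``lambda`` the GLS estimate of ``b`` and the
profiled ``sigma2`` are closed-form (Sherman–Morrison within each group).
The fitter profiles the log-likelihood down to a smooth one-dimensional
function of ``lambda`` and optimises it by bounded scalar search.

Everything is expressed through per-group sufficient statistics
(``X'X``, ``X'y``, ``y'y``, group sums), which makes a single fit a few
microseconds of linear algebra — the cluster bootstrap and the simulation
studies in this package refit the model ~10^5 times, so this matters.
statsmodels' ``MixedLM`` fits the identical model and serves as the
independent cross-check in the test suite.

ML (not REML) is used throughout: the Bayes-factor computation compares
BICs of models with different fixed-effect structures, which is only
meaningful under full ML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["LMMFit", "fit_random_intercept_ml", "RandomInterceptSuffStats"]

_LOG_LAM_LO, _LOG_LAM_HI = -14.0, 14.0
_BOUNDARY_LAM = 1e-5


@dataclass
class LMMFit:
    """ML fit of a random-intercept model."""

    beta: np.ndarray
    se: np.ndarray
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    loglik: float
    bic: float
    n: int
    k_fixed: int
    df_resid: int  # n - k_fixed
    boundary: bool  # True if tau2 was estimated at (numerically) zero


@dataclass
class RandomInterceptSuffStats:
    """Sufficient statistics of (X, y, groups) for the profiled likelihood."""

    XtX: np.ndarray  # p x p
    Xty: np.ndarray  # p
    yty: float
    Sx: np.ndarray  # g x p group-wise column sums of X
    sy: np.ndarray  # g group-wise sums of y
    sizes: np.ndarray  # g group sizes
    n: int

    @classmethod
    def from_arrays(
        cls, X: np.ndarray, y: np.ndarray, groups: np.ndarray
    ) -> "RandomInterceptSuffStats":
        """``groups`` must be integer codes 0..g-1."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        g = int(groups.max()) + 1
        p = X.shape[1]
        Sx = np.zeros((g, p))
        np.add.at(Sx, groups, X)
        sy = np.bincount(groups, weights=y, minlength=g)
        sizes = np.bincount(groups, minlength=g).astype(float)
        return cls(
            XtX=X.T @ X,
            Xty=X.T @ y,
            yty=float(y @ y),
            Sx=Sx,
            sy=sy,
            sizes=sizes,
            n=X.shape[0],
        )

    def drop_column(self, j: int) -> "RandomInterceptSuffStats":
        """Sufficient statistics of the design without column ``j``."""
        keep = [i for i in range(self.XtX.shape[0]) if i != j]
        return RandomInterceptSuffStats(
            XtX=self.XtX[np.ix_(keep, keep)],
            Xty=self.Xty[keep],
            yty=self.yty,
            Sx=self.Sx[:, keep],
            sy=self.sy,
            sizes=self.sizes,
            n=self.n,
        )


def _profile(lam: float, s: RandomInterceptSuffStats):
    """Profiled quantities at a fixed variance ratio lambda.

    Returns (negative log-likelihood, beta, A) where A = X' Vtilde^-1 X.
    """
    w = lam / (1.0 + lam * s.sizes)  # per-group Sherman-Morrison weight
    A = s.XtX - (s.Sx.T * w) @ s.Sx
    b = s.Xty - s.Sx.T @ (w * s.sy)
    beta = np.linalg.solve(A, b)
    q = s.yty - float(w @ (s.sy**2)) - float(beta @ b)
    q = max(q, 1e-300)
    sigma2 = q / s.n
    logdet = float(np.log1p(lam * s.sizes).sum())
    ll = -0.5 * (s.n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)
    return -ll, beta, A


def fit_random_intercept_ml(
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    stats: RandomInterceptSuffStats | None = None,
    n_variance_params: int = 2,
) -> LMMFit:
    """Fit ``y = X b + u_group + e`` by profiled maximum likelihood.

    Either pass raw arrays (``groups`` as integer codes ``0..g-1``) or
    precomputed :class:`RandomInterceptSuffStats` (the bootstrap path).

    ``BIC = -2 loglik + k ln(n)`` with ``k = p + n_variance_params`` and
    ``n`` the number of observations (not groups). When the likelihood is
    maximised at zero between-group variance the fit degenerates to OLS
    and is flagged ``boundary=True`` (never an error: pooled cohorts with
    tiny study differences land here legitimately).
    """
    if stats is None:
        stats = RandomInterceptSuffStats.from_arrays(X, y, groups)
    s = stats

    def nll_log(u: float) -> float:
        return _profile(np.exp(u), s)[0]

    res = minimize_scalar(
        nll_log, bounds=(_LOG_LAM_LO, _LOG_LAM_HI), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    nll0, _, _ = _profile(0.0, s)
    if nll0 <= res.fun:  # boundary: no between-group variance
        lam = 0.0
    boundary = lam < _BOUNDARY_LAM

    nll, beta, A = _profile(lam, s)
    q = s.yty - float((lam / (1.0 + lam * s.sizes)) @ (s.sy**2)) - float(
        beta @ (s.Xty - s.Sx.T @ ((lam / (1.0 + lam * s.sizes)) * s.sy))
    )
    sigma2 = max(q, 1e-300) / s.n
    tau2 = lam * sigma2
    p = beta.size
    k = p + n_variance_params
    loglik = -nll
    bic = -2.0 * loglik + k * np.log(s.n)
    cov = np.linalg.inv(A) * sigma2
    se = np.sqrt(np.diag(cov))
    return LMMFit(
        beta=beta,
        se=se,
        sigma2=float(sigma2),
        tau2=float(tau2),
        loglik=float(loglik),
        bic=float(bic),
        n=s.n,
        k_fixed=p,
        df_resid=s.n - p,
        boundary=bool(boundary),
    )
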
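"""Sleep-disturbance composite: first principal component of PSQI and AIS.

The two questionnaire totals are z-scored and combined by principal
component analysis of their correlation matrix. With two standardized
variables the first eigenvalue is exactly ``1 + r`` and the component is
proportional to ``z_psqi + z_ais``; scores are rescaled to unit variance
and oriented so that both loadings are positive — higher values mean more
disturbed sleep. Bartlett's test of sphericity checks that the inter-scale
correlation is large enough for a PCA to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CompositeResult", "bartlett_sphericity", "fit_composite"]


@dataclass
class CompositeResult:
    """First-principal-component summary of the sleep scales."""

    scores: np.ndarray  # one sleep-disturbance value per participant, unit variance
    eigenvalue_first: float
    variance_explained: float  # eigenvalue_first / n_variables
    loadings: np.ndarray  # per-scale weights, all positive after orientation
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def bartlett_sphericity(data: np.ndarray, n: int | None = None) -> tuple[float, int, float]:
    """Bartlett's test of sphericity (H0: correlation matrix is identity).

    ``data`` is either an ``n × p`` data matrix or, if ``n`` is given, a
    ``p × p`` correlation matrix. The statistic is

    ``chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R)``, with ``df = p(p-1)/2``.
    """
    data = np.asarray(data, dtype=float)
    if n is None:
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("need an n x p data matrix with p >= 2")
        n, p = data.shape
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
        corr = np.corrcoef(data, rowvar=False)
    else:
        corr = data
        p = corr.shape[0]
        if corr.shape != (p, p) or p < 2:
            raise ValueError("correlation matrix must be p x p with p >= 2")
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular correlation matrix: Bartlett's test undefined")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def fit_composite(psqi: np.ndarray, ais: np.ndarray) -> CompositeResult:
    """Combine PSQI and AIS totals into the sleep-disturbance score.

    Both inputs are z-scored (sample SD, ddof=1); the first eigenvector of
    their 2×2 correlation matrix defines the component. Scores are scaled
    to unit variance and oriented so that both loadings are positive.

    Raises ``ValueError`` on length mismatch, missing values, or a
    zero-variance input.
    """
    psqi = np.asarray(psqi, dtype=float)
    ais = np.asarray(ais, dtype=float)
    if psqi.shape != ais.shape or psqi.ndim != 1:
        raise ValueError("psqi and ais must be 1-D vectors of equal length")
    if np.isnan(psqi).any() or np.isnan(ais).any():
        raise ValueError("missing values are not allowed; drop them upstream")
    X = np.column_stack([psqi, ais])
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        which = ["psqi", "ais"][int(np.argmin(sd))]
        raise ValueError(f"zero-variance input: {which}")
    Z = (X - X.mean(axis=0)) / sd

    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    lam1 = float(eigvals[order[0]])
    v1 = eigvecs[:, order[0]]
    if v1.sum() < 0:  # orient: positive loadings, higher = more disturbed
        v1 = -v1
    if np.any(v1 < 0):
        raise ValueError(
            "scales load in opposite directions (negative correlation); "
            "a single disturbance component is not interpretable"
        )

    raw = Z @ v1
    raw_sd = raw.std(ddof=1)
    scores = raw / raw_sd if raw_sd > 0 else raw

    try:
        chi2, df, pval = bartlett_sphericity(Z)
    except ValueError:
        # perfectly collinear scales: PCA is still defined, Bartlett is not
        chi2, df, pval = float("inf"), 1, 0.0

    return CompositeResult(
        scores=scores,
        eigenvalue_first=lam1,
        variance_explained=lam1 / 2.0,
        loadings=v1,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
    )
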
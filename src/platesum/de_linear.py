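"""Precision-weighted moderated linear models on log-CPMs.

The voom/limma family: log-CPM values are modelled with a normal
distribution whose mean-variance relationship is captured empirically by a
LOWESS trend of the residual standard deviation against average log count.
Inverse fourth-power trend values at each observation's predicted count
give precision weights for weighted least squares; the per-gene residual
variances are then squeezed towards a common prior by empirical Bayes
(a scaled inverse-chi-squared prior fitted by log-F moment matching), and
contrasts are tested with moderated t-statistics on augmented degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .normalize import cpm
from .pseudobulk import residual_df
from .result import DEResult

__all__ = [
    "WeightedExpression",
    "ModeratedFit",
    "voom_transform",
    "fit_weighted_lm",
    "squeeze_variances",
    "moderated_t_test",
    "voom_pipeline",
]

LOWESS_FRAC = 0.5
LOWESS_ITER = 3


@dataclass(frozen=True)
class WeightedExpression:
    """log-CPM matrix with per-observation precision weights.

    ``trend_x``/``trend_y`` tabulate the fitted monotone-interpolated
    mean -> sqrt(residual sd) trend on the average-log2-count axis.
    """

    logcpm: np.ndarray
    weights: np.ndarray
    trend_x: np.ndarray
    trend_y: np.ndarray

    def __post_init__(self) -> None:
        if self.logcpm.shape != self.weights.shape:
            raise ValueError("logcpm and weights must have identical shapes")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and strictly positive")

    def trend(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the fitted trend, clamped to its boundary values."""
        return np.interp(x, self.trend_x, self.trend_y)


@dataclass(frozen=True)
class ModeratedFit:
    """Weighted least-squares fit with EB-moderated variances."""

    coefficients: np.ndarray  # gene x coefficient
    residual_df: int
    s2: np.ndarray  # per-gene residual variance
    cov_unscaled: np.ndarray  # gene x p x p, (X' W X)^{-1}
    d0: float  # prior degrees of freedom (may be inf)
    s0_2: float  # prior variance
    s2_post: np.ndarray  # per-gene posterior variance


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-gene ordinary least squares for a shared design. y: gene x n."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    df = residual_df(n, p)
    pinv = np.linalg.pinv(X)
    coef = y @ pinv.T
    fitted = coef @ X.T
    s2 = np.square(y - fitted).sum(axis=1) / df
    return coef, fitted, df


def _fit_lowess_trend(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    out = sm_lowess(y, x, frac=LOWESS_FRAC, it=LOWESS_ITER, return_sorted=True)
    tx, ty = out[:, 0], out[:, 1]
    # collapse ties on x so np.interp sees strictly increasing knots
    ux, inverse = np.unique(tx, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inverse, ty)
    np.add.at(counts, inverse, 1.0)
    return ux, np.maximum(uy / counts, 1e-6)


def voom_transform(
    counts: np.ndarray, size_factors: np.ndarray, design_matrix: np.ndarray
) -> WeightedExpression:
    """Compute log-CPMs and inverse-variance precision weights.

    Fits OLS per gene, estimates the sqrt-residual-sd vs average-log2-count
    LOWESS trend, maps each observation's predicted count through the trend
    and returns ``trend(pred)**-4`` as its weight. Trend evaluation outside
    the fitted range is clamped to the boundary values.
    """
    counts = np.asarray(counts, dtype=np.float64)
    lib = np.asarray(size_factors, dtype=np.float64)
    logcpm = cpm(counts, lib, log=True, prior_count=0.5)
    coef, fitted, df = _ols(logcpm, design_matrix)

    # average log2-count per gene (shift log-CPM back onto the count scale)
    shift = np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    ave_log_count = logcpm.mean(axis=1) + shift
    sqrt_sd = np.sqrt(np.sqrt(np.square(logcpm - fitted).sum(axis=1) / df))

    trend_x, trend_y = _fit_lowess_trend(ave_log_count, sqrt_sd)

    pred_log_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    w = np.interp(pred_log_count, trend_x, trend_y) ** -4
    return WeightedExpression(logcpm=logcpm, weights=w, trend_x=trend_x, trend_y=trend_y)


def fit_weighted_lm(
    y: np.ndarray, X: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Weighted least squares, vectorized over genes.

    ``y`` and ``w`` may be 1-D (one gene) or gene x sample matrices with a
    shared design. Returns ``(beta, s2, residual_df, cov_unscaled)`` where
    ``s2`` is the weighted residual sum of squares over the residual d.f.
    and ``cov_unscaled`` is ``(X' W X)^{-1}`` per gene.
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    w = np.atleast_2d(np.asarray(w, dtype=np.float64))
    if y.shape != w.shape:
        raise ValueError("y and w must share a shape")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and strictly positive")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    df = residual_df(n, p)
    A = np.einsum("gn,np,nq->gpq", w, X, X, optimize=True)
    b = np.einsum("gn,np->gp", w * y, X, optimize=True)
    cov = np.linalg.inv(A)
    beta = np.einsum("gpq,gq->gp", cov, b)
    resid = y - beta @ X.T
    s2 = np.einsum("gn,gn->g", w, resid**2) / df
    return beta, s2, df, cov


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, residual_df: int) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes squeezing of per-gene variances.

    Fits a scaled inverse-chi-squared prior (``d0``, ``s0_2``) by matching
    the first two moments of ``log s2`` to the log-F distribution
    (digamma/trigamma inversion) and returns the posterior variances
    ``(d0*s0_2 + df*s2) / (d0 + df)``. If the observed spread of log
    variances does not exceed the chi-squared sampling spread, the prior is
    degenerate: ``d0 = inf`` and every posterior equals ``s0_2``.
    """
    s2 = np.asarray(s2, dtype=np.float64)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    df = float(residual_df)
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
        s2_post = np.full_like(s2, s0_2)
    return d0, s0_2, s2_post


def moderated_t_test(fit: ModeratedFit, contrast) -> DEResult:
    """Moderated t-test of a contrast of the fitted coefficients.

    ``contrast`` is a coefficient index or a contrast vector. The statistic
    divides the contrast estimate by its standard error computed from the
    posterior variance; p-values are two-sided from a t distribution with
    ``d0 + residual_df`` degrees of freedom (normal when ``d0`` is
    infinite). The estimate is on the log2 scale of the log-CPMs.
    """
    p = fit.coefficients.shape[1]
    if np.isscalar(contrast):
        c = np.zeros(p)
        c[int(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=np.float64)
        if c.shape != (p,):
            raise ValueError(f"contrast must have length {p}")
    var_unscaled = np.einsum("p,gpq,q->g", c, fit.cov_unscaled, c)
    if np.any(var_unscaled <= 0):
        raise ValueError("contrast is not estimable under this design")
    est = fit.coefficients @ c
    se = np.sqrt(fit.s2_post * var_unscaled)
    t = est / se
    df_total = fit.d0 + fit.residual_df
    if np.isfinite(df_total):
        pval = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        pval = 2.0 * stats.norm.sf(np.abs(t))
    return DEResult(log2fc=est, stat=t, pvalue=pval)


def voom_pipeline(
    counts: np.ndarray,
    size_factors: np.ndarray,
    design_matrix: np.ndarray,
    contrast=-1,
) -> DEResult:
    """Full pipeline: voom weights -> WLS -> EB squeezing -> moderated t."""
    we = voom_transform(counts, size_factors, design_matrix)
    beta, s2, df, cov = fit_weighted_lm(we.logcpm, design_matrix, we.weights)
    d0, s0_2, s2_post = squeeze_variances(s2, df)
    if np.isscalar(contrast) and int(contrast) < 0:
        contrast = design_matrix.shape[1] + int(contrast)
    fit = ModeratedFit(
        coefficients=beta,
        residual_df=df,
        s2=s2,
        cov_unscaled=cov,
        d0=d0,
        s0_2=s0_2,
        s2_post=s2_post,
    )
    return moderated_t_test(fit, contrast)
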
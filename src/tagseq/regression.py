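"""Per-gene linear models for trait association.

The quantitative trait is the response and one gene's normalized
expression (plus optional covariates) the predictors:

    trait_i = b0 + b1 * expression_i + sum_p c_p * covariate_pi + e_i

Genes are called trait-associated by testing H0: b1 = 0.  Two estimators
are provided: ordinary least squares with the usual t test, and Huber's
M-estimator fitted by iteratively reweighted least squares (IRWLS) with a
Wald-type test built on a robust covariance estimate.  The robust fit
downweights samples whose residuals exceed ``k * sigma`` (tuning constant
k = 1.345 by default, sigma re-estimated each iteration by the normalized
median absolute deviation), so gross trait outliers do not drag the fitted
line the way they do under least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneFit",
    "Design",
    "build_design",
    "covariate_design",
    "fit_ols",
    "mad_scale",
    "huber_weight",
    "fit_huber_irwls",
    "robust_wald_test",
]

#: MAD consistency constant for the normal distribution.
MAD_CONSTANT = 0.6745

#: Default Huber tuning constant (95% efficiency at the Gaussian model).
DEFAULT_K = 1.345


@dataclass
class GeneFit:
    """One gene's fitted association model.

    ``params`` is ordered (intercept, expression slope, covariates...).
    For OLS fits all weights are exactly 1 and ``n_iter`` is 1; for robust
    fits ``weights``, ``scale`` and ``n_iter`` record the final IRWLS
    state and ``converged`` whether the coefficient tolerance was met.
    """

    gene_id: str | None
    method: str
    params: np.ndarray
    param_names: tuple[str, ...]
    se_beta1: float
    statistic: float
    df: int
    pvalue: float
    residuals: np.ndarray
    weights: np.ndarray
    scale: float
    n_iter: int
    converged: bool
    k: float | None = None
    design: np.ndarray | None = field(default=None, repr=False)
    dropped_samples: tuple = ()

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        return float(self.params[1])


@dataclass(frozen=True)
class Design:
    """Response vector and design matrix for one gene's model."""

    response: np.ndarray
    matrix: np.ndarray
    columns: tuple[str, ...]
    sample_ids: tuple
    dropped_samples: tuple


def build_design(
    phenotype: pd.DataFrame,
    expression: Sequence[float] | pd.Series,
    trait: str = "trait",
    covariates: Sequence[str] = (),
) -> Design:
    """Assemble (response, design matrix) for a single-gene model.

    Columns are ordered intercept, expression, then dummy-coded covariates
    (the first level of each categorical is the dropped reference).
    Samples with a missing value in any used column are removed and listed
    in ``dropped_samples``.

    Raises
    ------
    ValueError
        If the design is rank deficient (names the collinear columns) or
        there are no more samples than coefficients.
    """
    if trait not in phenotype.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype table")
    missing = [c for c in covariates if c not in phenotype.columns]
    if missing:
        raise ValueError(f"covariate column(s) not in phenotype table: {missing}")

    x = np.asarray(expression, dtype=float)
    if x.shape[0] != phenotype.shape[0]:
        raise ValueError(
            f"expression length {x.shape[0]} does not match "
            f"{phenotype.shape[0]} phenotype samples"
        )

    cov_names, cov_matrix = covariate_design(phenotype, covariates)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(x.shape[0]), "expression": x}
    for j, name in enumerate(cov_names):
        cols[name] = cov_matrix[:, j]

    y = phenotype[trait].to_numpy(dtype=float)
    table = np.column_stack(list(cols.values()))
    ok = np.isfinite(y) & np.all(np.isfinite(table), axis=1)
    dropped = tuple(phenotype.index[~ok])
    y, table = y[ok], table[ok]
    names = tuple(cols.keys())

    n, p = table.shape
    if n <= p:
        raise ValueError(
            f"{n} usable samples for {p} coefficients; need n > p"
        )
    if np.linalg.matrix_rank(table) < p:
        bad = _collinear_columns(table, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return Design(
        response=y,
        matrix=table,
        columns=names,
        sample_ids=tuple(phenotype.index[ok]),
        dropped_samples=dropped,
    )


def covariate_design(
    phenotype: pd.DataFrame, covariates: Sequence[str] = ()
) -> tuple[tuple[str, ...], np.ndarray]:
    """Dummy-coded covariate columns (no intercept, no expression).

    Numeric covariates pass through; categorical ones are dummy coded with
    the first level as the dropped reference.  Missing values stay NaN so
    callers can apply listwise deletion.  Returns (column names, n x q
    float matrix).
    """
    missing = [c for c in covariates if c not in phenotype.columns]
    if missing:
        raise ValueError(f"covariate column(s) not in phenotype table: {missing}")
    names: list[str] = []
    columns: list[np.ndarray] = []
    for name in covariates:
        col = phenotype[name]
        if pd.api.types.is_numeric_dtype(col):
            names.append(name)
            columns.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"categorical covariate {name!r} has a single level")
            # NaN categories come back as all-zero dummy rows; reinstate NaN
            # so listwise deletion sees them.
            na = col.isna().to_numpy()
            for dname in dummies.columns:
                v = dummies[dname].to_numpy()
                v[na] = np.nan
                names.append(str(dname))
                columns.append(v)
    matrix = (
        np.column_stack(columns)
        if columns
        else np.empty((phenotype.shape[0], 0))
    )
    return tuple(names), matrix


def _collinear_columns(x: np.ndarray, names: tuple[str, ...]) -> list[str]:
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(names)) if i >= len(diag) or diag[i] < tol]


def fit_ols(
    response: np.ndarray,
    design: np.ndarray,
    gene_id: str | None = None,
    param_names: tuple[str, ...] | None = None,
    dropped_samples: tuple = (),
) -> GeneFit:
    """Ordinary least squares with a t test on the expression slope.

    The slope's standard error uses the unbiased residual-variance
    estimate and the design's inverse Gram matrix; the two-sided p-value
    comes from the central t distribution with n - p degrees of freedom.
    A response with zero residual variance yields an indeterminate test
    (statistic and p-value NaN when the slope is also zero).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        raise ValueError("singular design matrix")
    resid = y - x @ beta
    df = n - p
    rss = float(resid @ resid)
    s2 = rss / df
    xtx_inv = np.linalg.inv(x.T @ x)
    # numerically-zero residual variance: inference is degenerate
    zero_rss = (
        rss
        <= (np.finfo(float).eps * max(1.0, float(np.abs(y).max()))) ** 2 * n * 100
    )
    if not zero_rss:
        se = float(np.sqrt(s2 * xtx_inv[1, 1]))
        statistic = float(beta[1] / se)
        pvalue = float(2.0 * stats.t.sf(abs(statistic), df))
    else:
        se = 0.0
        tiny_slope = abs(beta[1]) <= np.finfo(float).eps * max(
            1.0, float(np.abs(beta).max()))
        if tiny_slope:
            statistic, pvalue = np.nan, np.nan
        else:
            statistic, pvalue = np.inf * np.sign(beta[1]), 0.0
    return GeneFit(
        gene_id=gene_id,
        method="ols",
        params=beta,
        param_names=param_names or tuple(f"x{i}" for i in range(p)),
        se_beta1=se,
        statistic=statistic,
        df=df,
        pvalue=pvalue,
        residuals=resid,
        weights=np.ones(n),
        scale=float(np.sqrt(s2)),
        n_iter=1,
        converged=True,
        design=x,
        dropped_samples=dropped_samples,
    )


def mad_scale(residuals: np.ndarray) -> float:
    """Normalized median absolute deviation: ``median|r - median r| / 0.6745``.

    Consistent for the standard deviation under Gaussian residuals; raises
    ``ValueError`` when the residuals are all identical (zero scale).
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two residuals")
    s = float(np.median(np.abs(r - np.median(r))) / MAD_CONSTANT)
    if s == 0:
        raise ValueError("zero MAD scale: residuals are degenerate")
    return s


def huber_weight(residual, threshold: float):
    """Huber weight: 1 inside the threshold, ``threshold/|r|`` outside."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    r = np.abs(np.asarray(residual, dtype=float))
    with np.errstate(divide="ignore", over="ignore"):
        w = np.where(r <= threshold, 1.0, threshold / r)
    if w.ndim == 0:
        return float(w)
    return w


def fit_huber_irwls(
    response: np.ndarray,
    design: np.ndarray,
    k: float = DEFAULT_K,
    tol: float = 1e-8,
    max_iter: int = 100,
    gene_id: str | None = None,
    param_names: tuple[str, ...] | None = None,
    dropped_samples: tuple = (),
) -> GeneFit:
    """Huber M-estimation by iteratively reweighted least squares.

    Starts from the OLS fit; each iteration re-estimates the scale by
    :func:`mad_scale`, computes Huber weights at threshold ``k * scale``
    and refits by weighted least squares, until every coefficient changes
    by less than ``tol * max(1, |coefficient|)`` or ``max_iter`` is hit
    (recorded in ``converged``; non-convergence is not an exception).
    Inference fields are filled by the Wald-type test of
    :func:`robust_wald_test`.
    """
    if k <= 0:
        raise ValueError("tuning constant k must be positive")
    y = np.asarray(response, dtype=float)
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    ols = fit_ols(y, x, gene_id=gene_id, param_names=param_names)
    beta = ols.params.copy()
    resid = ols.residuals.copy()
    weights = np.ones(n)
    scale = np.nan
    converged = False
    n_iter = 0
    for _ in range(max_iter):
        scale = mad_scale(resid)
        weights = huber_weight(resid, k * scale)
        xw = x * weights[:, None]
        beta_new = np.linalg.solve(xw.T @ x, xw.T @ y)
        n_iter += 1
        delta = np.abs(beta_new - beta)
        beta = beta_new
        resid = y - x @ beta
        if np.all(delta < tol * np.maximum(1.0, np.abs(beta))):
            converged = True
            break
    fit = GeneFit(
        gene_id=gene_id,
        method="huber",
        params=beta,
        param_names=param_names or tuple(f"x{i}" for i in range(p)),
        se_beta1=np.nan,
        statistic=np.nan,
        df=n - p,
        pvalue=np.nan,
        residuals=resid,
        weights=weights,
        scale=scale,
        n_iter=n_iter,
        converged=converged,
        k=k,
        design=x,
        dropped_samples=dropped_samples,
    )
    fit.statistic, fit.df, fit.pvalue = robust_wald_test(fit)
    return fit


def robust_wald_test(fit: GeneFit) -> tuple[float, int, float]:
    """Wald-type test of the expression slope for a Huber fit.

    The slope variance is the Huber-corrected sandwich

        sigma^2 * [sum psi(r_i/sigma)^2 / (n-p)] / [mean psi'(r_i/sigma)]^2

    times the (1,1) element of the inverse Gram matrix, with
    ``psi(u) = clip(u, -k, k)``.  The statistic is beta1 / se and the
    two-sided p-value comes from the t distribution on n - p degrees of
    freedom.  When no residual exceeds the threshold this reduces exactly
    to the OLS t test.  The test is evaluated for non-converged fits too;
    callers should treat those with the ``converged`` flag in hand.

    Also stores ``se_beta1`` on the fit as a side effect.
    """
    if fit.design is None or fit.k is None:
        raise ValueError("robust_wald_test requires a fit from fit_huber_irwls")
    x = fit.design
    n, p = x.shape
    df = n - p
    u = fit.residuals / fit.scale
    psi = np.clip(u, -fit.k, fit.k)
    psi_prime_mean = float(np.mean(np.abs(u) <= fit.k))
    s2 = fit.scale**2 * float(np.sum(psi**2)) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    var = s2 / psi_prime_mean**2 * xtx_inv[1, 1]
    se = float(np.sqrt(var))
    fit.se_beta1 = se
    if se == 0:
        statistic = np.nan if fit.params[1] == 0 else np.inf * np.sign(fit.params[1])
        pvalue = np.nan if fit.params[1] == 0 else 0.0
    else:
        statistic = float(fit.params[1] / se)
        pvalue = float(2.0 * stats.t.sf(abs(statistic), df))
    return statistic, df, pvalue
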
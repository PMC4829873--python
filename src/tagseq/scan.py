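"""Genome-wide trait-association scans.

The central object is :class:`TagAssociation`, a statsmodels-style model
holding a normalized expression matrix and a phenotype table.  Its
``fit`` method runs the per-gene regression of the trait on each gene's
expression (plus covariates) — ordinary least squares or Huber-robust —
and returns a :class:`TagScanResults` carrying slopes, standard errors,
test statistics, raw and FDR-adjusted p-values and significance calls.

The per-gene models are exactly those of :mod:`tagseq.regression`; the
scan evaluates them in a batched (vectorized) form so genome-wide sweeps
and permutation simulations stay fast.  Equivalence of the two code paths
is part of the test suite.

Also here: Benjamini–Hochberg adjustment, the Shapiro–Wilk residual
normality screen, and cross-method overlap comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .normalization import NormFactors, log2_cpm, tmm_factors
from .regression import (
    DEFAULT_K,
    MAD_CONSTANT,
    GeneFit,
    build_design,
    covariate_design,
    fit_huber_irwls,
    fit_ols,
)

__all__ = [
    "TagAssociation",
    "TagScanResults",
    "NormalityScreen",
    "ScanComparison",
    "bh_adjust",
    "shapiro_screen",
    "tag_scan",
    "compare_scans",
]

logger = logging.getLogger(__name__)


class _ScanArrays(NamedTuple):
    """Raw per-gene arrays produced by a batched scan."""

    beta: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    df: int
    pvalue: np.ndarray
    scale: np.ndarray
    n_iter: np.ndarray
    usable: np.ndarray
    converged: np.ndarray


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Sorts ascending and takes ``q_(i) = min_{j>=i} min(1, p_(j) * m / j)``,
    returned in the original order.  NaN entries pass through untouched and
    are excluded from ``m``.  Values outside [0, 1] raise ``ValueError``
    naming the offending index.
    """
    p = np.asarray(pvalues, dtype=float)
    out_of_range = np.flatnonzero((p < 0) | (p > 1))
    if out_of_range.size:
        i = int(out_of_range[0])
        raise ValueError(f"p-value out of [0, 1] at index {i}: {p[i]}")
    flat = p.ravel()
    mask = ~np.isnan(flat)
    m = int(mask.sum())
    out = np.full(flat.shape, np.nan)
    if m:
        vals = flat[mask]
        order = np.argsort(vals, kind="stable")
        scaled = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        adj = np.empty(m)
        adj[order] = q
        out[mask] = adj
    return out.reshape(p.shape)


def _prepare_samples(
    expression: pd.DataFrame,
    phenotype: pd.DataFrame,
    trait: str,
    covariates: Sequence[str],
    allow_subset: bool,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple]:
    """Align samples and apply listwise deletion on trait/covariates."""
    if trait not in phenotype.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype table")
    missing = [s for s in phenotype.index if s not in expression.columns]
    if missing and not allow_subset:
        raise ValueError(
            f"phenotype sample(s) absent from expression matrix: {missing}; "
            "pass allow_subset=True to scan the intersection"
        )
    common = [s for s in expression.columns if s in set(phenotype.index)]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} samples shared; need at least 3")
    expression = expression[common]
    phenotype = phenotype.loc[common]

    used = [trait] + [c for c in covariates if c in phenotype.columns]
    ok = ~phenotype[used].isna().any(axis=1)
    dropped = tuple(phenotype.index[~ok])
    if dropped:
        logger.info("dropping %d sample(s) with missing values: %s",
                    len(dropped), list(dropped))
        phenotype = phenotype.loc[ok]
        expression = expression[phenotype.index.tolist()]
    return expression, phenotype, dropped


class TagAssociation:
    """Per-gene linear model of a continuous trait on gene expression.

    Parameters
    ----------
    expression : pandas.DataFrame
        Normalized expression, genes x samples (log2 TMM counts-per-million
        from :func:`tagseq.normalization.log2_cpm`, or any matrix on a
        roughly Gaussian scale).
    phenotype : pandas.DataFrame
        Indexed by sample identifier; must contain the trait column and any
        requested covariates.  Covariates may be numeric or categorical
        (dummy coded, first level dropped).
    trait : str
        Name of the continuous response column.
    covariates : sequence of str
        Covariate columns included in every gene's model.
    allow_subset : bool
        Permit phenotype samples missing from the expression matrix
        (the scan then runs on the intersection).

    Samples with missing trait/covariate values are removed once, for all
    genes.  Use :meth:`fit` for the genome-wide scan, :meth:`fit_gene` for
    a single gene's full fit and :meth:`check_normality` for the residual
    normality screen.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        phenotype: pd.DataFrame,
        trait: str = "trait",
        covariates: Sequence[str] = (),
        allow_subset: bool = False,
    ):
        expression, phenotype, dropped = _prepare_samples(
            expression, phenotype, trait, covariates, allow_subset
        )
        self.expression = expression
        self.phenotype = phenotype
        self.trait = trait
        self.covariates = tuple(covariates)
        self.dropped_samples = dropped
        self._y = phenotype[trait].to_numpy(dtype=float)
        cov_names, cov = covariate_design(phenotype, covariates)
        self._cov_names = cov_names
        self._cov = cov
        self.param_names = ("intercept", "expression") + cov_names
        n, q = cov.shape
        p = q + 2
        if n <= p:
            raise ValueError(f"{n} usable samples for {p} coefficients; need n > p")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        phenotype: pd.DataFrame,
        trait: str = "trait",
        covariates: Sequence[str] = (),
        factors: NormFactors | None = None,
        prior_count: float = 0.5,
        allow_subset: bool = False,
    ) -> "TagAssociation":
        """Build the model from raw counts via TMM + log2 CPM."""
        expression = log2_cpm(
            counts, factors if factors is not None else tmm_factors(counts),
            prior_count=prior_count,
        )
        return cls(expression, phenotype, trait=trait, covariates=covariates,
                   allow_subset=allow_subset)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    # -- single-gene interface --------------------------------------------

    def fit_gene(
        self, gene_id, method: str = "ols", k: float = DEFAULT_K,
        tol: float = 1e-8, max_iter: int = 100,
    ) -> GeneFit:
        """Fit one gene through the reference (non-batched) code path."""
        design = build_design(
            self.phenotype, self.expression.loc[gene_id].to_numpy(dtype=float),
            trait=self.trait, covariates=self.covariates,
        )
        if method == "ols":
            return fit_ols(design.response, design.matrix, gene_id=gene_id,
                           param_names=design.columns,
                           dropped_samples=design.dropped_samples)
        if method == "huber":
            return fit_huber_irwls(design.response, design.matrix, k=k, tol=tol,
                                   max_iter=max_iter, gene_id=gene_id,
                                   param_names=design.columns,
                                   dropped_samples=design.dropped_samples)
        raise ValueError(f"unknown method {method!r}; use 'ols' or 'huber'")

    # -- batched internals -------------------------------------------------

    def _design_tensor(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked per-gene designs X (G, n, p) and a validity mask.

        Column order matches the single-gene design: intercept, expression,
        covariates.  Genes whose expression is collinear with the
        intercept/covariate block (zero residual variance) are masked out
        and reported as flagged rows.
        """
        e = self.expression.to_numpy(dtype=float)
        g, n = e.shape
        q = self._cov.shape[1]
        x = np.empty((g, n, q + 2))
        x[:, :, 0] = 1.0
        x[:, :, 1] = e
        if q:
            x[:, :, 2:] = self._cov[None, :, :]
        z = np.column_stack([np.ones(n), self._cov])
        qz, _ = np.linalg.qr(z)
        e_resid = e - (e @ qz) @ qz.T
        sxx = np.einsum("gn,gn->g", e_resid, e_resid)
        scale_ref = np.maximum(np.einsum("gn,gn->g", e, e), 1.0)
        ok = sxx > scale_ref * n * np.finfo(float).eps**2 * 100
        return x, ok

    def _batched_ols(self, x: np.ndarray, ok: np.ndarray) -> "_ScanArrays":
        y = self._y
        g, n, p = x.shape
        df = n - p
        beta = np.full((g, p), np.nan)
        se = np.full(g, np.nan)
        scale = np.full(g, np.nan)
        xa = x[ok]
        xtx = np.einsum("gnp,gnq->gpq", xa, xa)
        xty = np.einsum("gnp,n->gp", xa, y)
        b = np.linalg.solve(xtx, xty[..., None])[..., 0]
        resid = y[None, :] - np.einsum("gnp,gp->gn", xa, b)
        rss = np.einsum("gn,gn->g", resid, resid)
        s2 = rss / df
        inv = np.linalg.inv(xtx)
        beta[ok] = b
        with np.errstate(invalid="ignore"):
            se[ok] = np.sqrt(s2 * inv[:, 1, 1])
        scale[ok] = np.sqrt(s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            statistic = beta[:, 1] / se
        pvalue = 2.0 * stats.t.sf(np.abs(statistic), df)
        n_iter = np.where(ok, 1, 0)
        return _ScanArrays(beta, se, statistic, df, pvalue, scale, n_iter,
                           ok.copy(), ok.copy())

    def _batched_huber(self, x: np.ndarray, ok: np.ndarray, k: float,
                       tol: float, max_iter: int) -> "_ScanArrays":
        """Lockstep IRWLS across genes; mirrors fit_huber_irwls per gene."""
        y = self._y
        g, n, p = x.shape
        df = n - p
        beta = np.full((g, p), np.nan)
        scale = np.full(g, np.nan)
        se = np.full(g, np.nan)
        n_iter = np.zeros(g, dtype=int)
        converged = np.zeros(g, dtype=bool)
        resid_final = np.full((g, n), np.nan)

        active = np.flatnonzero(ok)
        if active.size == 0:
            statistic = np.full(g, np.nan)
            return _ScanArrays(beta, se, statistic, df, statistic.copy(),
                               scale, n_iter, ok & False, converged)

        xa = x[active]
        xtx = np.einsum("gnp,gnq->gpq", xa, xa)
        xty = np.einsum("gnp,n->gp", xa, y)
        b = np.linalg.solve(xtx, xty[..., None])[..., 0]  # OLS start
        usable = ok.copy()

        idx = active
        xb = xa
        for _ in range(max_iter):
            resid = y[None, :] - np.einsum("gnp,gp->gn", xb, b)
            med = np.median(resid, axis=1)
            mad = np.median(np.abs(resid - med[:, None]), axis=1) / MAD_CONSTANT
            degenerate = mad == 0
            if degenerate.any():
                usable[idx[degenerate]] = False
                keep = ~degenerate
                idx, xb, b, resid, mad = (
                    idx[keep], xb[keep], b[keep], resid[keep], mad[keep])
                if idx.size == 0:
                    break
            thr = (k * mad)[:, None]
            absr = np.abs(resid)
            with np.errstate(divide="ignore"):
                w = np.where(absr <= thr, 1.0, thr / absr)
            xw = xb * w[:, :, None]
            xtwx = np.einsum("gnp,gnq->gpq", xw, xb)
            xtwy = np.einsum("gnp,n->gp", xw, y)
            b_new = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
            n_iter[idx] += 1
            done = np.all(
                np.abs(b_new - b) < tol * np.maximum(1.0, np.abs(b_new)), axis=1
            )
            b = b_new
            if done.any():
                fin = idx[done]
                beta[fin] = b[done]
                scale[fin] = mad[done]
                resid_final[fin] = y[None, :] - np.einsum(
                    "gnp,gp->gn", xb[done], b[done])
                converged[fin] = True
                keep = ~done
                idx, xb, b = idx[keep], xb[keep], b[keep]
                if idx.size == 0:
                    break
                mad = mad[keep]
        if idx.size:  # hit max_iter without meeting the tolerance
            beta[idx] = b
            scale[idx] = mad
            resid_final[idx] = y[None, :] - np.einsum("gnp,gp->gn", xb, b)

        live = np.flatnonzero(usable)
        u = resid_final[live] / scale[live, None]
        psi = np.clip(u, -k, k)
        psi_prime_mean = np.mean(np.abs(u) <= k, axis=1)
        s2 = scale[live] ** 2 * np.einsum("gn,gn->g", psi, psi) / df
        inv = np.linalg.inv(np.einsum("gnp,gnq->gpq", x[live], x[live]))
        se[live] = np.sqrt(s2 / psi_prime_mean**2 * inv[:, 1, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            statistic = beta[:, 1] / se
        pvalue = 2.0 * stats.t.sf(np.abs(statistic), df)
        return _ScanArrays(beta, se, statistic, df, pvalue, scale, n_iter,
                           usable, converged & usable)

    # -- genome-wide fit ----------------------------------------------------

    def fit(
        self,
        method: str = "ols",
        alpha: float = 0.05,
        adjust: str = "fdr",
        k: float = DEFAULT_K,
        tol: float = 1e-8,
        max_iter: int = 100,
    ) -> "TagScanResults":
        """Run the genome-wide scan.

        Parameters
        ----------
        method : {'ols', 'huber'}
            Estimator for every per-gene model.
        alpha : float
            Significance level for the ``significant`` calls.
        adjust : {'fdr', 'none'}
            Whether significance is called on Benjamini–Hochberg adjusted
            p-values (``fdr < alpha``) or raw ones (``pvalue < alpha``).
            Adjusted values are reported either way.
        k, tol, max_iter
            Huber tuning constant and IRWLS stopping rule (robust fits).

        Genes whose model cannot be fitted (constant expression, zero MAD
        scale) are returned as flagged rows with NaN statistics rather
        than aborting the scan.
        """
        if method not in ("ols", "huber"):
            raise ValueError(f"unknown method {method!r}; use 'ols' or 'huber'")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if adjust not in ("fdr", "none"):
            raise ValueError(f"unknown adjustment {adjust!r}; use 'fdr' or 'none'")
        logger.info("scanning %d genes (%d samples, method=%s, covariates=%s)",
                    self.n_genes, self.n_samples, method, list(self.covariates))
        x, ok = self._design_tensor()
        if method == "ols":
            arrays = self._batched_ols(x, ok)
        else:
            arrays = self._batched_huber(x, ok, k, tol, max_iter)
        beta, se, statistic, df, pvalue, scale, n_iter, usable, conv = arrays
        flagged = ~usable
        pvalue = np.where(flagged, np.nan, pvalue)
        fdr = bh_adjust(pvalue)
        crit = fdr if adjust == "fdr" else pvalue
        with np.errstate(invalid="ignore"):
            significant = (crit < alpha) & ~np.isnan(crit)

        table = pd.DataFrame(
            {
                "beta1": beta[:, 1],
                "se_beta1": se,
                "statistic": statistic,
                "df": df,
                "pvalue": pvalue,
                "fdr": fdr,
                "significant": significant,
                "flagged": flagged,
                "scale": scale,
                "n_iter": n_iter,
                "converged": conv,
            },
            index=self.expression.index.rename("gene_id"),
        )
        table["input_order"] = np.arange(self.n_genes)
        table = table.sort_values(
            ["pvalue", "input_order"], kind="stable", na_position="last"
        )
        return TagScanResults(
            table=table,
            method=method,
            trait=self.trait,
            covariates=self.covariates,
            alpha=alpha,
            adjust=adjust,
            k=k if method == "huber" else None,
            n_samples=self.n_samples,
            model=self,
        )

    # -- normality screen ---------------------------------------------------

    def check_normality(self) -> "NormalityScreen":
        """Shapiro–Wilk screen of per-gene OLS residuals.

        Fits the ordinary model for every gene and tests its residuals for
        normality, returning raw and FDR-adjusted p-values.  Genes with
        (numerically) constant residuals are flagged and excluded from the
        adjustment.
        """
        n = self.n_samples
        if not 3 <= n <= 5000:
            raise ValueError(
                f"Shapiro–Wilk requires 3 <= n <= 5000 samples, got {n}")
        x, ok = self._design_tensor()
        y = self._y
        g = x.shape[0]
        w_stat = np.full(g, np.nan)
        pval = np.full(g, np.nan)
        flagged = ~ok
        xa = x[ok]
        xtx = np.einsum("gnp,gnq->gpq", xa, xa)
        xty = np.einsum("gnp,n->gp", xa, y)
        b = np.linalg.solve(xtx, xty[..., None])[..., 0]
        resid = y[None, :] - np.einsum("gnp,gp->gn", xa, b)
        for pos, gi in enumerate(np.flatnonzero(ok)):
            r = resid[pos]
            if np.ptp(r) <= 1e-12 * max(1.0, float(np.abs(r).max())):
                flagged[gi] = True
                continue
            res = stats.shapiro(r)
            w_stat[gi], pval[gi] = res.statistic, res.pvalue
            if (pos + 1) % 1000 == 0:
                logger.info("normality screen: %d genes done", pos + 1)
        pval = np.where(flagged, np.nan, pval)
        table = pd.DataFrame(
            {"W": w_stat, "pvalue": pval, "fdr": bh_adjust(pval),
             "flagged": flagged},
            index=self.expression.index.rename("gene_id"),
        )
        return NormalityScreen(table=table, n_samples=n)


@dataclass
class NormalityScreen:
    """Per-gene Shapiro–Wilk results for OLS residuals."""

    table: pd.DataFrame
    n_samples: int

    def n_significant(self, threshold: float = 0.05, adjusted: bool = True) -> int:
        col = "fdr" if adjusted else "pvalue"
        return int((self.table[col] < threshold).sum())

    def summary(self, threshold: float = 0.05) -> str:
        k = self.n_significant(threshold)
        total = int((~self.table["flagged"]).sum())
        if k == 0:
            verdict = "No significant genes: the normality assumption is tenable."
        else:
            verdict = f"{k} gene(s) deviate from normality."
        return (
            f"Shapiro–Wilk residual screen on {total} genes "
            f"(n={self.n_samples}, FDR threshold {threshold:g}): {verdict}"
        )


class TagScanResults:
    """Results of a genome-wide trait-association scan.

    ``table`` has one row per gene, ordered by ascending p-value (original
    input order is recoverable from the ``input_order`` column), with the
    slope, its standard error, the test statistic, degrees of freedom, raw
    and BH-adjusted p-values, significance call and fit diagnostics.
    """

    def __init__(self, table, method, trait, covariates, alpha, adjust, k,
                 n_samples, model=None):
        self.table = table
        self.method = method
        self.trait = trait
        self.covariates = tuple(covariates)
        self.alpha = alpha
        self.adjust = adjust
        self.k = k
        self.n_samples = n_samples
        self._model = model

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_genes(self) -> list:
        return self.table.index[self.table["significant"]].tolist()

    def pvalues(self, original_order: bool = True) -> pd.Series:
        """Raw per-gene p-values, by default in the input gene order."""
        t = self.table
        if original_order:
            t = t.sort_values("input_order")
        return t["pvalue"]

    def summary(self, top: int = 10) -> str:
        """Human-readable account of the scan and its strongest hits."""
        rule = (f"FDR < {self.alpha:g}" if self.adjust == "fdr"
                else f"raw p < {self.alpha:g}")
        lines = [
            "Trait-association scan",
            "======================",
            f"method:       {self.method}"
            + (f" (k={self.k:g})" if self.k is not None else ""),
            f"trait:        {self.trait}",
            f"covariates:   {list(self.covariates) if self.covariates else 'none'}",
            f"samples:      {self.n_samples}",
            f"genes:        {len(self.table)}"
            f" ({int(self.table['flagged'].sum())} flagged)",
            f"significant:  {self.n_significant} at {rule}",
            "",
        ]
        cols = ["beta1", "se_beta1", "statistic", "pvalue", "fdr"]
        head = self.table[cols].head(top)
        lines.append(head.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<TagScanResults method={self.method!r} genes={len(self.table)} "
                f"significant={self.n_significant}>")

    def to_tsv(self, path, float_format: str = "%.6g") -> None:
        """Write the result table as TSV with a reproducibility header."""
        meta = (
            f"# tagseq {__version__} scan: method={self.method} "
            f"trait={self.trait} covariates={','.join(self.covariates) or '-'} "
            f"alpha={self.alpha:g} adjust={self.adjust}"
            + (f" k={self.k:g}" if self.k is not None else "")
            + f" n_samples={self.n_samples}\n"
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(meta)
            self.table.to_csv(fh, sep="\t", float_format=float_format)

    def plot_gene(self, gene_id, ax=None):
        """Scatter of trait against one gene's expression with fitted line(s).

        Requires the originating model (available unless results were read
        back from disk) and matplotlib.
        """
        if self._model is None:
            raise ValueError("plotting needs the originating TagAssociation model")
        import matplotlib.pyplot as plt

        fit = self._model.fit_gene(
            gene_id, method=self.method,
            **({"k": self.k} if self.method == "huber" else {}),
        )
        x = self._model.expression.loc[gene_id].to_numpy(dtype=float)
        y = self._model._y
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(x, y, s=12, alpha=0.7, label="samples")
        grid = np.linspace(x.min(), x.max(), 50)
        # covariates held at their sample means
        base = fit.beta0
        if len(fit.params) > 2:
            base = base + float(self._model._cov.mean(axis=0) @ fit.params[2:])
        ax.plot(grid, base + fit.beta1 * grid, color="C3",
                label=f"{self.method} fit (b1={fit.beta1:.3g}, p={fit.pvalue:.2g})")
        ax.set_xlabel(f"log2 normalized expression of {gene_id}")
        ax.set_ylabel(self.trait)
        ax.legend()
        return ax


def tag_scan(
    expression: pd.DataFrame,
    phenotype: pd.DataFrame,
    method: str = "ols",
    trait: str = "trait",
    covariates: Sequence[str] = (),
    alpha: float = 0.05,
    adjust: str = "fdr",
    k: float = DEFAULT_K,
    allow_subset: bool = False,
) -> TagScanResults:
    """Functional one-call wrapper around :class:`TagAssociation`."""
    model = TagAssociation(expression, phenotype, trait=trait,
                           covariates=covariates, allow_subset=allow_subset)
    return model.fit(method=method, alpha=alpha, adjust=adjust, k=k)


def shapiro_screen(
    expression: pd.DataFrame,
    phenotype: pd.DataFrame,
    trait: str = "trait",
    covariates: Sequence[str] = (),
    allow_subset: bool = False,
) -> NormalityScreen:
    """Functional wrapper for the per-gene residual normality screen."""
    model = TagAssociation(expression, phenotype, trait=trait,
                           covariates=covariates, allow_subset=allow_subset)
    return model.check_normality()


@dataclass
class ScanComparison:
    """Overlap structure of significant-gene sets across scans.

    ``membership`` is genes x methods booleans; ``pattern_counts`` counts
    every intersection pattern (keys like ``'ols+huber'`` or ``'none'``).
    """

    membership: pd.DataFrame
    pattern_counts: pd.Series = field(init=False)

    def __post_init__(self):
        labels = self.membership.apply(
            lambda row: "+".join(self.membership.columns[row]) or "none", axis=1
        )
        self.pattern_counts = labels.value_counts().rename("n_genes")
        self._labels = labels

    @property
    def patterns(self) -> pd.Series:
        """Per-gene intersection pattern label."""
        return self._labels

    def categorize(
        self,
        existing: Sequence[str],
        suggesting: Sequence[str],
        robust: str | None = None,
    ) -> pd.Series:
        """Label genes AM / EM / SM / RM by method family.

        AM: significant in every method; EM: only in the existing
        (two-group) methods; SM: only in the suggesting association
        methods; RM: only in the robust scan; NS: significant nowhere;
        other mixtures are labelled 'mixed'.
        """
        m = self.membership
        for name in list(existing) + list(suggesting) + ([robust] if robust else []):
            if name not in m.columns:
                raise ValueError(f"unknown scan name {name!r}")
        ex = m[list(existing)].any(axis=1)
        ex_all = m[list(existing)].all(axis=1)
        sg = m[list(suggesting)].any(axis=1)
        sg_all = m[list(suggesting)].all(axis=1)
        out = pd.Series("mixed", index=m.index, name="category")
        out[~m.any(axis=1)] = "NS"
        out[ex_all & sg_all] = "AM"
        out[ex & ~sg] = "EM"
        out[sg & ~ex] = "SM"
        if robust is not None:
            only_robust = m[robust] & ~m.drop(columns=[robust]).any(axis=1)
            out[only_robust] = "RM"
        return out


def compare_scans(
    results: Mapping[str, "TagScanResults | pd.Series"],
    alpha: float = 0.05,
    use: str = "pvalue",
) -> ScanComparison:
    """Compare significant-gene sets across scans over one gene universe.

    ``results`` maps a scan name to either a :class:`TagScanResults` or a
    plain per-gene p-value Series (the plug-in contract for external
    methods such as count-model DE tools).  Significance is raw
    ``p < alpha`` by default (``use='pvalue'``); ``use='significant'``
    honours each scan's own call instead.  Mismatched gene universes raise
    with the symmetric difference listed.
    """
    if len(results) < 2:
        raise ValueError("need at least two scans to compare")
    sets: dict[str, pd.Series] = {}
    universe: pd.Index | None = None
    for name, res in results.items():
        if isinstance(res, TagScanResults):
            if use == "significant":
                member = res.table["significant"]
            else:
                member = res.table["pvalue"] < alpha
        else:
            pv = pd.Series(res).astype(float)
            member = pv < alpha
        member = member.fillna(False)
        genes = member.index.sort_values()
        if universe is None:
            universe = genes
        elif not universe.equals(genes):
            diff = universe.symmetric_difference(genes).tolist()
            raise ValueError(f"gene universes differ between scans: {diff}")
        sets[name] = member
    membership = pd.DataFrame(
        {name: member.reindex(universe) for name, member in sets.items()}
    ).astype(bool)
    membership.index.name = "gene_id"
    return ScanComparison(membership=membership)
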
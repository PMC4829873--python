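"""Mock-comparison estimation of the proportion of false discoveries.

A mock dataset is the real dataset with its trait (and group label)
permuted across samples, so every test statistic is drawn from the null.
The proportion of false discoveries (PFD) of a method is

    |significant in real  ∩  significant in mock| / |significant in real|

Sweeping the number of biological replicates — subsampling the columns,
scanning real and permuted traits, and repeating — traces how fast a
method's PFD converges to the nominal significance level as replication
grows.

A *method* here is any plug-in callable ``f(counts, phenotype) ->
pandas.Series`` of one p-value per gene, so external differential
expression tools can be swept through the same harness; built-in plug-ins
wrap the package's own regression scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .normalization import log2_cpm, tmm_factors
from .scan import TagAssociation, bh_adjust

__all__ = [
    "MockResult",
    "permute_trait",
    "pfd",
    "subsample_replicates",
    "mock_comparison",
    "regression_pvalues",
    "sweep_table",
    "write_sweep",
]

logger = logging.getLogger(__name__)

MethodPlugin = Callable[[pd.DataFrame, pd.DataFrame], pd.Series]


def permute_trait(
    phenotype: pd.DataFrame,
    rng: np.random.Generator | int,
    trait: str = "trait",
    group: str | None = "group",
) -> pd.DataFrame:
    """Return a copy with trait (and group, if present) jointly permuted.

    One uniform random permutation is applied to the trait column and,
    when a group column exists, the same permutation to it, so the
    trait/group pair stays consistent while covariates remain attached to
    their original samples.  Deterministic given the generator state.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = phenotype.copy()
    perm = rng.permutation(len(out))
    out[trait] = out[trait].to_numpy()[perm]
    if group is not None and group in out.columns:
        out[group] = out[group].to_numpy()[perm]
    return out


def pfd(real_significant: Iterable, mock_significant: Iterable) -> float | None:
    """Proportion of false discoveries: |real ∩ mock| / |real|.

    Returns ``None`` (undefined, to be excluded from averages) when no
    gene is significant in the real data.
    """
    real = set(real_significant)
    mock = set(mock_significant)
    if not real:
        logger.warning("pfd undefined: no significant genes in real data")
        return None
    return len(real & mock) / len(real)


def subsample_replicates(
    counts: pd.DataFrame,
    phenotype: pd.DataFrame,
    n_per_group: int,
    rng: np.random.Generator | int,
    group: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ``n_per_group`` samples per group, without replacement.

    When the phenotype has a binary ``group`` column the draw is
    stratified; with a continuous trait and no group column,
    ``2 * n_per_group`` samples are drawn uniformly so replicate counts
    stay comparable with the two-group tools.  Columns of the count matrix
    and rows of the phenotype are subset consistently, preserving the
    original sample order.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    samples = phenotype.index.to_numpy()
    if group in phenotype.columns:
        chosen: list = []
        for level, members in phenotype.groupby(group, observed=True).groups.items():
            members = np.asarray(members)
            if members.size < n_per_group:
                sizes = phenotype[group].value_counts().to_dict()
                raise ValueError(
                    f"group {level!r} has {members.size} samples, "
                    f"need {n_per_group}; available sizes: {sizes}"
                )
            chosen.extend(rng.choice(members, size=n_per_group, replace=False))
        chosen_set = set(chosen)
    else:
        total = 2 * n_per_group
        if samples.size < total:
            raise ValueError(
                f"need {total} samples for n_per_group={n_per_group}, "
                f"have {samples.size}"
            )
        chosen_set = set(rng.choice(samples, size=total, replace=False))
    keep = [s for s in samples if s in chosen_set]
    return counts[keep], phenotype.loc[keep]


@dataclass
class MockResult:
    """Mock-comparison outcome at one replicate count.

    Per-repeat arrays use NaN for repeats whose PFD is undefined (empty
    real significant set); summaries skip those.
    """

    method: str
    alpha: float
    n_per_group: int
    n_repeats: int
    n_sig_real: np.ndarray
    n_sig_mock: np.ndarray
    n_common: np.ndarray
    pfd_values: np.ndarray
    n_failures: int = 0

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.pfd_values)))

    @property
    def mean_pfd(self) -> float:
        return float(np.nanmean(self.pfd_values)) if self.n_valid else float("nan")

    @property
    def se_pfd(self) -> float:
        """Standard error of the mean PFD: sample SD / sqrt(#valid repeats)."""
        if self.n_valid < 2:
            return float("nan")
        return float(np.nanstd(self.pfd_values, ddof=1) / np.sqrt(self.n_valid))

    @property
    def mean_n_sig_real(self) -> float:
        return float(np.nanmean(self.n_sig_real))

    def __repr__(self) -> str:
        return (
            f"<MockResult {self.method} n_per_group={self.n_per_group} "
            f"mean_pfd={self.mean_pfd:.4f} se={self.se_pfd:.4f} "
            f"mean_n_sig={self.mean_n_sig_real:.1f}>"
        )


def _repeat_rng(base_seed: int, grid_index: int, repeat: int) -> np.random.Generator:
    """Independent, reproducible stream per (grid point, repeat)."""
    ss = np.random.SeedSequence(entropy=base_seed,
                                spawn_key=(grid_index, repeat))
    return np.random.default_rng(ss)


def mock_comparison(
    counts: pd.DataFrame,
    phenotype: pd.DataFrame,
    method: MethodPlugin,
    replicate_grid: Sequence[int],
    trait: str = "trait",
    group: str = "group",
    alpha: float = 0.05,
    n_repeats: int = 1000,
    base_seed: int = 0,
    adjust: str = "none",
    method_name: str | None = None,
    max_failure_rate: float = 0.10,
) -> list[MockResult]:
    """Sweep the mock comparison over a grid of replicate counts.

    For every grid value and repeat: subsample the columns, run the method
    plug-in on the real trait and on a permuted copy (permutation happens
    within the subsample), call significance at raw ``p < alpha``
    (``adjust='fdr'`` switches to BH-adjusted calls) and record the
    significant-set sizes, their overlap and the PFD.  Per-repeat seeds
    derive deterministically from ``base_seed`` so the whole sweep is
    reproducible bit for bit.

    Repeats in which the plug-in raises are logged and skipped; if more
    than ``max_failure_rate`` of a grid point's repeats fail the sweep
    aborts with a summary.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if adjust not in ("none", "fdr"):
        raise ValueError("adjust must be 'none' or 'fdr'")
    name = method_name or getattr(method, "__name__", "method")
    results: list[MockResult] = []
    for gi, n_per_group in enumerate(replicate_grid):
        n_sig_real = np.zeros(n_repeats)
        n_sig_mock = np.zeros(n_repeats)
        n_common = np.zeros(n_repeats)
        pfd_values = np.full(n_repeats, np.nan)
        failures = 0
        for rep in range(n_repeats):
            rng = _repeat_rng(base_seed, gi, rep)
            try:
                c_sub, p_sub = subsample_replicates(
                    counts, phenotype, n_per_group, rng, group=group)
                p_mock = permute_trait(p_sub, rng, trait=trait, group=group)
                pv_real = method(c_sub, p_sub)
                pv_mock = method(c_sub, p_mock)
            except Exception as exc:  # per-repeat failure: log and skip
                failures += 1
                logger.warning("repeat %d at n_per_group=%d failed: %s",
                               rep, n_per_group, exc)
                n_sig_real[rep] = n_sig_mock[rep] = n_common[rep] = np.nan
                continue
            if adjust == "fdr":
                pv_real = pd.Series(bh_adjust(pv_real.to_numpy()), index=pv_real.index)
                pv_mock = pd.Series(bh_adjust(pv_mock.to_numpy()), index=pv_mock.index)
            real = set(pv_real.index[pv_real < alpha])
            mock = set(pv_mock.index[pv_mock < alpha])
            n_sig_real[rep] = len(real)
            n_sig_mock[rep] = len(mock)
            n_common[rep] = len(real & mock)
            value = pfd(real, mock) if real else None
            if value is not None:
                pfd_values[rep] = value
        if failures > max_failure_rate * n_repeats:
            raise RuntimeError(
                f"{failures}/{n_repeats} repeats failed at "
                f"n_per_group={n_per_group} (limit {max_failure_rate:.0%}); "
                "aborting sweep"
            )
        result = MockResult(
            method=name, alpha=alpha, n_per_group=n_per_group,
            n_repeats=n_repeats, n_sig_real=n_sig_real,
            n_sig_mock=n_sig_mock, n_common=n_common,
            pfd_values=pfd_values, n_failures=failures,
        )
        logger.info("mock comparison %s: %r", name, result)
        results.append(result)
    return results


def regression_pvalues(
    method: str = "ols",
    trait: str = "trait",
    covariates: Sequence[str] = (),
    k: float = 1.345,
    normalize: bool = True,
    prior_count: float = 0.5,
) -> MethodPlugin:
    """Built-in plug-in: TMM + log2 CPM + per-gene regression p-values.

    Normalization is recomputed inside every call so each subsample is
    treated as its own experiment.
    """
    def plugin(counts: pd.DataFrame, phenotype: pd.DataFrame) -> pd.Series:
        if normalize:
            expression = log2_cpm(counts, tmm_factors(counts),
                                  prior_count=prior_count)
        else:
            expression = counts.astype(float)
        model = TagAssociation(expression, phenotype, trait=trait,
                               covariates=covariates)
        res = model.fit(method=method, adjust="none", k=k)
        return res.pvalues(original_order=True)

    plugin.__name__ = f"{method}_regression"
    return plugin


def sweep_table(results: Sequence[MockResult]) -> pd.DataFrame:
    """One row per grid point: replicate count, method, PFD summaries."""
    return pd.DataFrame(
        {
            "replicate_count": [r.n_per_group for r in results],
            "method": [r.method for r in results],
            "mean_pfd": [r.mean_pfd for r in results],
            "se_pfd": [r.se_pfd for r in results],
            "mean_n_sig": [r.mean_n_sig_real for r in results],
        }
    )


def write_sweep(results: Sequence[MockResult], path,
                params: str = "") -> None:
    """Write the sweep summary as TSV with a reproducibility header."""
    table = sweep_table(results)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tagseq {__version__} mock-comparison sweep {params}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
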
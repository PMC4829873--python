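"""Between-sample normalization of RNA-seq count matrices.

Scaling factors are computed by the trimmed mean of M-values (TMM)
procedure: per-sample log expression ratios against a reference sample are
doubly trimmed (by ratio and by average abundance) and averaged with
inverse-asymptotic-variance weights.  The normalized expression used as the
regression predictor downstream is log2 counts-per-million with
TMM-adjusted effective library sizes and a small prior count so every cell
is finite.

Counts live in a plain :class:`pandas.DataFrame` with genes as rows and
samples as columns; gene and sample identifiers are the index and columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NormFactors",
    "validate_counts",
    "select_reference",
    "tmm_factors",
    "log2_cpm",
    "filter_by_cpm",
]


@dataclass(frozen=True)
class NormFactors:
    """TMM scaling factors for one count matrix.

    Attributes
    ----------
    factors : pandas.Series
        One positive factor per sample, rescaled so that their geometric
        mean is 1.  A sample's effective library size is
        ``total_count * factor``.
    reference : str
        Identifier of the reference sample the pairwise M/A statistics
        were computed against.
    """

    factors: pd.Series
    reference: str

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if not np.all(f > 0):
            raise ValueError("normalization factors must be positive")

    def align_to(self, counts: pd.DataFrame) -> np.ndarray:
        """Return the factors ordered like ``counts.columns``."""
        missing = [s for s in counts.columns if s not in self.factors.index]
        extra = [s for s in self.factors.index if s not in counts.columns]
        if missing or extra:
            raise ValueError(
                "sample sets differ between counts and factors: "
                f"missing from factors {missing}, not in counts {extra}"
            )
        return self.factors.reindex(counts.columns).to_numpy(dtype=float)


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the count-matrix invariants, raising ``ValueError`` on failure.

    Requirements: at least 1 gene and 2 samples, unique gene and sample
    identifiers, and all cells nonnegative integers.
    """
    if counts.shape[0] < 1:
        raise ValueError("count matrix must contain at least one gene")
    if counts.shape[1] < 2:
        raise ValueError("count matrix must contain at least two samples")
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups}")
    if counts.columns.has_duplicates:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric cells")
    if np.any(values < 0):
        gene, sample = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[gene]!r}, "
            f"sample {counts.columns[sample]!r}"
        )
    if not np.issubdtype(values.dtype, np.integer):
        if np.any(values != np.floor(values)):
            gene, sample = np.argwhere(values != np.floor(values))[0]
            raise ValueError(
                f"non-integer count at gene {counts.index[gene]!r}, "
                f"sample {counts.columns[sample]!r}"
            )


def _library_sizes(counts: pd.DataFrame) -> np.ndarray:
    lib = counts.to_numpy(dtype=float).sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = [counts.columns[i] for i in zero]
        raise ValueError(f"sample(s) with zero total count: {names}")
    return lib


def select_reference(counts: pd.DataFrame) -> str:
    """Pick the TMM reference sample.

    The reference is the sample whose 75th-percentile counts-per-million is
    closest to the mean of that quantity across samples; ties are broken by
    the lowest sample index so the choice is deterministic.
    """
    validate_counts(counts)
    lib = _library_sizes(counts)
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    q75 = np.percentile(cpm, 75, axis=0)
    dist = np.abs(q75 - q75.mean())
    return str(counts.columns[int(np.argmin(dist))])


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """Compute TMM scaling factors against a reference sample.

    For sample *k* versus reference *r*, using only genes with positive
    counts in both, the log ratio and average abundance are

        M_g = log2((y_gk / N_k) / (y_gr / N_r))
        A_g = 0.5 * log2((y_gk / N_k) * (y_gr / N_r))

    Genes in the top or bottom ``trim_m`` fraction by M, or the top or
    bottom ``trim_a`` fraction by A, are discarded (the intersection of
    survivors is kept; trim bounds follow the rank rule
    ``floor(n*trim)+1 <= rank <= n-floor(n*trim)``).  The factor is
    ``2**(sum(w*M)/sum(w))`` over surviving genes with inverse
    asymptotic-variance precision weights

        w_g = 1 / [ (N_k - y_gk)/(N_k*y_gk) + (N_r - y_gr)/(N_r*y_gr) ]

    and the factors are finally rescaled to geometric mean 1.

    Parameters
    ----------
    trim_m, trim_a
        Two-sided trim fractions applied to M and A (defaults 0.30/0.05).
    reference
        Reference sample identifier; picked by :func:`select_reference`
        when omitted.
    """
    validate_counts(counts)
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    if reference is None:
        reference = select_reference(counts)
    elif reference not in counts.columns:
        raise ValueError(f"reference sample {reference!r} not in count matrix")

    y = counts.to_numpy(dtype=float)
    lib = _library_sizes(counts)
    r = counts.columns.get_loc(reference)
    yr, nr = y[:, r], lib[r]

    raw = np.ones(counts.shape[1])
    for k, sample in enumerate(counts.columns):
        if k == r:
            continue
        yk, nk = y[:, k], lib[k]
        both = (yk > 0) & (yr > 0)
        if not both.any():
            raise ValueError(
                f"no genes with positive counts in both sample {sample!r} "
                f"and reference {reference!r}"
            )
        pk, pr = yk[both] / nk, yr[both] / nr
        m = np.log2(pk / pr)
        if np.max(np.abs(m)) < 1e-6:  # columns proportional: no adjustment
            continue
        a = 0.5 * np.log2(pk * pr)
        v = (nk - yk[both]) / (nk * yk[both]) + (nr - yr[both]) / (nr * yr[both])
        w = 1.0 / v

        n = m.size
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        keep = (
            (rank_m >= lo_m)
            & (rank_m <= n - lo_m + 1)
            & (rank_a >= lo_a)
            & (rank_a <= n - lo_a + 1)
        )
        if keep.sum() < 1:
            raise ValueError(
                f"no genes survive TMM trimming for sample {sample!r}"
            )
        raw[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        reference=reference,
    )


def log2_cpm(
    counts: pd.DataFrame,
    factors: NormFactors | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    Each cell is ``log2((y + prior) / (N*f + 2*prior) * 1e6)`` where ``N*f``
    is the sample's effective library size.  The prior keeps zero counts
    finite.  Factors are computed with default TMM settings when omitted.
    """
    validate_counts(counts)
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if factors is None:
        factors = tmm_factors(counts)
    f = factors.align_to(counts)
    lib = _library_sizes(counts)
    eff = lib * f
    values = np.log2(
        (counts.to_numpy(dtype=float) + prior_count)
        / (eff + 2.0 * prior_count)
        * 1e6
    )
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def filter_by_cpm(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 1
) -> pd.DataFrame:
    """Optional low-expression filter (off by default in every pipeline).

    Keeps genes whose raw counts-per-million exceed ``min_cpm`` in at least
    ``min_samples`` samples.  Genome-wide scans run unfiltered unless the
    caller opts in.
    """
    validate_counts(counts)
    lib = _library_sizes(counts)
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]
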
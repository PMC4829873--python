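"""Reading and writing the plain-text formats the tool exchanges.

Counts travel as tab-separated text (first column gene identifier, header
row of sample identifiers, integer cells); phenotypes as comma- or
tab-separated tables with a sample-identifier first column.  Writers are
deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .normalization import NormFactors, validate_counts

__all__ = [
    "read_counts",
    "write_counts",
    "read_phenotype",
    "write_phenotype",
    "read_factors",
    "write_factors",
    "read_pvalues",
]

logger = logging.getLogger(__name__)


def read_counts(path) -> pd.DataFrame:
    """Parse a tab-separated count matrix, validating every invariant.

    Raises ``ValueError`` with the offending gene/sample (and line number
    where possible) for duplicate identifiers, negative, non-integer or
    non-numeric cells, and ragged rows.  Lines starting with ``#`` are
    ignored.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed counts file: {exc}") from exc
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifier(s): {dups}")
    if raw.isna().any().any():
        gene = raw.index[raw.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing/ragged cell in gene row {gene!r}")
    counts = pd.DataFrame(index=raw.index.rename("gene_id"))
    for sample in raw.columns:
        col = raw[sample]
        try:
            numeric = pd.to_numeric(col)
        except (ValueError, TypeError):
            bad = col[pd.to_numeric(col, errors="coerce").isna()].index[0]
            raise ValueError(
                f"{path}: non-numeric count at gene {bad!r}, sample {sample!r}"
            ) from None
        frac = numeric.astype(float) % 1 != 0
        if frac.any():
            bad = numeric.index[frac][0]
            raise ValueError(
                f"{path}: non-integer count {numeric[bad]!r} at gene {bad!r}, "
                f"sample {sample!r}"
            )
        counts[sample] = numeric.astype(np.int64)
    validate_counts(counts)
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a count matrix in the same tab-separated dialect it is read in.

    No comment header is added so a read/write cycle is byte-stable.
    """
    validate_counts(counts)
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "gene_id")


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            try:
                return csv.Sniffer().sniff(line, delimiters=",\t").delimiter
            except csv.Error:
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def read_phenotype(
    path,
    trait: str | None = None,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a per-sample phenotype table (CSV or TSV, auto-detected).

    First column is the sample identifier; ``NA`` (or empty) cells are
    treated as missing.  Non-numeric columns are kept as categorical
    covariates.  When ``trait`` is given, its presence and numeric type
    are enforced; covariates that are entirely missing are dropped with a
    warning.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    table = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                        na_values=["NA"])
    table.index.name = "sample_id"
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample identifier(s): {dups}")
    if trait is not None:
        if trait not in table.columns:
            raise ValueError(
                f"{path}: trait column {trait!r} not found; "
                f"columns are {list(table.columns)}"
            )
        if not pd.api.types.is_numeric_dtype(table[trait]):
            raise ValueError(f"{path}: trait column {trait!r} is not numeric")
        if table[trait].isna().all():
            raise ValueError(f"{path}: trait column {trait!r} is entirely missing")
    for name in covariates:
        if name not in table.columns:
            raise ValueError(f"{path}: covariate column {name!r} not found")
        if table[name].isna().all():
            warnings.warn(
                f"{path}: covariate {name!r} is entirely missing; dropped",
                stacklevel=2,
            )
            table = table.drop(columns=[name])
    return table


def write_phenotype(phenotype: pd.DataFrame, path) -> None:
    """Write a phenotype table as CSV (sample identifier first)."""
    phenotype.to_csv(path, index_label=phenotype.index.name or "sample_id",
                     na_rep="NA")


def read_factors(path) -> NormFactors:
    """Read normalization factors written by :func:`write_factors`."""
    path = Path(path)
    reference = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# reference="):
                reference = line.split("=", 1)[1].strip()
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if reference is None:
        raise ValueError(f"{path}: missing '# reference=' header line")
    return NormFactors(factors=table.iloc[:, 0].rename("tmm_factor"),
                       reference=reference)


def write_factors(factors: NormFactors, path) -> None:
    """Write factors as two-column TSV with version/reference header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tagseq {__version__} TMM factors\n")
        fh.write(f"# reference={factors.reference}\n")
        factors.factors.to_csv(fh, sep="\t", header=["tmm_factor"],
                               index_label="sample_id", float_format="%.10g")


def read_pvalues(path) -> pd.Series:
    """Read an external method's per-gene p-values (gene_id, pvalue TSV).

    This is the plug-in contract for comparing against tools not bundled
    here (e.g. count-model differential expression methods).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    table = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if table.shape[1] < 1:
        raise ValueError(f"{path}: expected columns gene_id, pvalue")
    pv = pd.to_numeric(table.iloc[:, 0], errors="coerce")
    if ((pv < 0) | (pv > 1)).any():
        bad = pv.index[(pv < 0) | (pv > 1)][0]
        raise ValueError(f"{path}: p-value out of [0, 1] for gene {bad!r}")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifier(s): {dups}")
    return pv.rename("pvalue")
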
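"""Delimited-table input/output.

Two genotype dialects are supported:

* ``csv-simple`` — header ``ID,snp1,...,snpM``, one row per individual,
  integer codes 0/1/2.
* ``plink-raw`` — whitespace-delimited PLINK ``.raw``-style export: six
  leading metadata columns (FID IID PAT MAT SEX PHENOTYPE) then per-SNP
  additive dosages; individual ids are taken from IID.

Missing genotype values are rejected outright (no silent imputation), and
out-of-range codes are reported with their row/column coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classic import AccuracyResult
from .exceptions import ParseError, ValidationError
from .grm import GRM
from .simulate import GenotypeMatrix, RecordCounts

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_counts_table",
    "write_counts_table",
    "write_scores",
    "read_grm_table",
    "write_grm_table",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _codes_from_frame(df: pd.DataFrame, ids: pd.Series, path) -> GenotypeMatrix:
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ParseError(
            f"{path}: missing genotype value for individual {ids.iloc[r]!r}, "
            f"column {df.columns[c]!r}; missing values are not supported"
        )
    codes = df.to_numpy()
    try:
        codes = codes.astype(np.int64)
    except (TypeError, ValueError):
        raise ParseError(f"{path}: non-integer genotype entries") from None
    bad = ~np.isin(codes, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: genotype code {codes[r, c]} not in {{0,1,2}} for "
            f"individual {ids.iloc[r]!r}, column {df.columns[c]!r}"
        )
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate individual id {dup!r}")
    return GenotypeMatrix(ids=tuple(ids.astype(str)), codes=codes)


def read_genotype_table(path: str | Path, dialect: str = "csv-simple") -> GenotypeMatrix:
    """Parse a genotype table in one of the supported dialects."""
    if dialect == "csv-simple":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected an ID column plus >= 1 SNP column")
        return _codes_from_frame(df.iloc[:, 1:], df.iloc[:, 0].astype(str), path)
    if dialect == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+")
        if list(df.columns[:6]) != _RAW_META:
            raise ParseError(
                f"{path}: plink-raw tables must start with columns "
                f"{' '.join(_RAW_META)}"
            )
        if df.shape[1] < 7:
            raise ParseError(f"{path}: plink-raw table has no SNP columns")
        return _codes_from_frame(df.iloc[:, 6:], df["IID"].astype(str), path)
    raise ValidationError(f"unknown genotype dialect {dialect!r}")


def write_genotype_table(
    g: GenotypeMatrix, path: str | Path, dialect: str = "csv-simple"
) -> None:
    """Write genotypes in the requested dialect (inverse of the reader)."""
    if dialect == "csv-simple":
        df = pd.DataFrame(
            g.codes, columns=[f"snp{j + 1}" for j in range(g.n_snps)]
        )
        df.insert(0, "ID", list(g.ids))
        df.to_csv(path, index=False)
    elif dialect == "plink-raw":
        df = pd.DataFrame(
            g.codes, columns=[f"snp{j + 1}_A" for j in range(g.n_snps)]
        )
        meta = pd.DataFrame(
            {
                "FID": list(g.ids),
                "IID": list(g.ids),
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        pd.concat([meta, df], axis=1).to_csv(path, sep=" ", index=False)
    else:
        raise ValidationError(f"unknown genotype dialect {dialect!r}")


def read_counts_table(path: str | Path) -> tuple[tuple[str, ...], RecordCounts]:
    """Two-column ``ID,count`` table -> (ids, RecordCounts)."""
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly two columns ID,count")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValidationError(f"{path}: duplicate ids in counts table")
    raw = df.iloc[:, 1]
    if raw.isna().any():
        raise ParseError(f"{path}: missing record counts")
    return tuple(ids), RecordCounts(counts=raw.to_numpy())


def write_counts_table(
    ids: tuple[str, ...], counts: RecordCounts, path: str | Path
) -> None:
    pd.DataFrame({"ID": list(ids), "count": counts.counts}).to_csv(path, index=False)


def write_scores(results: list[AccuracyResult], path: str | Path) -> None:
    """TSV of per-individual scores, floats at 10 significant digits."""
    with open(path, "w") as fh:
        fh.write("id\tcqq\treliability\taccuracy\tphenotyped\n")
        for r in results:
            fh.write(
                f"{r.id}\t{r.cqq:.10g}\t{r.reliability:.10g}\t"
                f"{r.accuracy:.10g}\t{int(r.phenotyped)}\n"
            )


def write_grm_table(grm: GRM, path: str | Path) -> None:
    """Dense delimited G with an ID header column."""
    df = pd.DataFrame(grm.values, columns=list(grm.ids))
    df.insert(0, "ID", list(grm.ids))
    df.to_csv(path, index=False, float_format="%.17g")


def read_grm_table(path: str | Path) -> GRM:
    """Read a dense G table written by :func:`write_grm_table`.

    ``denom`` and ``blend_weight`` metadata live in the JSON sidecar the CLI
    writes; here they default to NaN/1.0.
    """
    df = pd.read_csv(path)
    ids = tuple(df.iloc[:, 0].astype(str))
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if values.shape != (len(ids), len(ids)):
        raise ParseError(f"{path}: G table is not square")
    return GRM(ids=ids, values=values, denom=float("nan"), blend_weight=1.0)
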
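"""Expression-matrix, gene-set and sample-metadata I/O plus basic normalization.

The pipeline consumes three delimited-text inputs:

* an expression matrix (genes in rows, samples in columns, first column gene
  identifiers, header row sample identifiers) holding raw counts or FPKM;
* gene sets in standard GMT (one set per line: name, description, members);
* a sample table (TSV) with columns ``sample_id``, ``response_label``,
  ``timepoint``, ``pair_id``, ``cohort``.

Matrices are always genes x samples.  Counts are integers, no missing
values are permitted: an absent observation must be an explicit zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALUE_KINDS = ("counts", "fpkm", "normalized")

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_lengths",
    "read_sample_table",
    "read_gmt",
    "write_gmt",
    "counts_to_fpkm",
    "filter_low_expression",
]


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A gene x sample numeric matrix tagged with the kind of values it holds.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with sample ids as columns.
    value_kind:
        One of ``"counts"``, ``"fpkm"`` or ``"normalized"``.
    """

    data: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values).any():
            rows, cols = np.where(np.isnan(values))
            raise ValueError(
                "missing value at gene "
                f"{self.data.index[rows[0]]!r}, sample {self.data.columns[cols[0]]!r}; "
                "explicit zeros are required"
            )
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.value_kind == "counts" and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path, value_kind: str, *, transpose: bool = False
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix.

    ``transpose=True`` reads a samples x genes file; the orientation is never
    guessed.  Duplicate identifiers and non-numeric cells raise ``ValueError``
    naming the offender.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    _check_unique(df.index, "gene" if not transpose else "sample")
    _check_unique(df.columns, "sample" if not transpose else "gene")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            for row in df.index:
                try:
                    float(df.at[row, col])
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric cell at row {row!r}, column {col!r}: "
                        f"{df.at[row, col]!r}"
                    ) from None
        raise
    if transpose:
        numeric = numeric.T
    return ExpressionMatrix(numeric, value_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as delimited text (TSV, or CSV for ``.csv`` paths)."""
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column table (gene_id, length_bp) into a Series."""
    df = pd.read_csv(path, sep=_sep_for(path))
    lengths = pd.Series(
        df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str).str.strip()
    )
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValueError(f"gene length must be >= 1 bp; offender: {bad!r}")
    return lengths


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata and validate pre/on pairing.

    A non-null ``pair_id`` must link exactly two samples with distinct
    timepoints.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("sample table must contain a 'sample_id' column")
    _check_unique(df["sample_id"], "sample")
    if "pair_id" in df.columns:
        paired = df[df["pair_id"].notna() & (df["pair_id"] != "")]
        for pid, grp in paired.groupby("pair_id"):
            if len(grp) != 2:
                raise ValueError(
                    f"pair_id {pid!r} links {len(grp)} samples; exactly 2 required"
                )
            if "timepoint" in grp.columns and grp["timepoint"].nunique() != 2:
                raise ValueError(f"pair_id {pid!r} samples share a timepoint")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: member gene list}``.

    Each line needs at least name, description and one member.  Duplicate
    members within a line are dropped with a warning; a repeated set name is
    an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            dupes = 0
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dupes += 1
                    continue
                seen.add(g)
                members.append(g)
            if dupes:
                warnings.warn(
                    f"GMT set {name!r}: {dupes} duplicate member(s) dropped",
                    stacklevel=2,
                )
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write gene sets in GMT format."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def counts_to_fpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to FPKM.

    FPKM[g, s] = counts[g, s] * 1e9 / (library_size[s] * length_bp[g]),
    with library size the raw column sum of the input matrix.
    """
    if counts.value_kind != "counts":
        raise ValueError("counts_to_fpkm requires a counts matrix")
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene length for: {missing[:5]}")
    lib = counts.data.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"zero library size in sample {bad!r}")
    lens = lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    fpkm = counts.values * 1e9 / (lib.to_numpy(dtype=float)[None, :] * lens[:, None])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids), "fpkm"
    )


def filter_low_expression(
    counts: ExpressionMatrix, min_reads: int = 1, min_samples: int = 3
) -> ExpressionMatrix:
    """Drop genes without at least ``min_reads`` reads in ``min_samples`` samples.

    The default (1 read in 3 samples) is the conventional pre-filter for
    small bulk cohorts before differential expression.
    """
    if counts.value_kind != "counts":
        raise ValueError("filter_low_expression requires a counts matrix")
    n_samples = counts.shape[1]
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({n_samples})"
        )
    keep = (counts.data >= min_reads).sum(axis=1) >= min_samples
    return ExpressionMatrix(counts.data.loc[keep], "counts")
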
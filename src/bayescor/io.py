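"""Delimited-text I/O for count matrices and correlation matrices.

Count matrices travel as TSV/CSV with condition labels in the header row and
entity identifiers in the first column; missing cells are an error (there is
no NA semantics for raw counts).  Correlation matrices are written either as
a square labelled matrix or as long-format ``(entity_a, entity_b, r)``
triples above a threshold.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .correlation import CorrelationResult
from .count_model import CountMatrix

__all__ = [
    "UNATTRIBUTED_ID",
    "read_counts",
    "write_counts",
    "read_correlation",
    "write_correlation",
]

_CANDIDATE_DELIMITERS = ("\t", ",", ";")

#: Reserved entity id for the reads of each condition that belong to none of
#: the listed entities.  It lets a matrix covering only part of a larger
#: transcriptome carry its true sequencing depths through plain TSV: the row
#: holds ``R_c - sum_i R_ic`` and is folded back into the column totals (and
#: removed from the entity set) on reading.
UNATTRIBUTED_ID = "__unattributed__"


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(64 * 1024)
    if not sample.strip():
        raise ValueError(f"input file {path} is empty")
    try:
        return csv.Sniffer().sniff(sample, delimiters="".join(_CANDIDATE_DELIMITERS)).delimiter
    except csv.Error:
        # single-column file or no recognizable delimiter; default to tab
        return "\t"


def read_counts(path, delimiter: str | None = None) -> CountMatrix:
    """Read a count matrix from delimited text.

    The delimiter is auto-detected among tab, comma and semicolon unless
    given.  The header row holds condition labels and the first column holds
    entity identifiers; all remaining cells must be numeric and present.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"count matrix in {path} has no data rows or columns")
    if df.isna().any().any():
        raise ValueError(f"count matrix in {path} has missing cells")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"count matrix in {path} has non-numeric cells: {exc}") from None
    entity_ids = df.index.astype(str)
    column_totals = None
    if UNATTRIBUTED_ID in set(entity_ids):
        keep = entity_ids != UNATTRIBUTED_ID
        column_totals = values.sum(axis=0)
        values = values[keep]
        entity_ids = entity_ids[keep]
    return CountMatrix(
        values,
        entity_ids=entity_ids,
        condition_ids=df.columns.astype(str),
        column_totals=column_totals,
    )


def write_counts(R: CountMatrix, path, delimiter: str = "\t") -> None:
    """Write a count matrix as delimited text (inverse of :func:`read_counts`).

    Integral counts are written without a decimal point so that matrices
    round-trip byte-for-byte through read/write.  If the matrix's column
    totals exceed its column sums (a sub-matrix of a larger transcriptome),
    the difference is written as a trailing :data:`UNATTRIBUTED_ID` row so
    the depths survive the round-trip.
    """
    values = R.counts
    ids = list(R.entity_ids)
    leftover = R.column_totals - R.counts.sum(axis=0)
    if np.any(leftover > 0):
        values = np.vstack([values, leftover])
        ids.append(UNATTRIBUTED_ID)
    df = pd.DataFrame(values, index=ids, columns=list(R.condition_ids))
    if np.all(values == np.round(values)):
        df = df.astype(np.int64)
    df.to_csv(path, sep=delimiter, index_label="entity")


def write_correlation(
    result: CorrelationResult,
    path,
    delimiter: str = "\t",
    digits: int = 6,
    fmt: str = "square",
    threshold: float | None = None,
) -> None:
    """Write a correlation matrix as square or long-format delimited text.

    In ``long`` format each unordered pair appears once as
    ``(entity_a, entity_b, r)``; pairs with ``|r|`` below ``threshold`` (or
    undefined) are omitted.
    """
    ids = list(result.entity_ids)
    if fmt == "square":
        df = pd.DataFrame(result.matrix, index=ids, columns=ids)
        df.to_csv(path, sep=delimiter, index_label="entity",
                  float_format=f"%.{digits}f")
    elif fmt == "long":
        thr = 0.0 if threshold is None else float(threshold)
        iu, ju = np.triu_indices(len(ids), k=1)
        r = result.matrix[iu, ju]
        keep = ~np.isnan(r) & (np.abs(r) >= thr)
        df = pd.DataFrame(
            {
                "entity_a": [ids[i] for i in iu[keep]],
                "entity_b": [ids[j] for j in ju[keep]],
                "r": r[keep],
            }
        )
        df.to_csv(path, sep=delimiter, index=False, float_format=f"%.{digits}f")
    else:
        raise ValueError(f"unknown output format {fmt!r}; expected 'square' or 'long'")


def read_correlation(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a square correlation matrix written by :func:`write_correlation`."""
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"correlation matrix in {path} is not square")
    return df
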
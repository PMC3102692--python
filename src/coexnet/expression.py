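"""Expression-matrix input/output, the log2 transform, and low-information gene filtering.

The in-memory representation of an expression matrix is a :class:`pandas.DataFrame`
with unique gene identifiers as the index and stage/sample labels as columns
(e.g. ``L-l``, ``S-9``, ``C-6`` for the growth, starvation and conjugation
stages of the *Tetrahymena* life cycle). All operations validate the invariants
(unique gene ids, finite numeric values) on entry.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, ParseError, ValidationError

__all__ = [
    "FilterReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_expression_matrix",
    "log2_transform",
    "filter_low_information",
]


@dataclass(frozen=True)
class FilterReport:
    """Outcome of :func:`filter_low_information`.

    Attributes
    ----------
    kept, removed:
        Gene identifiers surviving / failing the combined filter. Together
        they partition the input gene set.
    median_range:
        Median over all input genes of the per-gene (max - min) expression
        difference, computed once on the full input before any removal.
    median_mean:
        Median over all input genes of the per-gene mean expression signal,
        likewise computed on the full input.
    """

    kept: tuple[str, ...]
    removed: tuple[str, ...]
    median_range: float
    median_mean: float


def validate_expression_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants, returning ``m`` unchanged."""
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r}")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = m.columns[[not np.issubdtype(d, np.number) for d in m.dtypes]][0]
        raise ParseError(f"non-numeric values in column {bad!r}")
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite value for gene {m.index[i]!r}, sample {m.columns[j]!r}"
        )
    return m


def _read_tsv_table(text: str, source: str) -> pd.DataFrame:
    """Parse a tab-delimited gene × sample table with strict shape checks."""
    rows = list(csv.reader(io.StringIO(text), delimiter="\t"))
    rows = [r for r in rows if r and any(field.strip() for field in r)]
    if not rows:
        raise ParseError(f"{source}: empty table")
    header = rows[0]
    n_cols = len(header)
    labels = [h.strip().strip('"') for h in header[1:]]
    gene_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ParseError(
                f"{source}: line {lineno} has {len(row)} fields, expected {n_cols}"
            )
        gene = row[0].strip().strip('"')
        values = []
        for label, cell in zip(labels, row[1:]):
            try:
                values.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{source}: line {lineno}: non-numeric value {cell!r} "
                    f"for gene {gene!r}, sample {label!r}"
                ) from None
        gene_ids.append(gene)
        data.append(values)
    m = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene"), columns=labels)
    return validate_expression_matrix(m)


def read_expression_matrix(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes × samples expression matrix.

    Parameters
    ----------
    path:
        Tab-delimited file; first column gene id, header row sample labels.
    dialect:
        ``"tsv"`` for a plain table, or ``"geo_series_matrix"`` for a GEO
        series-matrix file, in which ``!``-prefixed metadata lines are skipped
        and the table is delimited by the ``!series_matrix_table_begin`` /
        ``!series_matrix_table_end`` markers.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if dialect == "tsv":
        return _read_tsv_table(text, str(path))
    if dialect == "geo_series_matrix":
        lines = text.splitlines()
        begin = [i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")]
        end = [i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")]
        if begin and end:
            table = lines[begin[0] + 1 : end[0]]
        else:
            table = [l for l in lines if not l.startswith("!")]
        return _read_tsv_table("\n".join(table), str(path))
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def write_expression_matrix(m: pd.DataFrame, path) -> None:
    """Write a matrix in the tab-delimited dialect read back by :func:`read_expression_matrix`."""
    validate_expression_matrix(m)
    m.to_csv(path, sep="\t", index_label=m.index.name or "gene")


def log2_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Return the element-wise base-2 logarithm of ``m``.

    Raises
    ------
    DomainError
        If any value is ≤ 0, naming the first offending gene and sample.
    """
    validate_expression_matrix(m)
    values = m.to_numpy()
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise DomainError(
            f"log2 undefined: gene {m.index[i]!r}, sample {m.columns[j]!r} "
            f"has value {values[i, j]!r} <= 0"
        )
    return pd.DataFrame(np.log2(values), index=m.index, columns=m.columns)


def filter_low_information(m: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the combined low-information gene filter.

    A gene is removed iff BOTH hold, with both medians computed once on the
    full input before any removal:

    1. its between-sample expression difference (max - min) is strictly below
       the median of all genes' differences, and
    2. its mean expression signal is strictly below the median of all genes'
       means.

    Genes failing only one condition are kept, as are genes exactly at a
    median (strict inequality). The surviving matrix preserves input row
    order. The function is scale-agnostic: it filters whichever scale (raw
    or log2) it is handed.
    """
    validate_expression_matrix(m)
    if m.shape[1] < 2:
        raise ValidationError(
            "low-information filtering needs >= 2 samples; "
            "the between-sample expression difference is undefined otherwise"
        )
    values = m.to_numpy()
    ranges = values.max(axis=1) - values.min(axis=1)
    means = values.mean(axis=1)
    median_range = float(np.median(ranges))
    median_mean = float(np.median(means))
    removed_mask = (ranges < median_range) & (means < median_mean)
    kept_ids = tuple(m.index[~removed_mask])
    removed_ids = tuple(m.index[removed_mask])
    return m.loc[~removed_mask], FilterReport(kept_ids, removed_ids, median_range, median_mean)
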
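"""Multinomial count tables and the DNA nucleotide-count front end.

A :class:`CountTable` is an ``h x k`` matrix of nonnegative integer counts:
``h`` independent groups (rows), ``k`` mutually exclusive categories
(columns).  Tables are read from and written to CSV/TSV with a header row
of category labels and a leading column of group labels; thousands
separators inside numeric cells are accepted, so published tables can be
used verbatim.

:func:`count_nucleotides` derives such a table from a FASTA file, with the
categories fixed to A, C, G, T.  Characters outside that alphabet
(ambiguity codes, gaps) are excluded from the counts, not errors, and
their number is reported per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CountTable",
    "NeutrosophicCountTable",
    "NucleotideCounts",
    "read_count_table",
    "write_count_table",
    "count_nucleotides",
    "NUCLEOTIDES",
]

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")

Dialect = Literal["csv", "tsv"]
_SEPARATORS: dict[str, str] = {"csv": ",", "tsv": "\t"}


@dataclass(frozen=True)
class CountTable:
    """Observed counts for ``h`` groups over ``k`` categories."""

    group_labels: tuple[str, ...]
    category_labels: tuple[str, ...]
    counts: np.ndarray  # h x k, nonnegative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be a 2-D matrix, got ndim={counts.ndim}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            j, i = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count {counts[j, i]} at group "
                f"{self.group_labels[j]!r}, category {self.category_labels[i]!r}"
            )
        h, k = counts.shape
        if h < 1:
            raise ValueError("a count table needs at least one group")
        if k < 2:
            raise ValueError(f"a count table needs at least 2 categories, got {k}")
        groups = tuple(str(g) for g in self.group_labels)
        cats = tuple(str(c) for c in self.category_labels)
        if len(groups) != h or len(cats) != k:
            raise ValueError(
                f"label lengths ({len(groups)} groups, {len(cats)} categories) "
                f"do not match counts shape {counts.shape}"
            )
        if any(not g for g in groups) or any(not c for c in cats):
            raise ValueError("labels must be non-empty")
        if len(set(groups)) != h:
            raise ValueError("group labels must be unique")
        if len(set(cats)) != k:
            raise ValueError("category labels must be unique")
        counts.setflags(write=False)
        object.__setattr__(self, "group_labels", groups)
        object.__setattr__(self, "category_labels", cats)
        object.__setattr__(self, "counts", counts)

    @property
    def n_groups(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def group_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def category_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=list(self.group_labels),
            columns=list(self.category_labels),
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(
            group_labels=tuple(str(i) for i in frame.index),
            category_labels=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(),
        )

    def permute_groups(self, order: Sequence[int]) -> "CountTable":
        order = list(order)
        return CountTable(
            tuple(self.group_labels[j] for j in order),
            self.category_labels,
            self.counts[order, :],
        )

    def permute_categories(self, order: Sequence[int]) -> "CountTable":
        order = list(order)
        return CountTable(
            self.group_labels,
            tuple(self.category_labels[i] for i in order),
            self.counts[:, order],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.group_labels == other.group_labels
            and self.category_labels == other.category_labels
            and np.array_equal(self.counts, other.counts)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays: hash on labels
        return hash((self.group_labels, self.category_labels))


@dataclass(frozen=True)
class NeutrosophicCountTable:
    """An interval-valued count table: elementwise lower and upper counts.

    Both endpoint tables share labels and shape and satisfy
    ``lower.counts <= upper.counts`` elementwise.  A degenerate instance
    (``lower == upper``) represents ordinary determinate counts.
    """

    lower: CountTable
    upper: CountTable

    def __post_init__(self) -> None:
        if self.lower.group_labels != self.upper.group_labels:
            raise ValueError("lower and upper tables have different group labels")
        if self.lower.category_labels != self.upper.category_labels:
            raise ValueError("lower and upper tables have different category labels")
        if (self.lower.counts > self.upper.counts).any():
            raise ValueError("lower counts exceed upper counts in at least one cell")

    @classmethod
    def degenerate(cls, table: CountTable) -> "NeutrosophicCountTable":
        return cls(table, table)

    @property
    def is_degenerate(self) -> bool:
        return np.array_equal(self.lower.counts, self.upper.counts)


class NucleotideCounts(NamedTuple):
    """Result of counting bases in a FASTA file."""

    table: CountTable
    excluded: tuple[int, ...]  # non-ACGT characters dropped, per group


def read_count_table(path: str | Path, dialect: Dialect = "csv") -> CountTable:
    """Read a count table from CSV or TSV.

    Layout: first row holds category labels, first column holds group
    labels, body cells are nonnegative integers.  Thousands separators
    (``38,514``) are stripped.  Errors name the offending cell.
    """
    path = Path(path)
    if dialect not in _SEPARATORS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    frame = pd.read_csv(
        path, sep=_SEPARATORS[dialect], index_col=0, dtype=str,
        skipinitialspace=True, quotechar='"',
    )
    if frame.shape[1] < 2:
        raise ValueError(
            f"{path}: a count table needs at least 2 category columns, "
            f"got {frame.shape[1]}"
        )
    counts = np.empty(frame.shape, dtype=np.int64)
    for j, group in enumerate(frame.index):
        for i, cat in enumerate(frame.columns):
            raw = str(frame.iat[j, i]).strip().replace(",", "")
            try:
                value = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer cell {frame.iat[j, i]!r} at group "
                    f"{group!r}, category {cat!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"{path}: negative count {value} at group {group!r}, "
                    f"category {cat!r}"
                )
            counts[j, i] = value
    return CountTable(
        group_labels=tuple(str(g).strip() for g in frame.index),
        category_labels=tuple(str(c).strip() for c in frame.columns),
        counts=counts,
    )


def write_count_table(
    table: CountTable, path: str | Path, dialect: Dialect = "csv"
) -> None:
    """Write a count table so that :func:`read_count_table` round-trips it."""
    if dialect not in _SEPARATORS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    table.to_dataframe().to_csv(Path(path), sep=_SEPARATORS[dialect])


def count_nucleotides(
    fasta_path: str | Path,
    grouping: Literal["per-record", "pooled"] = "per-record",
) -> NucleotideCounts:
    """Count A/C/G/T per FASTA record (or pooled over all records).

    Sequences are uppercased before counting; characters outside
    ``{A, C, G, T}`` are excluded and tallied per group in
    ``NucleotideCounts.excluded``.  Per-record grouping yields one table
    row per record (labelled by record id); pooled grouping yields a
    single row labelled ``"pooled"``.
    """
    fasta_path = Path(fasta_path)
    if grouping not in ("per-record", "pooled"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if not fasta_path.exists():
        raise FileNotFoundError(f"FASTA file not found: {fasta_path}")

    rows: list[np.ndarray] = []
    labels: list[str] = []
    excluded: list[int] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        row = np.array([seq.count(base) for base in NUCLEOTIDES], dtype=np.int64)
        if row.sum() == 0:
            raise ValueError(
                f"record {record.id!r} contains no countable A/C/G/T bases"
            )
        rows.append(row)
        labels.append(record.id)
        excluded.append(len(seq) - int(row.sum()))
    if not rows:
        raise ValueError(f"no FASTA records found in {fasta_path}")

    if grouping == "pooled":
        counts = np.vstack(rows).sum(axis=0, keepdims=True)
        table = CountTable(("pooled",), NUCLEOTIDES, counts)
        return NucleotideCounts(table, (sum(excluded),))

    table = CountTable(tuple(labels), NUCLEOTIDES, np.vstack(rows))
    return NucleotideCounts(table, tuple(excluded))
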
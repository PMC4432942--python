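"""Ingestion of contig metadata tables, contig sequences, and GFF3 annotations.

This module mirrors an assembly-explorer upload wizard: a delimited text
table (one row per contig, header in the first row) is parsed and each
column's kind is inferred; the user then assigns plot roles to columns
(contig id, x-axis, y-axis, point size, color); optional FASTA sequences
and GFF3 gene annotations are cross-validated against the table and the
three parts combine into one :class:`Dataset`.

Conventions
-----------
* Column kinds: a column is *numeric* iff every non-missing cell parses as
  a plain real number (scientific notation accepted, thousands separators
  and ``inf``/``nan`` tokens rejected); otherwise it is *ordinal*. The id
  column becomes *identifier* once roles are assigned.
* Missing values: empty cells. Numeric columns store them as NaN, text
  columns as ``None``. They are excluded from filters and binning.
* GC content: fraction of G+C among unambiguous A/C/G/T bases,
  case-insensitive; N and IUPAC ambiguity codes are excluded from the
  denominator so gappy contigs are not biased toward 0.5.
* Coordinates: GFF3, 1-based inclusive.

All readers accept file paths (plain or gzip-compressed, detected by a
``.gz`` suffix) or open text handles.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import Feature as _GffFeature, feature_from_line as _gff_from_line

from .errors import (
    AnnotationError,
    LinkError,
    RoleError,
    SequenceError,
    TableError,
)

logger = logging.getLogger(__name__)

KINDS = ("numeric", "ordinal", "identifier")
ROLES = ("id", "x", "y", "size", "color", "filter", "info")
#: roles that may be held by at most one column each
_UNIQUE_ROLES = ("id", "x", "y", "size", "color")

# Plain real number: optional sign, digits with optional decimal point or a
# bare ".5", optional exponent.  Deliberately rejects "1_000", "1,000",
# "inf" and "nan" so kind inference is predictable.
_NUMERIC_RE = re.compile(r"^[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?$")

_GC_SET = frozenset("GCgc")
_ATGC_SET = frozenset("ACGTacgt")


def _is_numeric_token(cell: str) -> bool:
    return bool(_NUMERIC_RE.match(cell))


def render_value(value) -> str:
    """Canonical text rendering of a cell: shortest full-precision repr for
    floats, empty string for missing.  Search and CSV export both use this
    rendering, so a search for ``3051`` matches a coverage of ``3051.0``."""
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def _open_text(source, mode: str = "rt"):
    """Return (handle, should_close) for a path or an open text handle."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8", newline=""), True
    return open(path, mode, encoding="utf-8", newline=""), True


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    """One table column: its name, inferred kind, and plot role."""

    name: str
    kind: str = "ordinal"
    role: str = "info"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise TableError(f"unknown column kind {self.kind!r}")
        if self.role not in ROLES:
            raise TableError(f"unknown column role {self.role!r}")
        if self.role == "filter" and self.kind != "numeric":
            raise TableError(
                f"column {self.name!r}: role 'filter' requires a numeric column"
            )


@dataclass(frozen=True)
class ContigRecord:
    """Typed view of one contig row with the canonical fields pulled out."""

    contig_id: str
    length: int | None = None
    gc: float | None = None
    coverage: float | None = None
    lineage_text: str | None = None
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.contig_id:
            raise TableError("contig_id must be non-empty")
        if self.length is not None and self.length < 0:
            raise TableError(f"{self.contig_id}: negative length")
        if self.gc is not None and not 0.0 <= self.gc <= 1.0:
            raise TableError(f"{self.contig_id}: gc {self.gc} outside [0, 1]")
        if self.coverage is not None and self.coverage < 0:
            raise TableError(f"{self.contig_id}: negative coverage")


# canonical metadata column names recognised when building ContigRecords
_CANON = {
    "length": ("length", "len", "contig length", "seq length"),
    "gc": ("gc", "gc content", "gc_content", "gc%"),
    "coverage": ("coverage", "ave. fold coverage", "avg fold coverage",
                 "average fold coverage", "cov", "depth"),
    "lineage": ("complete lineage", "lineage", "taxonomy"),
}


def canonical_column(table: "ContigTable", which: str) -> str | None:
    """Find the table column holding a canonical quantity (by common names)."""
    wanted = _CANON[which]
    lower = {spec.name.lower(): spec.name for spec in table.columns}
    for cand in wanted:
        if cand in lower:
            return lower[cand]
    return None


class ContigTable:
    """Ordered, typed contig metadata table.

    Backed by a :class:`pandas.DataFrame` (numeric columns float64 with NaN
    for missing, text columns object with ``None``) plus a parallel list of
    :class:`ColumnSpec`.
    """

    def __init__(self, columns: Sequence[ColumnSpec], df: pd.DataFrame):
        names = [c.name for c in columns]
        if list(df.columns) != names:
            raise TableError("column specs do not match dataframe columns")
        if len(set(names)) != len(names):
            raise TableError(f"duplicate column names: {sorted(names)}")
        self.columns: list[ColumnSpec] = list(columns)
        self.df = df

    # -- basic accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def spec(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise TableError(f"no such column: {name!r}")

    def has_column(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    def values(self, name: str) -> np.ndarray:
        self.spec(name)
        return self.df[name].to_numpy()

    @property
    def id_spec(self) -> ColumnSpec | None:
        for c in self.columns:
            if c.role == "id":
                return c
        return None

    @property
    def contig_ids(self) -> list[str]:
        spec = self.id_spec
        if spec is None:
            raise TableError("no column has role 'id'; call assign_roles first")
        return [str(v) for v in self.df[spec.name]]

    def with_specs(self, columns: Sequence[ColumnSpec]) -> "ContigTable":
        return ContigTable(columns, self.df)

    def subset(self, ids: Iterable[str]) -> "ContigTable":
        """Rows whose contig id is in *ids*, preserving original row order."""
        keep = set(ids)
        mask = [cid in keep for cid in self.contig_ids]
        return ContigTable(self.columns, self.df[mask].reset_index(drop=True))

    # -- records ------------------------------------------------------------
    def records(self) -> Iterator[ContigRecord]:
        """Yield typed records; canonical fields located by common names."""
        id_spec = self.id_spec
        if id_spec is None:
            raise TableError("no column has role 'id'")
        cols = {k: canonical_column(self, k) for k in _CANON}
        special = {id_spec.name} | {c for c in cols.values() if c}
        for _, row in self.df.iterrows():
            length = row.get(cols["length"]) if cols["length"] else None
            gc = row.get(cols["gc"]) if cols["gc"] else None
            cov = row.get(cols["coverage"]) if cols["coverage"] else None
            lin = row.get(cols["lineage"]) if cols["lineage"] else None

            def _num(v):
                return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

            yield ContigRecord(
                contig_id=str(row[id_spec.name]),
                length=None if _num(length) is None else int(length),
                gc=_num(gc),
                coverage=_num(cov),
                lineage_text=None if lin in (None, "") else str(lin),
                extra={c.name: row[c.name] for c in self.columns
                       if c.name not in special},
            )

    # -- equality -----------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, ContigTable):
            return NotImplemented
        if self.columns != other.columns or len(self) != len(other):
            return False
        for spec in self.columns:
            a, b = self.df[spec.name], other.df[spec.name]
            if spec.kind == "numeric":
                av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
                if not np.array_equal(av, bv, equal_nan=True):
                    return False
            else:
                if not a.where(a.notna(), None).equals(b.where(b.notna(), None)):
                    return False
        return True

    def __repr__(self) -> str:
        return f"<ContigTable {len(self)} rows × {len(self.columns)} columns>"


@dataclass(frozen=True)
class AnnotationFeature:
    """One GFF3 feature (1-based inclusive coordinates).

    ``attributes`` maps attribute keys to tuples of (already unescaped)
    values, preserving file order.
    """

    contig_id: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    ftype: str
    attributes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    source: str = "."
    score: str = "."
    phase: str = "."

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise AnnotationError(
                f"{self.contig_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def attribute_values(self) -> Iterator[str]:
        for vals in self.attributes.values():
            yield from vals

    def to_gff_line(self) -> str:
        """Serialize back to one GFF3 line (attribute escaping delegated to
        gffutils)."""
        feat = _GffFeature(
            seqid=self.contig_id,
            source=self.source,
            featuretype=self.ftype,
            start=self.start,
            end=self.end,
            score=self.score,
            strand=self.strand,
            frame=self.phase,
            attributes={k: list(v) for k, v in self.attributes.items()},
        )
        return str(feat)


#: A sequence set is a plain ordered mapping contig_id -> nucleotide string.
SequenceSet = dict


@dataclass
class Dataset:
    """A validated bundle: metadata table (+roles), optional sequences and
    annotations, cross-referenced by contig id."""

    table: ContigTable
    sequences: dict[str, str] | None = None
    annotations: list[AnnotationFeature] | None = None

    @property
    def contig_ids(self) -> list[str]:
        return self.table.contig_ids

    def features_of(self, contig_id: str) -> list[AnnotationFeature]:
        return self._by_contig().get(contig_id, [])

    def _by_contig(self) -> dict[str, list[AnnotationFeature]]:
        cached = getattr(self, "_feature_index", None)
        if cached is None:
            cached = {}
            for feat in self.annotations or ():
                cached.setdefault(feat.contig_id, []).append(feat)
            object.__setattr__(self, "_feature_index", cached)
        return cached


# ---------------------------------------------------------------------------
# table reading / writing
# ---------------------------------------------------------------------------

def _detect_delimiter(header_line: str) -> str:
    tabs, commas = header_line.count("\t"), header_line.count(",")
    if tabs > commas:
        return "\t"
    if commas > tabs:
        return ","
    raise TableError(
        "cannot auto-detect delimiter: header has equal counts of tabs and "
        "commas; pass dialect='tab' or dialect='comma'"
    )


def read_metadata_table(source, dialect: str = "auto") -> ContigTable:
    """Parse a delimited contig metadata table.

    The first row is the header; kinds are inferred per column (numeric iff
    every non-missing cell is a plain real number); every role starts as
    ``info``.
    """
    if dialect not in ("auto", "tab", "comma"):
        raise TableError(f"unknown dialect {dialect!r}")
    handle, close = _open_text(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if not text.strip():
        raise TableError("empty metadata source")

    first_line = text.splitlines()[0]
    delim = {"tab": "\t", "comma": ","}.get(dialect) or _detect_delimiter(first_line)

    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if r]  # ignore fully blank lines
    header = rows[0]
    if any(not h.strip() for h in header):
        raise TableError("empty column name in header")
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise TableError(f"duplicate column names: {sorted(dupes)}")

    ncol = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise TableError(
                f"row {i}: expected {ncol} fields, got {len(row)}"
            )

    data_rows = rows[1:]
    columns: list[ColumnSpec] = []
    series: dict[str, object] = {}
    for j, name in enumerate(header):
        cells = [row[j] for row in data_rows]
        non_missing = [c for c in cells if c != ""]
        numeric = all(_is_numeric_token(c) for c in non_missing)
        if numeric:
            vals = np.array(
                [float(c) if c != "" else np.nan for c in cells], dtype=float
            )
            columns.append(ColumnSpec(name, "numeric", "info"))
            series[name] = vals
        else:
            columns.append(ColumnSpec(name, "ordinal", "info"))
            series[name] = pd.Series(
                [c if c != "" else None for c in cells], dtype=object
            )
    df = pd.DataFrame(series, columns=header)
    return ContigTable(columns, df)


def write_metadata_table(table: ContigTable, dest, dialect: str = "comma") -> None:
    """Write a table back to delimited text (RFC-4180 quoting for CSV).

    Values are rendered at full precision; missing cells become empty
    strings, so ``read_metadata_table(write(t)) == t`` for tables the
    reader produced.
    """
    delim = {"comma": ",", "tab": "\t"}.get(dialect)
    if delim is None:
        raise TableError(f"unknown dialect {dialect!r}")
    handle, close = _open_text(dest, "wt")
    try:
        writer = csv.writer(handle, delimiter=delim, lineterminator="\n")
        writer.writerow(table.column_names)
        cols = [table.df[c.name].tolist() for c in table.columns]
        for row in zip(*cols) if cols else ():
            writer.writerow([render_value(v) for v in row])
        if not cols:  # zero-column table cannot occur; zero rows can
            pass
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# role assignment
# ---------------------------------------------------------------------------

def assign_roles(table: ContigTable, roles: Mapping[str, str]) -> Dataset:
    """Apply a column→role mapping and auto-assign the rest.

    Exactly one column must map to ``id`` (with unique, non-empty values).
    Numeric columns not claimed by x/y/size/color become ``filter``
    parameters; remaining columns become ``info``.
    """
    for name, role in roles.items():
        if not table.has_column(name):
            raise RoleError(f"no such column: {name!r}")
        if role not in ROLES:
            raise RoleError(f"unknown role {role!r} for column {name!r}")
    for role in _UNIQUE_ROLES:
        holders = [n for n, r in roles.items() if r == role]
        if len(holders) > 1:
            raise RoleError(f"role {role!r} assigned to multiple columns: {holders}")
    id_cols = [n for n, r in roles.items() if r == "id"]
    if not id_cols:
        raise RoleError("no column assigned to role 'id'")
    id_col = id_cols[0]

    ids = [render_value(v) for v in table.df[id_col]]
    if any(v == "" for v in ids):
        raise RoleError(f"id column {id_col!r} contains empty values")
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for v in ids:
            (dupes if v in seen else seen).add(v)
        raise RoleError(f"id column {id_col!r} has duplicate values: {sorted(dupes)[:5]}")

    for name, role in roles.items():
        if role in ("x", "y", "size") and table.spec(name).kind != "numeric":
            raise RoleError(
                f"role {role!r} requires a numeric column but {name!r} is "
                f"{table.spec(name).kind}"
            )

    new_specs = []
    for spec in table.columns:
        if spec.name == id_col:
            new_specs.append(replace(spec, kind="identifier", role="id"))
        elif spec.name in roles:
            new_specs.append(replace(spec, role=roles[spec.name]))
        elif spec.kind == "numeric":
            new_specs.append(replace(spec, role="filter"))
        else:
            new_specs.append(replace(spec, role="info"))
    # id column values normalised to their text rendering
    df = table.df.copy()
    df[id_col] = pd.Series(ids, dtype=object)
    return Dataset(table=ContigTable(new_specs, df))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(source) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into an ordered mapping."""
    from Bio import SeqIO

    handle, close = _open_text(source)
    try:
        sequences: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in sequences:
                raise SequenceError(f"duplicate FASTA id {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise SequenceError(f"empty sequence for {rec.id!r}")
            sequences[rec.id] = seq
    finally:
        if close:
            handle.close()
    if not sequences:
        raise SequenceError("no FASTA records found")
    return sequences


def compute_sequence_stats(sequences: Mapping[str, str]) -> dict[str, dict]:
    """Per-contig length (bp) and GC fraction.

    GC = (#G + #C) / (#A + #C + #G + #T), case-insensitive; N and ambiguity
    codes count toward length but not toward the GC denominator. GC is None
    when no unambiguous base exists.
    """
    stats: dict[str, dict] = {}
    for cid, seq in sequences.items():
        if not seq:
            raise SequenceError(f"empty sequence for {cid!r}")
        gc_n = sum(1 for ch in seq if ch in _GC_SET)
        denom = sum(1 for ch in seq if ch in _ATGC_SET)
        stats[cid] = {
            "length": len(seq),
            "gc": (gc_n / denom) if denom else None,
        }
    return stats


def add_sequence_stats(table: ContigTable, sequences: Mapping[str, str]) -> ContigTable:
    """Append ``length``/``gc`` columns computed from sequences when the
    table lacks them (missing for contigs without a sequence)."""
    stats = compute_sequence_stats(sequences)
    ids = table.contig_ids
    df = table.df.copy()
    specs = list(table.columns)
    if canonical_column(table, "length") is None:
        df["length"] = np.array(
            [float(stats[c]["length"]) if c in stats else np.nan for c in ids]
        )
        specs.append(ColumnSpec("length", "numeric", "filter"))
    if canonical_column(table, "gc") is None:
        df["gc"] = np.array(
            [
                np.nan if c not in stats or stats[c]["gc"] is None
                else stats[c]["gc"]
                for c in ids
            ]
        )
        specs.append(ColumnSpec("gc", "numeric", "filter"))
    return ContigTable(specs, df)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(source) -> list[AnnotationFeature]:
    """Parse GFF3 feature lines; comment and pragma lines are ignored."""
    handle, close = _open_text(source)
    features: list[AnnotationFeature] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}..{fields[4]!r}"
                ) from None
            if not 1 <= start <= end:
                raise AnnotationError(
                    f"line {lineno}: start {start} > end {end} (or start < 1)"
                )
            strand = fields[6].replace("−", "-")
            try:
                parsed = _gff_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(f"line {lineno}: {exc}") from None
            features.append(
                AnnotationFeature(
                    contig_id=fields[0],
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-", ".") else ".",
                    ftype=fields[2],
                    attributes={k: tuple(v) for k, v in parsed.attributes.items()},
                    source=fields[1],
                    score=fields[5],
                    phase=fields[7],
                )
            )
    finally:
        if close:
            handle.close()
    return features


# ---------------------------------------------------------------------------
# attachment
# ---------------------------------------------------------------------------

def attach(
    table: ContigTable,
    sequences: Mapping[str, str] | None = None,
    annotations: Sequence[AnnotationFeature] | None = None,
) -> Dataset:
    """Combine table + optional sequences/annotations into a Dataset.

    Sequence ids absent from the table are an error (the FASTA does not
    describe this assembly); annotation features on unknown contigs are
    dropped with a logged count (partial GFFs are common in practice).
    """
    known = set(table.contig_ids)
    seqs = None
    if sequences is not None:
        unknown = [cid for cid in sequences if cid not in known]
        if unknown:
            raise LinkError(
                f"{len(unknown)} sequence id(s) absent from table: "
                f"{sorted(unknown)[:10]}"
            )
        seqs = dict(sequences)
    feats = None
    if annotations is not None:
        feats, dropped = [], 0
        for feat in annotations:
            if feat.contig_id in known:
                feats.append(feat)
            else:
                dropped += 1
        if dropped:
            logger.warning(
                "dropped %d annotation feature(s) on contigs absent from the table",
                dropped,
            )
    return Dataset(table=table, sequences=seqs, annotations=feats)
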
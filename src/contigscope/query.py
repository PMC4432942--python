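"""Search, range filters, group visibility, and GC×coverage genome gating.

Search scans *every* metadata field (by its canonical text rendering, so a
search for ``3051`` matches a coverage value) plus all annotation feature
types and attribute values; matching is case-insensitive substring by
default, with regular expressions behind an explicit flag. Numeric range
filters conjoin; missing values fail every filter (conservative
exclusion). Genome bins are axis-aligned rectangles in the (GC, coverage)
plane; the first matching gate in list order wins.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import QueryError
from .ingest import ContigTable, Dataset, canonical_column, render_value
from .taxonomy import TaxonPartition

UNBINNED = "unbinned"


@dataclass(frozen=True)
class FilterRange:
    """Inclusive numeric range on one column."""

    column: str
    min: float = -math.inf
    max: float = math.inf

    def __post_init__(self):
        if self.min > self.max:
            raise QueryError(
                f"filter on {self.column!r}: min {self.min} > max {self.max}"
            )


@dataclass(frozen=True)
class Selection:
    """A set of contig ids plus a human-readable provenance string."""

    contig_ids: frozenset
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.contig_ids)

    def __contains__(self, cid: str) -> bool:
        return cid in self.contig_ids

    def ordered(self, dataset: Dataset) -> list[str]:
        """Selected ids in the dataset's original row order."""
        return [cid for cid in dataset.contig_ids if cid in self.contig_ids]

    def to_csv(self, dest) -> None:
        from .ingest import _open_text

        handle, close = _open_text(dest, "wt")
        try:
            handle.write("contig_id\n")
            for cid in sorted(self.contig_ids):
                handle.write(f"{cid}\n")
        finally:
            if close:
                handle.close()


@dataclass
class SearchResult:
    """Per-contig hit counts for one search term.

    A contig's count = number of metadata fields whose rendering contains
    the term + number of annotation features whose type or any attribute
    value contains it. Contigs with zero hits are omitted.
    """

    term: str
    per_contig_hits: dict[str, int] = field(default_factory=dict)

    @property
    def total_hits(self) -> int:
        return sum(self.per_contig_hits.values())

    def __len__(self) -> int:
        return len(self.per_contig_hits)

    def selection(self) -> Selection:
        return Selection(
            frozenset(self.per_contig_hits), provenance=f"search:{self.term}"
        )


@dataclass(frozen=True)
class GateRect:
    """Axis-aligned rectangle in the (GC, coverage) plane with a bin label."""

    label: str
    gc_min: float
    gc_max: float
    cov_min: float
    cov_max: float

    def __post_init__(self):
        if self.gc_min > self.gc_max or self.cov_min > self.cov_max:
            raise QueryError(f"gate {self.label!r}: min exceeds max")

    def contains(self, gc: float, cov: float) -> bool:
        return (
            self.gc_min <= gc <= self.gc_max
            and self.cov_min <= cov <= self.cov_max
        )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_filters(dataset: Dataset, filters: Sequence[FilterRange]) -> Selection:
    """Conjunction of inclusive range filters; rows with a missing value in
    any filtered column are excluded."""
    table = dataset.table
    ids = np.array(table.contig_ids, dtype=object)
    mask = np.ones(len(table), dtype=bool)
    for f in filters:
        spec = table.spec(f.column)
        if spec.kind != "numeric":
            raise QueryError(f"cannot filter non-numeric column {f.column!r}")
        vals = table.values(f.column).astype(float)
        with np.errstate(invalid="ignore"):
            mask &= ~np.isnan(vals) & (vals >= f.min) & (vals <= f.max)
    prov = " AND ".join(
        f"{f.column} in [{f.min}, {f.max}]" for f in filters
    ) or "all contigs"
    return Selection(frozenset(ids[mask]), provenance=f"filter:{prov}")


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def search(dataset: Dataset, term: str, regex: bool = False) -> SearchResult:
    """Case-insensitive scan of all metadata fields and annotations."""
    term = term.strip() if term else ""
    if not term:
        raise QueryError("empty search term")
    if regex:
        pattern = re.compile(term, re.IGNORECASE)
        matches = lambda text: pattern.search(text) is not None  # noqa: E731
    else:
        needle = term.lower()
        matches = lambda text: needle in text.lower()  # noqa: E731

    table = dataset.table
    ids = table.contig_ids
    hits: dict[str, int] = {}

    rendered = {
        spec.name: [render_value(v) for v in table.df[spec.name]]
        for spec in table.columns
    }
    for i, cid in enumerate(ids):
        n = sum(1 for name in rendered if matches(rendered[name][i]))
        if n:
            hits[cid] = n

    for feat in dataset.annotations or ():
        if matches(feat.ftype) or any(matches(v) for v in feat.attribute_values()):
            hits[feat.contig_id] = hits.get(feat.contig_id, 0) + 1

    return SearchResult(term=term, per_contig_hits=hits)


def summarize_hits_by_group(
    result: SearchResult, partition: TaxonPartition
) -> pd.DataFrame:
    """Distribution of search hits across taxon groups.

    Returns columns (group, n_contigs, total_hits), groups with zero hits
    omitted, ordered by descending total hits (ties by name).
    """
    missing = [c for c in result.per_contig_hits if c not in partition.assignment]
    if missing:
        raise QueryError(
            f"{len(missing)} hit contig(s) absent from partition: "
            f"{sorted(missing)[:5]}"
        )
    contigs: dict[str, int] = {}
    totals: dict[str, int] = {}
    for cid, n in result.per_contig_hits.items():
        grp = partition.assignment[cid]
        contigs[grp] = contigs.get(grp, 0) + 1
        totals[grp] = totals.get(grp, 0) + n
    rows = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(g, contigs[g], t) for g, t in rows],
        columns=["group", "n_contigs", "total_hits"],
    )


def search_result_tables(
    result: SearchResult, partition: TaxonPartition | None = None
) -> tuple[pd.DataFrame | None, pd.DataFrame]:
    """The two result tables a search UI shows: per-group summary (when a
    partition is given) and the individual contig list."""
    per_contig = pd.DataFrame(
        sorted(result.per_contig_hits.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["contig_id", "hits"],
    )
    per_group = (
        summarize_hits_by_group(result, partition) if partition is not None else None
    )
    return per_group, per_contig


# ---------------------------------------------------------------------------
# group visibility
# ---------------------------------------------------------------------------

def toggle_groups(
    dataset: Dataset, partition: TaxonPartition, hidden: Iterable[str]
) -> Selection:
    """Contigs whose group is not hidden."""
    hidden = set(hidden)
    unknown = hidden - set(partition.groups)
    if unknown:
        raise QueryError(f"unknown group(s): {sorted(unknown)}")
    keep = frozenset(
        cid for cid in dataset.contig_ids
        if partition.assignment.get(cid) not in hidden
    )
    return Selection(keep, provenance=f"hide:{sorted(hidden)}")


# ---------------------------------------------------------------------------
# genome-bin gating
# ---------------------------------------------------------------------------

def gate_bins(
    dataset: Dataset,
    gates: Sequence[GateRect],
    gc_column: str | None = None,
    coverage_column: str | None = None,
) -> dict[str, str]:
    """Assign every contig to the first gate containing its (GC, coverage)
    point, or to ``"unbinned"``; total over the dataset.

    Contigs with a missing GC or coverage value match no gate.
    """
    table = dataset.table
    gc_column = gc_column or canonical_column(table, "gc")
    coverage_column = coverage_column or canonical_column(table, "coverage")
    if gc_column is None or not table.has_column(gc_column):
        raise QueryError("no GC column designated or found")
    if coverage_column is None or not table.has_column(coverage_column):
        raise QueryError("no coverage column designated or found")
    gc_vals = table.values(gc_column).astype(float)
    cov_vals = table.values(coverage_column).astype(float)
    labels: dict[str, str] = {}
    for cid, gc, cov in zip(table.contig_ids, gc_vals, cov_vals):
        label = UNBINNED
        if not (math.isnan(gc) or math.isnan(cov)):
            for gate in gates:
                if gate.contains(gc, cov):
                    label = gate.label
                    break
        labels[cid] = label
    return labels


def bin_assignments_to_csv(assignments: Mapping[str, str], dest) -> None:
    from .ingest import _open_text

    handle, close = _open_text(dest, "wt")
    try:
        handle.write("contig_id,bin\n")
        for cid, label in assignments.items():
            handle.write(f"{cid},{label}\n")
    finally:
        if close:
            handle.close()
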
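"""Lineage parsing, taxonomy trees, and bounded "deepest frontier" collapse.

A metagenome assembly carries a full taxonomic lineage per contig
("Complete lineage": an ordered chain of taxon names, root-first), but a
plot legend can only show a bounded number of colors. The collapse
operation finds a *frontier* — a set of at most ``k_max`` tree nodes such
that every classified contig has exactly one selected ancestor (or is
itself at a selected node) — that is as taxonomically deep as a greedy
refinement can make it.

Algorithm (greedy frontier refinement)
--------------------------------------
Start with the frontier ``{root}``. Repeatedly take the frontier node with
the largest contig count that has children and whose expansion keeps the
frontier within ``k_max``, and replace it by its children; ties are broken
by lexicographic node name. A node at which some contigs' lineages
*terminate* is retained alongside its children when expanded (those
contigs have no deeper classification and must stay covered). The loop
stops when no expansion fits, which makes the result maximal: no single
frontier node can be refined further without exceeding the bound.

Contigs with an empty lineage go to the reserved ``"Unclassified"`` group
so they remain plottable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import TableError
from .ingest import ContigTable, Dataset, canonical_column

UNCLASSIFIED = "Unclassified"
DEFAULT_K_MAX = 30


@dataclass(frozen=True)
class Lineage:
    """Ordered chain of taxon names, root-first; empty means unclassified."""

    ranks: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.ranks)

    def __bool__(self) -> bool:
        return bool(self.ranks)


def parse_lineage(text: str | None, delimiter: str = ";") -> Lineage:
    """Split a lineage string into ranks; a total function.

    Segments are whitespace-trimmed and empty segments dropped, so
    ``" Archaea ; Euryarchaeota "`` and ``"Archaea;;Euryarchaeota"`` both
    yield two ranks. ``None``/empty input yields the empty lineage.
    """
    if text is None:
        return Lineage()
    ranks = tuple(seg.strip() for seg in str(text).split(delimiter) if seg.strip())
    return Lineage(ranks)


class TaxNode:
    """One node of the contig-count-weighted taxonomy tree.

    ``count`` is the number of contigs whose lineage passes through (or
    terminates at) this node; ``terminal_ids`` are the contigs whose
    lineage ends exactly here.
    """

    __slots__ = ("name", "depth", "parent", "children", "terminal_ids", "count",
                 "unclassified_ids")

    def __init__(self, name: str, depth: int = 0, parent: "TaxNode | None" = None):
        self.name = name
        self.depth = depth
        self.parent = parent
        self.children: dict[str, TaxNode] = {}
        self.terminal_ids: list[str] = []
        self.count: int = 0
        self.unclassified_ids: list[str] = []  # populated on the root only

    def child(self, name: str) -> "TaxNode":
        node = self.children.get(name)
        if node is None:
            node = TaxNode(name, self.depth + 1, self)
            self.children[name] = node
        return node

    @property
    def terminal_count(self) -> int:
        return len(self.terminal_ids)

    def walk(self) -> Iterable["TaxNode"]:
        yield self
        for ch in self.children.values():
            yield from ch.walk()

    def __repr__(self) -> str:
        return f"<TaxNode {self.name!r} depth={self.depth} count={self.count}>"


ROOT_NAME = "Root"


def tree_from_lineages(pairs: Iterable[tuple[str, Lineage]]) -> TaxNode:
    """Build the count-weighted tree from (contig_id, Lineage) pairs."""
    root = TaxNode(ROOT_NAME, depth=0)
    for cid, lineage in pairs:
        if not lineage:
            root.unclassified_ids.append(cid)
            continue
        node = root
        for rank in lineage.ranks:
            node = node.child(rank)
        node.terminal_ids.append(cid)

    def _fill(node: TaxNode) -> int:
        node.count = node.terminal_count + sum(
            _fill(ch) for ch in node.children.values()
        )
        return node.count

    _fill(root)
    return root


def build_taxonomy_tree(dataset: Dataset | ContigTable, lineage_column: str | None = None) -> TaxNode:
    """Build the taxonomy tree for a dataset's lineage column.

    When ``lineage_column`` is omitted, the table is scanned for a
    canonical lineage column name ("Complete lineage", "lineage", ...).
    """
    table = dataset.table if isinstance(dataset, Dataset) else dataset
    if lineage_column is None:
        lineage_column = canonical_column(table, "lineage")
        if lineage_column is None:
            raise TableError("no lineage column found; name one explicitly")
    if not table.has_column(lineage_column):
        raise TableError(f"no such column: {lineage_column!r}")
    ids = table.contig_ids
    texts = table.df[lineage_column].tolist()
    return tree_from_lineages(
        (cid, parse_lineage(txt if isinstance(txt, str) else None))
        for cid, txt in zip(ids, texts)
    )


@dataclass
class TaxonPartition:
    """Collapse result: ordered group labels and a full contig→group map.

    ``frontier`` holds the selected tree nodes (parallel in meaning, not
    order, to the non-reserved labels); group order is by descending
    contig count, ties by name, with ``Unclassified`` participating like
    any other group.
    """

    groups: list[str]
    assignment: dict[str, str]
    frontier: list[TaxNode] = field(default_factory=list, repr=False)

    def to_csv(self, dest) -> None:
        from .ingest import _open_text

        handle, close = _open_text(dest, "wt")
        try:
            handle.write("contig_id,group\n")
            for cid, grp in self.assignment.items():
                g = f'"{grp}"' if "," in grp or '"' in grp else grp
                handle.write(f"{cid},{g}\n")
        finally:
            if close:
                handle.close()


def _expansion_size(frontier_size: int, node: TaxNode) -> int:
    """Frontier size after expanding *node*: children replace it, and it is
    retained when contig lineages terminate at it."""
    return frontier_size - 1 + len(node.children) + (1 if node.terminal_count else 0)


def collapse_to_groups(root: TaxNode, k_max: int = DEFAULT_K_MAX) -> TaxonPartition:
    """Greedy frontier refinement bounded by ``k_max`` selected taxa.

    See module docstring for the procedure. The returned partition covers
    every contig (classified ones by their deepest selected ancestor,
    unclassified ones by the reserved label) and the frontier is maximal
    under the size bound.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    # frontier entries: node -> expandable flag (False once retained after
    # its own expansion; its children are already selected)
    frontier: dict[TaxNode, bool] = {root: True}
    while True:
        candidates = [
            node
            for node, expandable in frontier.items()
            if expandable and node.children
            and _expansion_size(len(frontier), node) <= k_max
        ]
        if not candidates:
            break
        node = min(candidates, key=lambda n: (-n.count, n.name))
        if node.terminal_count:
            frontier[node] = False
        else:
            del frontier[node]
        for ch in node.children.values():
            frontier[ch] = True

    selected = set(frontier)

    # labels: node name, disambiguated with ancestor ranks on collision
    def _label(node: TaxNode, depth_back: int = 0) -> str:
        parts, cur = [], node
        for _ in range(depth_back + 1):
            if cur is None:
                break
            parts.append(cur.name)
            cur = cur.parent
        return ";".join(reversed(parts))

    labels: dict[TaxNode, str] = {}
    back = 0
    nodes = sorted(selected, key=lambda n: (n.depth, n.name))
    while True:
        labels = {n: _label(n, back) for n in nodes}
        if len(set(labels.values())) == len(nodes):
            break
        back += 1

    assignment: dict[str, str] = {}

    def _assign(node: TaxNode, current_label: str | None):
        label = labels.get(node, current_label)
        for cid in node.terminal_ids:
            # lineages terminating above the frontier keep the deepest
            # selected ancestor's label
            assignment[cid] = label if label is not None else labels.get(node, ROOT_NAME)
        for ch in node.children.values():
            _assign(ch, label)

    _assign(root, labels.get(root))
    for cid in root.unclassified_ids:
        assignment[cid] = UNCLASSIFIED

    counts: dict[str, int] = {}
    for grp in assignment.values():
        counts[grp] = counts.get(grp, 0) + 1
    # selected nodes with zero assigned contigs still appear as groups
    for node in selected:
        counts.setdefault(labels[node], 0)
    ordered = sorted(counts, key=lambda g: (-counts[g], g))
    frontier_nodes = sorted(selected, key=lambda n: (-n.count, n.name))
    return TaxonPartition(groups=ordered, assignment=assignment, frontier=frontier_nodes)


def group_counts(partition: TaxonPartition) -> pd.DataFrame:
    """Table of (group, contig count), descending by count, ties by name."""
    counts: dict[str, int] = {}
    for grp in partition.assignment.values():
        counts[grp] = counts.get(grp, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["group", "n_contigs"])
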
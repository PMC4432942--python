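"""Independent oracles used by the tests.

These deliberately avoid the library's own algorithms: the frontier
oracle enumerates *all* valid frontiers of a taxonomy tree by brute
force, and the filter oracle is a plain row scan. They are small and
slow on purpose.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# exhaustive frontier enumeration
# ---------------------------------------------------------------------------

def _internal_nodes(root):
    return [n for n in root.walk() if n.children]


def _descendants(node):
    for ch in node.children.values():
        yield ch
        yield from _descendants(ch)


def _frontier_of(root, expanded: frozenset) -> frozenset:
    """Frontier induced by a set of expanded nodes: unexpanded nodes whose
    parent is expanded (or the root itself), plus expanded nodes at which
    contig lineages terminate (they stay covered)."""
    if root not in expanded:
        return frozenset({root})
    frontier = set()
    for node in root.walk():
        if node in expanded:
            if node.terminal_count:
                frontier.add(node)
        elif node.parent is not None and node.parent in expanded:
            frontier.add(node)
    return frozenset(frontier)


def _is_downward_closed(expanded: frozenset, root) -> bool:
    return all(
        node is root or node.parent in expanded for node in expanded
    )


def enumerate_frontiers(root, k_max: int):
    """All distinct frontiers with |frontier| <= k_max, from every
    downward-closed set of expanded internal nodes."""
    internal = _internal_nodes(root)
    out = set()
    for r in range(len(internal) + 1):
        for combo in itertools.combinations(internal, r):
            expanded = frozenset(combo)
            if not _is_downward_closed(expanded, root):
                continue
            frontier = _frontier_of(root, expanded)
            if len(frontier) <= k_max:
                out.add(frontier)
    return out


def is_maximal_frontier(frontier: frozenset, k_max: int) -> bool:
    """No unexpanded frontier node can be replaced by its children (keeping
    itself when lineages terminate there) within the size bound.  A
    frontier node with a descendant also in the frontier was already
    expanded (it is retained only for its terminators)."""
    for node in frontier:
        if not node.children:
            continue
        if any(desc in frontier for desc in _descendants(node)):
            continue  # retained node, already refined
        new_size = (
            len(frontier) - 1 + len(node.children)
            + (1 if node.terminal_count else 0)
        )
        if new_size <= k_max:
            return False
    return True


def maximal_frontiers(root, k_max: int):
    return {
        f for f in enumerate_frontiers(root, k_max) if is_maximal_frontier(f, k_max)
    }


def check_partition(root, partition, k_max: int) -> dict:
    """Assert cover / bound / maximality for a collapse result; returns
    the assigned depth per classified contig."""
    from contigscope.taxonomy import UNCLASSIFIED

    all_ids = set(root.unclassified_ids)
    for node in root.walk():
        all_ids.update(node.terminal_ids)
    assert set(partition.assignment) == all_ids, "assignment must cover all contigs"

    non_reserved = [g for g in partition.groups if g != UNCLASSIFIED]
    assert len(non_reserved) <= k_max, "group bound violated"

    frontier = frozenset(partition.frontier)
    assert is_maximal_frontier(frontier, k_max), "frontier not maximal"

    depths = {}
    for node in root.walk():
        for cid in node.terminal_ids:
            cur = node
            while cur is not None and cur not in frontier:
                cur = cur.parent
            assert cur is not None, f"{cid}: no selected ancestor"
            depths[cid] = cur.depth
    return depths


def weighted_mean_depth(depths: dict) -> float:
    return sum(depths.values()) / len(depths) if depths else 0.0


# ---------------------------------------------------------------------------
# random small trees
# ---------------------------------------------------------------------------

def random_lineage_pairs(rng, n_contigs=25, alphabet="ABCDEF", max_depth=4):
    """Random (contig_id, lineage-text) pairs producing small, bushy trees
    with terminators at internal nodes."""
    pairs = []
    for i in range(n_contigs):
        depth = int(rng.integers(0, max_depth + 1))
        ranks = [alphabet[int(rng.integers(len(alphabet)))] + str(level)
                 for level in range(depth)]
        pairs.append((f"c{i}", ";".join(ranks)))
    return pairs


# ---------------------------------------------------------------------------
# brute-force row scan
# ---------------------------------------------------------------------------

def brute_force_filter(dataset, filters) -> set:
    """Plain row scan: missing values fail every filter, bounds inclusive."""
    table = dataset.table
    keep = set()
    for record_idx, cid in enumerate(table.contig_ids):
        ok = True
        for f in filters:
            v = table.df[f.column].iloc[record_idx]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                ok = False
                break
            if not (f.min <= float(v) <= f.max):
                ok = False
                break
        if ok:
            keep.add(cid)
    return keep
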
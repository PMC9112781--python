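"""Haplotype DAG construction from read-fragment evidence.

The haplotype DAG (H-DAG) places one *sibling pair* of nodes per
heterozygous site ("level"): sibling 1 carries the REF allele, sibling 2
the ALT allele.  Directed edges exist only between adjacent levels, so the
graph is acyclic by construction and at most four edges can join any two
neighbouring levels.  Edges are created from two kinds of evidence:

* **continuous** fragments — molecules whose allele observations cover a
  consecutive run of levels — contribute direct edges whose counters tally
  the supporting fragments;
* **discontinuous** fragments — molecules that skip one or more levels
  (typically because a variant falls in the unsequenced inner gap of a
  read pair) — contribute *induced* edges built by a look-ahead pre-order
  depth-first traversal that bridges the gap while respecting the edges
  already present.

Every edge counter starts at 1 and is incremented once per continuous
fragment spanning it; induced edges therefore sit at 1 until direct
evidence arrives, which gives them a well-defined minimum weight
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .io import Fragment, HetVariant

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
DISCONTINUOUS = "discontinuous"


class EmptyGraphError(ValueError):
    """Raised when an H-DAG is requested for zero variants."""


@dataclass(frozen=True)
class Node:
    """One member of a sibling pair: ``sibling_index`` 1 = REF, 2 = ALT."""

    level: int
    sibling_index: int
    allele: str

    @property
    def allele_index(self) -> int:
        return self.sibling_index - 1


@dataclass
class Edge:
    """Directed edge between adjacent levels with its evidence counter."""

    source_level: int
    source_sibling: int
    target_sibling: int
    counter: int = 1
    induced: bool = False

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.source_level, self.source_sibling, self.target_sibling)


@dataclass
class Block:
    """A maximal run of consecutive levels joined by >=1 edge per pair."""

    parent: "HDag"
    first_level: int
    last_level: int

    @property
    def n_levels(self) -> int:
        return self.last_level - self.first_level + 1

    @property
    def levels(self) -> range:
        return range(self.first_level, self.last_level + 1)


class HDag:
    """Levels of sibling node pairs plus counted directed edges.

    The two virtual cap nodes (start/end dummies) are implicit: they are
    materialised only during path optimisation, where their edges carry
    zero cost.
    """

    def __init__(self, chrom: str, variants: Sequence[HetVariant]):
        if not variants:
            raise EmptyGraphError("cannot build an H-DAG with no variants")
        self.chrom = chrom
        self.variants: list[HetVariant] = list(variants)
        # edges keyed by (source level, source sibling, target sibling)
        self.edges: dict[tuple[int, int, int], Edge] = {}
        # nodes with at least one read observation, keyed (level, sibling)
        self.observed: set[tuple[int, int]] = set()
        # gap spans already traversed (identical spans carry no new
        # evidence: induced counters stay at their floor)
        self._processed_spans: set[tuple[int, int, int, int]] = set()

    # -- structure ---------------------------------------------------------

    @property
    def n_levels(self) -> int:
        return len(self.variants)

    def node(self, level: int, sibling_index: int) -> Node:
        v = self.variants[level]
        allele = v.ref_allele if sibling_index == 1 else v.alt_allele
        return Node(level, sibling_index, allele)

    def sibling(self, node: Node) -> Node:
        return self.node(node.level, 3 - node.sibling_index)

    def node_for_allele(self, level: int, allele_index: int) -> Node:
        return self.node(level, allele_index + 1)

    def edges_from(self, level: int, sibling_index: int) -> list[Edge]:
        return [
            e
            for (lv, i, _), e in self.edges.items()
            if lv == level and i == sibling_index
        ]

    def edges_between(self, level: int) -> list[Edge]:
        """All edges joining ``level`` and ``level + 1``."""
        return [e for (lv, _, _), e in self.edges.items() if lv == level]

    def has_parent(self, level: int, sibling_index: int) -> bool:
        """True if the node at ``level`` has any incoming edge."""
        return any(
            (level - 1, i, sibling_index) in self.edges for i in (1, 2)
        )

    def is_observed(self, node: Node) -> bool:
        return (node.level, node.sibling_index) in self.observed

    def mark_observed(self, level: int, allele_index: int) -> None:
        self.observed.add((level, allele_index + 1))

    # -- edge bookkeeping --------------------------------------------------

    def _bump_edge(self, level: int, i: int, j: int) -> Edge:
        """Create-or-increment for continuous fragment evidence.

        Counters start at 1 and gain +1 per spanning fragment, so a pair
        seen by a single molecule carries counter 2.
        """
        key = (level, i, j)
        edge = self.edges.get(key)
        if edge is None:
            edge = Edge(level, i, j, counter=1)
            self.edges[key] = edge
        edge.counter += 1
        return edge

    def _induce_edge(self, level: int, i: int, j: int) -> Edge | None:
        """Create an induced edge at its floor counter; never duplicate."""
        key = (level, i, j)
        if key in self.edges:
            return None
        edge = Edge(level, i, j, counter=1, induced=True)
        self.edges[key] = edge
        return edge

    # -- export ------------------------------------------------------------

    def to_dot(self) -> str:
        """Render the graph in DOT format for inspection."""
        lines = ["digraph hdag {", "  rankdir=LR;"]
        for level, v in enumerate(self.variants):
            for sib, allele in ((1, v.ref_allele), (2, v.alt_allele)):
                obs = "*" if (level, sib) in self.observed else ""
                lines.append(
                    f'  "n{level}_{sib}" [label="L{level}/{sib}:{allele}{obs}"];'
                )
        for (lv, i, j), e in sorted(self.edges.items()):
            style = "dashed" if e.induced else "solid"
            lines.append(
                f'  "n{lv}_{i}" -> "n{lv + 1}_{j}" '
                f'[label="{e.counter}" style={style}];'
            )
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# skeleton & fragment classification
# ---------------------------------------------------------------------------


def build_skeleton(variants: Sequence[HetVariant], chrom: str | None = None) -> HDag:
    """One level per variant, sibling 1 = REF and sibling 2 = ALT, no edges.

    The REF/ALT assignment is a deterministic stand-in for an arbitrary
    initial phase; the phased output is invariant to it because the path
    optimisation treats the two siblings symmetrically.
    """
    if not variants:
        raise EmptyGraphError("cannot build an H-DAG with no variants")
    return HDag(chrom or variants[0].chrom, variants)


@dataclass(frozen=True)
class GapSpan:
    """A discontinuity inside one fragment: observed flanks of a level gap."""

    source: Node
    target: Node


@dataclass(frozen=True)
class FragmentShape:
    kind: str  # CONTINUOUS | DISCONTINUOUS
    runs: tuple[tuple[int, int], ...]  # maximal consecutive level runs
    gap_spans: tuple[tuple[int, int], ...]  # (last level before, first after)


def classify_fragment(fragment: Fragment) -> FragmentShape:
    """Split a fragment's observed levels into maximal consecutive runs.

    A fragment is continuous iff its levels form one consecutive integer
    run; otherwise the gaps between successive runs define spans whose
    source is the last observed level before the gap and whose target is
    the first observed level after it.
    """
    levels = [o.level for o in fragment.observations]
    runs: list[tuple[int, int]] = []
    start = prev = levels[0]
    for lv in levels[1:]:
        if lv == prev + 1:
            prev = lv
            continue
        runs.append((start, prev))
        start = prev = lv
    runs.append((start, prev))
    gaps = tuple(
        (runs[k][1], runs[k + 1][0]) for k in range(len(runs) - 1)
    )
    kind = CONTINUOUS if len(runs) == 1 else DISCONTINUOUS
    return FragmentShape(kind=kind, runs=tuple(runs), gap_spans=gaps)


# ---------------------------------------------------------------------------
# continuous evidence
# ---------------------------------------------------------------------------


def add_continuous_evidence(hdag: HDag, fragment: Fragment) -> None:
    """Count the fragment's consecutive runs into adjacent-level edges.

    Every observation also marks its node as read-observed (used by the
    induction pseudocode's branch condition).  Conflicting fragments
    accumulate naturally into the 2-, 3- or 4-edge configurations between
    a level pair (in-phase, out-of-phase, single- or double-ambiguity).
    """
    by_level = {o.level: o for o in fragment.observations}
    for obs in fragment.observations:
        hdag.mark_observed(obs.level, obs.allele_index)
    shape = classify_fragment(fragment)
    for run_start, run_end in shape.runs:
        for level in range(run_start, run_end):
            i = by_level[level].allele_index + 1
            j = by_level[level + 1].allele_index + 1
            hdag._bump_edge(level, i, j)


def fragment_gap_spans(hdag: HDag, fragment: Fragment) -> list[GapSpan]:
    """Materialise a fragment's gaps as (source node, target node) spans."""
    by_level = {o.level: o for o in fragment.observations}
    spans = []
    for src_level, tgt_level in classify_fragment(fragment).gap_spans:
        spans.append(
            GapSpan(
                source=hdag.node_for_allele(
                    src_level, by_level[src_level].allele_index
                ),
                target=hdag.node_for_allele(
                    tgt_level, by_level[tgt_level].allele_index
                ),
            )
        )
    return spans


# ---------------------------------------------------------------------------
# induced edges for discontinuous fragments
# ---------------------------------------------------------------------------


def get_potential_children(
    hdag: HDag,
    parent: Node,
    target: Node,
    preexisting: frozenset[tuple[int, int, int]] | None = None,
) -> list[Node]:
    """Look-ahead edge induction between ``parent``'s level and the next.

    Branch A: if the parent's sibling has a read-observed allele AND
    directed edges to both children at the next level (local phase
    ambiguity), induce edges from the parent to both children.

    Branch B: otherwise induce an edge from the parent to each child with
    no incoming edge — excluding, when the next level is the target level,
    the sibling of the target node.

    Both branch conditions are judged against ``preexisting``, the edge
    set as it stood when the current gap span started (edges induced
    earlier in the same traversal do not mask a child as "having a
    parent"; that is what lets every intermediate node of an ambiguous
    gap reach the target).  Pre-existing edges are never duplicated and
    counters never change.  Returns the parent's children (via any edge,
    including just-induced ones) for the onward traversal.
    """
    if preexisting is None:
        preexisting = frozenset(hdag.edges)
    level = parent.level
    sib = hdag.sibling(parent)
    n_sib_edges = sum(
        1 for j in (1, 2) if (level, sib.sibling_index, j) in preexisting
    )
    if hdag.is_observed(sib) and n_sib_edges == 2:
        for j in (1, 2):
            hdag._induce_edge(level, parent.sibling_index, j)
    else:
        for j in (1, 2):
            if any((level, i, j) in preexisting for i in (1, 2)):
                continue  # child already had a parent before this span
            if level + 1 == target.level and j == 3 - target.sibling_index:
                continue
            hdag._induce_edge(level, parent.sibling_index, j)
    return [
        hdag.node(level + 1, j)
        for j in (1, 2)
        if (level, parent.sibling_index, j) in hdag.edges
    ]


def _traverse_span(hdag: HDag, span: GapSpan) -> bool:
    """Pre-order DFS from the span's source to its target level.

    Children are visited sibling-index ascending; each node is expanded at
    most once per span.  Returns True if the target node gained or already
    had an incoming edge by the end of the traversal.
    """
    target = span.target
    preexisting = frozenset(hdag.edges)
    visited: set[tuple[int, int]] = set()
    stack = [span.source]
    while stack:
        parent = stack.pop()
        key = (parent.level, parent.sibling_index)
        if key in visited or parent.level >= target.level:
            continue
        visited.add(key)
        children = get_potential_children(hdag, parent, target, preexisting)
        # reversed push => sibling-index-ascending visit order
        for child in reversed(children):
            stack.append(child)
    return hdag.has_parent(target.level, target.sibling_index)


def induce_edges(hdag: HDag, spans: Iterable[GapSpan]) -> list[GapSpan]:
    """Process gap spans in the prescribed order, inducing bridge edges.

    Spans are sorted by target level ascending, ties broken by source
    level descending; each traversal's induced edges immediately join the
    edge framework seen by later spans.  Spans whose target remains
    unreachable are returned (and logged) rather than repaired.
    """
    ordered = sorted(
        spans,
        key=lambda s: (
            s.target.level,
            -s.source.level,
            s.target.sibling_index,
            s.source.sibling_index,
        ),
    )
    unreachable = []
    for span in ordered:
        if span.target.level - span.source.level <= 1:
            raise ValueError("gap span must skip at least one level")
        key = (
            span.source.level,
            span.source.sibling_index,
            span.target.level,
            span.target.sibling_index,
        )
        if key in hdag._processed_spans:
            continue
        hdag._processed_spans.add(key)
        if not _traverse_span(hdag, span):
            unreachable.append(span)
    if unreachable:
        logger.info(
            "%d gap span(s) left their target without an incoming edge",
            len(unreachable),
        )
    return unreachable


# ---------------------------------------------------------------------------
# block partitioning & orchestration
# ---------------------------------------------------------------------------


def partition_blocks(hdag: HDag) -> list[Block]:
    """Split the level range at every adjacent pair with zero edges.

    Single-level blocks (no edge on either side) are returned too; they
    are reported as unphased and skipped by the path optimiser.
    """
    blocks = []
    first = 0
    for level in range(hdag.n_levels - 1):
        if not hdag.edges_between(level):
            blocks.append(Block(hdag, first, level))
            first = level + 1
    blocks.append(Block(hdag, first, hdag.n_levels - 1))
    return blocks


def build_hdag(
    chrom: str,
    variants: Sequence[HetVariant],
    fragments: Iterable[Fragment],
) -> HDag:
    """Full graph construction: skeleton, continuous evidence, induction.

    All continuous evidence (including the consecutive sub-runs of
    discontinuous fragments) is counted first, then every gap span is
    bridged by the look-ahead traversal in the prescribed global order.
    """
    hdag = build_skeleton(variants, chrom)
    spans: list[GapSpan] = []
    for fragment in fragments:
        add_continuous_evidence(hdag, fragment)
        spans.extend(fragment_gap_spans(hdag, fragment))
    induce_edges(hdag, spans)
    return hdag
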
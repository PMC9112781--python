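"""Edge weighting and minimum negative-log-likelihood path phasing.

Each directed edge e at level delta gets the local probability

    w = n(e) / sum_k n(e_k)

where the sum runs over the counters of all edges emitting from the same
source node, so outgoing weights always sum to 1 and a lone edge carries
weight exactly 1 (cost 0).  A path through a block visits one node per
level; its likelihood is the product of its edge weights, and the optimal
phase is the path minimising the summed edge costs -log(w).  Because
edges only join adjacent levels the block is already topologically sorted
by level, and a single forward dynamic-programming sweep with backtracking
finds the optimum in time linear in edges plus nodes.

The first haplotype reads the alleles on the optimal path; the second is
its complement (the sibling allele at every level).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .graph import Block, HDag, partition_blocks

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-9


class UnreachableLevelError(RuntimeError):
    """No complete start-to-end path exists through the block."""

    def __init__(self, level: int):
        super().__init__(f"no path reaches level {level}")
        self.level = level


@dataclass(frozen=True)
class WeightedEdge:
    """An edge with its local probability and additive cost -log(w)."""

    source_level: int
    source_sibling: int
    target_sibling: int
    counter: int
    weight: float
    cost: float
    induced: bool


@dataclass
class PhasedBlock:
    """One phased block: the optimal path and its complement haplotype."""

    block: Block
    path_siblings: list[int]  # sibling index chosen at each level
    hap1: list[str]  # alleles on the minimum-weight path
    hap2: list[str]  # sibling alleles (the complement haplotype)
    path_cost: float

    @property
    def n_levels(self) -> int:
        return self.block.n_levels

    @property
    def first_pos(self) -> int:
        return self.block.parent.variants[self.block.first_level].pos

    @property
    def last_pos(self) -> int:
        return self.block.parent.variants[self.block.last_level].pos

    @property
    def span_bp(self) -> int:
        """Genomic span, first to last phased variant, inclusive."""
        return self.last_pos - self.first_pos + 1

    @property
    def likelihood(self) -> float:
        return math.exp(-self.path_cost)

    def bridges_discontinuity(self) -> bool:
        """True if some internal level pair is joined by induced edges only
        (i.e. the block owes its connectivity to a discontinuous fragment)."""
        hdag = self.block.parent
        for level in range(self.block.first_level, self.block.last_level):
            edges = hdag.edges_between(level)
            if edges and all(e.induced and e.counter == 1 for e in edges):
                return True
        return False


def compute_weights(block: Block) -> dict[tuple[int, int, int], WeightedEdge]:
    """Eq.-style local probabilities for every edge in the block.

    weight = counter / (sum of counters of edges sharing the source node);
    cost = -log(weight) (natural log; the base does not affect the argmin).
    """
    hdag = block.parent
    out: dict[tuple[int, int, int], WeightedEdge] = {}
    for level in range(block.first_level, block.last_level):
        for i in (1, 2):
            edges = [
                hdag.edges[(level, i, j)]
                for j in (1, 2)
                if (level, i, j) in hdag.edges
            ]
            if not edges:
                continue
            total = sum(e.counter for e in edges)
            for e in edges:
                w = e.counter / total
                out[e.key] = WeightedEdge(
                    source_level=level,
                    source_sibling=i,
                    target_sibling=e.target_sibling,
                    counter=e.counter,
                    weight=w,
                    cost=-math.log(w),
                    induced=e.induced,
                )
    return out


def min_weight_path(
    block: Block, weights: dict[tuple[int, int, int], WeightedEdge]
) -> PhasedBlock:
    """Minimum-cost start-dummy-to-end-dummy path by forward DP.

    Dummy edges to/from both boundary siblings cost 0, leaving the
    optimisation unconstrained at the block ends.  Equal-cost paths are
    broken toward the lower sibling index at the first divergence, which
    makes the output deterministic.  Raises UnreachableLevelError if some
    level cannot be reached by any path (possible in rare single-edge
    chain configurations; the caller splits the block there).
    """
    hdag = block.parent
    INF = math.inf
    # per level: {sibling: (cost, tie_key, predecessor sibling)}
    # tie_key is a nested tuple encoding the path's sibling sequence so
    # that tuple comparison resolves ties from the first divergence.
    dist: dict[int, tuple[float, tuple, int | None]] = {
        1: (0.0, ((), 1), None),
        2: (0.0, ((), 2), None),
    }
    trace: list[dict[int, int | None]] = [{1: None, 2: None}]
    for level in range(block.first_level, block.last_level):
        nxt: dict[int, tuple[float, tuple, int | None]] = {}
        for j in (1, 2):
            best: tuple[float, tuple, int | None] | None = None
            for i in (1, 2):
                we = weights.get((level, i, j))
                if we is None or i not in dist:
                    continue
                cost0, key0, _ = dist[i]
                if cost0 is INF:
                    continue
                cand = (cost0 + we.cost, (key0, j), i)
                if best is None:
                    best = cand
                elif cand[0] < best[0] - _TIE_EPS:
                    best = cand
                elif abs(cand[0] - best[0]) <= _TIE_EPS and cand[1] < best[1]:
                    best = cand
            if best is not None:
                nxt[j] = best
        if not nxt:
            raise UnreachableLevelError(level + 1)
        dist = nxt
        trace.append({j: dist[j][2] if j in dist else None for j in (1, 2)})

    # end dummy: zero-cost edges from both siblings at the last level
    end_best = min(
        ((dist[j][0], dist[j][1], j) for j in dist),
        key=lambda t: (t[0], t[1]),
    )
    path_cost, _, last = end_best

    siblings = [last]
    for step in range(len(trace) - 1, 0, -1):
        last = trace[step][last]
        assert last is not None
        siblings.append(last)
    siblings.reverse()

    hap1, hap2 = [], []
    for offset, level in enumerate(block.levels):
        node = hdag.node(level, siblings[offset])
        hap1.append(node.allele)
        hap2.append(hdag.sibling(node).allele)
    return PhasedBlock(
        block=block,
        path_siblings=siblings,
        hap1=hap1,
        hap2=hap2,
        path_cost=path_cost,
    )


def _phase_block(block: Block) -> list[PhasedBlock]:
    """Optimise one block, splitting at unreachable levels if necessary."""
    if block.n_levels < 2:
        return []
    try:
        return [min_weight_path(block, compute_weights(block))]
    except UnreachableLevelError as exc:
        hdag = block.parent
        logger.warning(
            "%s: block %d-%d has no complete path; splitting at level %d",
            hdag.chrom,
            block.first_level,
            block.last_level,
            exc.level,
        )
        left = Block(hdag, block.first_level, exc.level - 1)
        right = Block(hdag, exc.level, block.last_level)
        return _phase_block(left) + _phase_block(right)


def phase_chromosome(hdag: HDag) -> list[PhasedBlock]:
    """Partition into blocks and optimise each multi-level block.

    Single-variant blocks carry no phase information and are passed over
    (they remain unphased in the output); blocks are returned in genomic
    order.
    """
    phased: list[PhasedBlock] = []
    for block in partition_blocks(hdag):
        phased.extend(_phase_block(block))
    return phased


def unphased_levels(hdag: HDag) -> list[int]:
    """Levels that end up in single-variant blocks (reported, not phased)."""
    return [
        b.first_level for b in partition_blocks(hdag) if b.n_levels == 1
    ]
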
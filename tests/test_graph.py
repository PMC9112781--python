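"""H-DAG construction: skeleton, fragment classification, continuous
evidence scenarios, edge induction, and block partitioning."""

import numpy as np
import pytest

from hapdag.graph import (
    CONTINUOUS,
    DISCONTINUOUS,
    EmptyGraphError,
    GapSpan,
    build_hdag,
    build_skeleton,
    add_continuous_evidence,
    classify_fragment,
    fragment_gap_spans,
    get_potential_children,
    induce_edges,
    partition_blocks,
)
from hapdag.io import HetVariant

from conftest import make_fragment, make_variants, hdag_with_edges


class TestSkeleton:
    def test_levels_nodes_and_no_edges(self):
        hdag = build_skeleton(make_variants(3))
        assert hdag.n_levels == 3
        assert len(hdag.edges) == 0

    def test_sibling_one_is_ref_two_is_alt(self):
        v = HetVariant("chr1", 50, "A", "T", 0, "SNP")
        hdag = build_skeleton([v])
        assert hdag.node(0, 1).allele == "A"
        assert hdag.node(0, 2).allele == "T"

    def test_single_variant_graph(self):
        hdag = build_skeleton(make_variants(1))
        assert hdag.n_levels == 1 and not hdag.edges

    def test_empty_variant_list_rejected(self):
        with pytest.raises(EmptyGraphError):
            build_skeleton([])


def _brute_runs(levels):
    """Independent maximal-consecutive-run finder (brute force over the
    index set)."""
    runs = []
    for lv in sorted(levels):
        if runs and runs[-1][-1] == lv - 1:
            runs[-1].append(lv)
        else:
            runs.append([lv])
    return [(r[0], r[-1]) for r in runs]


class TestClassifyFragment:
    def test_consecutive_run_is_continuous(self):
        f = make_fragment({lv: 0 for lv in range(4, 9)})
        shape = classify_fragment(f)
        assert shape.kind == CONTINUOUS
        assert shape.runs == ((4, 8),)
        assert shape.gap_spans == ()

    def test_single_gap_is_discontinuous(self):
        f = make_fragment({5: 0, 7: 1})
        shape = classify_fragment(f)
        assert shape.kind == DISCONTINUOUS
        assert shape.gap_spans == ((5, 7),)

    @pytest.mark.parametrize(
        "levels",
        [
            (3, 4, 6, 7, 9),
            (0, 2),
            (0, 1, 5),
            (2, 4, 6, 8),
        ],
    )
    def test_runs_match_brute_force_enumeration(self, levels):
        f = make_fragment({lv: 0 for lv in levels})
        shape = classify_fragment(f)
        expect = _brute_runs(levels)
        assert list(shape.runs) == expect
        assert list(shape.gap_spans) == [
            (expect[k][1], expect[k + 1][0]) for k in range(len(expect) - 1)
        ]


class TestContinuousEvidence:
    def test_in_phase_fragments_make_two_straight_edges(self):
        hdag = build_skeleton(make_variants(2))
        add_continuous_evidence(hdag, make_fragment({0: 0, 1: 0}, "a"))
        add_continuous_evidence(hdag, make_fragment({0: 1, 1: 1}, "b"))
        assert set(hdag.edges) == {(0, 1, 1), (0, 2, 2)}

    def test_out_of_phase_fragments_make_two_crossing_edges(self):
        hdag = build_skeleton(make_variants(2))
        add_continuous_evidence(hdag, make_fragment({0: 0, 1: 1}, "a"))
        add_continuous_evidence(hdag, make_fragment({0: 1, 1: 0}, "b"))
        assert set(hdag.edges) == {(0, 1, 2), (0, 2, 1)}

    def test_single_ambiguity_makes_third_diagonal_edge(self):
        hdag = build_skeleton(make_variants(2))
        add_continuous_evidence(hdag, make_fragment({0: 0, 1: 0}, "a"))
        add_continuous_evidence(hdag, make_fragment({0: 1, 1: 1}, "b"))
        add_continuous_evidence(hdag, make_fragment({0: 0, 1: 1}, "c"))
        assert set(hdag.edges) == {(0, 1, 1), (0, 2, 2), (0, 1, 2)}

    def test_counter_is_one_plus_spanning_fragments(self):
        hdag = build_skeleton(make_variants(2))
        for k in range(3):
            add_continuous_evidence(hdag, make_fragment({0: 0, 1: 0}, str(k)))
        assert hdag.edges[(0, 1, 1)].counter == 4  # init 1 + 3 fragments

    def test_discontinuous_subruns_also_count(self):
        hdag = build_skeleton(make_variants(5))
        add_continuous_evidence(
            hdag, make_fragment({0: 0, 1: 0, 3: 1, 4: 1})
        )
        assert set(hdag.edges) == {(0, 1, 1), (3, 2, 2)}


class TestGetPotentialChildren:
    def test_single_preexisting_edge_routes_to_parentless_child(self):
        # one edge sibling(l)->v1(l+1): the parentless child v2(l+1)
        # receives the induced edge (complement phase)
        hdag = hdag_with_edges(3, {(0, 2, 1): 3})
        parent = hdag.node(0, 1)
        target = hdag.node(2, 1)
        children = get_potential_children(hdag, parent, target)
        assert (0, 1, 2) in hdag.edges and hdag.edges[(0, 1, 2)].induced
        assert [c.sibling_index for c in children] == [2]

    def test_ambiguous_sibling_induces_edges_to_both_children(self):
        # sibling v2(0) has edges to both children -> branch A
        hdag = hdag_with_edges(3, {(0, 2, 1): 2, (0, 2, 2): 2})
        parent = hdag.node(0, 1)
        target = hdag.node(2, 1)
        children = get_potential_children(hdag, parent, target)
        assert (0, 1, 1) in hdag.edges and (0, 1, 2) in hdag.edges
        assert [c.sibling_index for c in children] == [1, 2]

    def test_target_sibling_never_receives_edge_at_target_level(self):
        hdag = hdag_with_edges(2, {})
        parent = hdag.node(0, 1)
        target = hdag.node(1, 1)
        get_potential_children(hdag, parent, target)
        assert (0, 1, 1) in hdag.edges
        assert (0, 1, 2) not in hdag.edges

    def test_existing_edges_not_duplicated_or_incremented(self):
        hdag = hdag_with_edges(3, {(0, 2, 1): 2, (0, 2, 2): 2, (0, 1, 1): 5})
        parent = hdag.node(0, 1)
        get_potential_children(hdag, parent, hdag.node(2, 1))
        assert hdag.edges[(0, 1, 1)].counter == 5  # untouched
        assert hdag.edges[(0, 1, 2)].counter == 1  # newly induced


class TestInduceEdges:
    def test_span_ordering_target_ascending_then_source_descending(self):
        processed = []
        hdag = hdag_with_edges(10, {})

        spans = [
            GapSpan(hdag.node(5, 1), hdag.node(8, 1)),
            GapSpan(hdag.node(2, 1), hdag.node(4, 1)),
            GapSpan(hdag.node(3, 1), hdag.node(7, 1)),
            GapSpan(hdag.node(5, 1), hdag.node(7, 1)),
        ]
        ordered = sorted(
            spans,
            key=lambda s: (
                s.target.level,
                -s.source.level,
                s.target.sibling_index,
                s.source.sibling_index,
            ),
        )
        assert [(s.source.level, s.target.level) for s in ordered] == [
            (2, 4),
            (5, 7),
            (3, 7),
            (5, 8),
        ]

    def test_fig_style_bridge_over_known_edge(self):
        # pre-existing T->C between the gap's interior pair: the induced
        # path follows the complement and ends at the target only
        hdag = hdag_with_edges(3, {(1, 2, 1): 3})
        span = GapSpan(hdag.node(0, 1), hdag.node(2, 2))
        left = induce_edges(hdag, [span])
        assert left == []
        induced = {k for k, e in hdag.edges.items() if e.induced}
        assert (1, 1, 2) in induced  # complement route into the target

    def test_idempotent_reinduction(self):
        hdag = hdag_with_edges(4, {(1, 2, 1): 3})
        spans = [GapSpan(hdag.node(0, 1), hdag.node(3, 2))]
        induce_edges(hdag, spans)
        snapshot = {
            k: (e.counter, e.induced) for k, e in hdag.edges.items()
        }
        induce_edges(hdag, spans)
        assert snapshot == {
            k: (e.counter, e.induced) for k, e in hdag.edges.items()
        }

    def test_gap_must_skip_a_level(self):
        hdag = hdag_with_edges(3, {})
        with pytest.raises(ValueError):
            induce_edges(
                hdag, [GapSpan(hdag.node(0, 1), hdag.node(1, 1))]
            )


class TestPartitionBlocks:
    def test_fully_connected_single_block(self):
        counters = {(lv, 1, 1): 2 for lv in range(9)}
        hdag = hdag_with_edges(10, counters)
        blocks = partition_blocks(hdag)
        assert len(blocks) == 1 and blocks[0].n_levels == 10

    def test_single_cut_splits_in_two(self):
        counters = {(lv, 1, 1): 2 for lv in range(9) if lv != 4}
        hdag = hdag_with_edges(10, counters)
        blocks = partition_blocks(hdag)
        assert [(b.first_level, b.last_level) for b in blocks] == [
            (0, 4),
            (5, 9),
        ]

    def test_no_edges_all_singletons(self):
        hdag = hdag_with_edges(10, {})
        blocks = partition_blocks(hdag)
        assert len(blocks) == 10
        assert all(b.n_levels == 1 for b in blocks)


# ---------------------------------------------------------------------------
# structural invariants & determinism
# ---------------------------------------------------------------------------


def _random_fragments(rng, n_levels, n_frags):
    frags = []
    for k in range(n_frags):
        start = int(rng.integers(0, n_levels - 1))
        length = int(rng.integers(2, min(5, n_levels - start) + 1))
        levels = list(range(start, start + length))
        # knock out interior levels sometimes to create discontinuities
        keep = [
            lv
            for pos, lv in enumerate(levels)
            if pos in (0, len(levels) - 1) or rng.random() > 0.3
        ]
        alleles = {lv: int(rng.integers(2)) for lv in keep}
        if len(alleles) >= 2:
            frags.append(make_fragment(alleles, f"r{k}"))
    return frags


class TestInvariants:
    def test_edges_adjacent_only_and_at_most_four_per_pair(self, rng):
        for trial in range(20):
            frags = _random_fragments(rng, 8, 15)
            if not frags:
                continue
            hdag = build_hdag("chr1", make_variants(8), frags)
            for (lv, i, j), e in hdag.edges.items():
                assert 0 <= lv < 7 and i in (1, 2) and j in (1, 2)
                assert e.counter >= 1
            for lv in range(7):
                assert len(hdag.edges_between(lv)) <= 4

    def test_counter_conservation(self, rng):
        # sum(counter - 1) over non-induced-created edges equals the
        # number of adjacent-level traversals by continuous evidence
        for trial in range(10):
            frags = _random_fragments(rng, 8, 12)
            if not frags:
                continue
            hdag = build_hdag("chr1", make_variants(8), frags)
            traversals = 0
            for f in frags:
                for a, b in classify_fragment(f).runs:
                    traversals += b - a
            assert (
                sum(e.counter - 1 for e in hdag.edges.values())
                == traversals
            )

    def test_edge_set_independent_of_fragment_order(self, rng):
        frags = _random_fragments(rng, 10, 25)
        base = build_hdag("chr1", make_variants(10), frags)
        for trial in range(5):
            shuffled = list(frags)
            rng.shuffle(shuffled)
            other = build_hdag("chr1", make_variants(10), shuffled)
            assert {
                k: (e.counter, e.induced) for k, e in base.edges.items()
            } == {
                k: (e.counter, e.induced) for k, e in other.edges.items()
            }

    def test_connectivity_matches_naive_pseudocode_reference(self, rng):
        """Cross-check induction against an independently coded, plainly
        recursive rendition of the look-ahead traversal."""
        for trial in range(30):
            n = 7
            frags = _random_fragments(rng, n, 10)
            if not frags:
                continue
            hdag = build_hdag("chr1", make_variants(n), frags)
            ref_edges = _naive_reference(n, frags)
            mine = {
                lv
                for lv in range(n - 1)
                if hdag.edges_between(lv)
            }
            theirs = {
                lv
                for lv in range(n - 1)
                if any(k[0] == lv for k in ref_edges)
            }
            assert mine == theirs


def _naive_reference(n_levels, fragments):
    """Straight-line reimplementation of the construction rules, kept
    deliberately primitive (dict edges, recursion) as an oracle."""
    edges = {}  # (lv, i, j) -> counter
    observed = set()
    spans = []
    for f in fragments:
        obs = {o.level: o.allele_index + 1 for o in f.observations}
        for lv, s in obs.items():
            observed.add((lv, s))
        lvs = sorted(obs)
        for a, b in zip(lvs, lvs[1:]):
            if b == a + 1:
                key = (a, obs[a], obs[b])
                edges[key] = edges.get(key, 1) + 1
            else:
                spans.append((a, obs[a], b, obs[b]))
    spans.sort(key=lambda s: (s[2], -s[0], s[3], s[1]))

    def expand(lv, i, tgt_lv, tgt_sib, seen, pre):
        # branch conditions read the span-start snapshot `pre`
        if (lv, i) in seen or lv >= tgt_lv:
            return
        seen.add((lv, i))
        sib = 3 - i
        sib_children = [j for j in (1, 2) if (lv, sib, j) in pre]
        if (lv, sib) in observed and len(sib_children) == 2:
            for j in (1, 2):
                edges.setdefault((lv, i, j), 1)
        else:
            for j in (1, 2):
                if any((lv, x, j) in pre for x in (1, 2)):
                    continue
                if lv + 1 == tgt_lv and j == 3 - tgt_sib:
                    continue
                edges.setdefault((lv, i, j), 1)
        for j in (1, 2):
            if (lv, i, j) in edges:
                expand(lv + 1, j, tgt_lv, tgt_sib, seen, pre)

    for src_lv, src_sib, tgt_lv, tgt_sib in spans:
        expand(src_lv, src_sib, tgt_lv, tgt_sib, set(), frozenset(edges))
    return edges
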
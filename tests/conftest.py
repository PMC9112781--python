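"""Shared fixture builders: tiny variant lists, fragments, and H-DAGs
constructed directly, plus text VCF/SAM writers for the I/O tests."""

from __future__ import annotations

import numpy as np
import pytest

from hapdag.graph import HDag, build_skeleton
from hapdag.io import AlleleObservation, Fragment, HetVariant


def make_variants(n: int, chrom: str = "chr1", spacing: int = 100):
    """n heterozygous SNPs: REF=A, ALT=T, evenly spaced."""
    return [
        HetVariant(
            chrom=chrom,
            pos=(i + 1) * spacing,
            ref_allele="A",
            alt_allele="T",
            level=i,
            kind="SNP",
        )
        for i in range(n)
    ]


def make_fragment(allele_by_level: dict[int, int], frag_id="f", qual=40):
    """Fragment from {level: allele_index}."""
    obs = tuple(
        AlleleObservation(lv, a, qual)
        for lv, a in sorted(allele_by_level.items())
    )
    return Fragment(fragment_id=frag_id, observations=obs)


def hdag_with_edges(
    n_levels: int,
    counters: dict[tuple[int, int, int], int],
    observed: set[tuple[int, int]] | None = None,
) -> HDag:
    """Directly assemble an H-DAG with given edge counters.

    ``counters`` maps (source level, source sibling, target sibling) to a
    counter value; ``observed`` marks nodes as read-observed (defaults to
    every node, the generic fully-covered case).
    """
    hdag = build_skeleton(make_variants(n_levels))
    for (lv, i, j), c in counters.items():
        e = hdag._induce_edge(lv, i, j)
        assert e is not None
        e.counter = c
        e.induced = c == 1
    if observed is None:
        observed = {
            (lv, s) for lv in range(n_levels) for s in (1, 2)
        }
    hdag.observed = set(observed)
    return hdag


def random_block_hdag(rng: np.random.Generator, n_levels: int) -> HDag:
    """Random connected block: nonempty edge subset per adjacent pair,
    counters 1-10, resampled until a complete start-to-end path exists."""
    from hapdag.graph import partition_blocks

    while True:
        counters = {}
        for lv in range(n_levels - 1):
            pairs = [(i, j) for i in (1, 2) for j in (1, 2)]
            k = int(rng.integers(1, 5))
            chosen = rng.choice(len(pairs), size=k, replace=False)
            for idx in chosen:
                i, j = pairs[idx]
                counters[(lv, i, j)] = int(rng.integers(1, 11))
        hdag = hdag_with_edges(n_levels, counters)
        if brute_force_paths(hdag, 0, n_levels - 1):
            return hdag


def brute_force_paths(hdag: HDag, first: int, last: int):
    """Exhaustively enumerate complete paths with their costs.

    Independent of the DP optimiser: walks every sibling assignment and
    sums -log of counter/source-total for each traversed edge.
    """
    import itertools
    import math

    out = []
    levels = list(range(first, last + 1))
    for combo in itertools.product((1, 2), repeat=len(levels)):
        cost = 0.0
        ok = True
        for k in range(len(levels) - 1):
            lv = levels[k]
            e = hdag.edges.get((lv, combo[k], combo[k + 1]))
            if e is None:
                ok = False
                break
            total = sum(
                hdag.edges[(lv, combo[k], j)].counter
                for j in (1, 2)
                if (lv, combo[k], j) in hdag.edges
            )
            cost += -math.log(e.counter / total)
        if ok:
            out.append((cost, combo))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(path, records):
    """records: iterable of (chrom, pos, ref, alt, gt) tuples."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom, pos, ref, alt, gt in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gt}\n"
            )
    return str(path)


SAM_HEADER = (
    "@HD\tVN:1.6\tSO:coordinate\n"
    "@SQ\tSN:chr1\tLN:100000\n"
    "@SQ\tSN:chr2\tLN:100000\n"
)


def write_sam(path, records):
    """records: iterable of (qname, flag, chrom, pos1, mapq, cigar, seq)
    or full 11+-field tuples; qualities default to Q40."""
    with open(path, "w") as fh:
        fh.write(SAM_HEADER)
        for rec in records:
            qname, flag, chrom, pos1, mapq, cigar, seq = rec
            qual = "I" * len(seq)
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t"
                f"*\t0\t0\t{seq}\t{qual}\n"
            )
    return str(path)
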
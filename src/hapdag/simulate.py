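"""Self-contained diploid read simulation for end-to-end testing.

Generates a random reference region, a truth-phased set of heterozygous
SNPs and short INDELs (1-20 bp), and pre-aligned reads drawn from the two
truth haplotypes: short paired-end fragments with a configurable insert
(so that a variant can fall in the unsequenced inner gap, producing
discontinuous fragments whenever insert_mean > 2 * read_length) or long
single-end reads with exponentially distributed lengths.  Per-base
substitution errors are injected at a configurable rate and logged, with
the source haplotype, to a JSON sidecar.

Reads are written with correct CIGARs against the reference at their true
coordinates; no mapper is involved, because alignment is out of scope for
the phasing algorithm itself.  All outputs are deterministic functions of
the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated region.

    Defaults emulate a 25x short-read regime over a human-like region:
    one heterozygous site per kilobase, 10% INDELs, 2 x 150 bp pairs with
    a 500 +/- 50 bp insert (inner gap ~200 bp, so discontinuous fragments
    occur), and error-free bases unless stated otherwise.
    """

    region_length: int = 100_000
    het_density: float = 0.001  # expected het sites per bp
    indel_fraction: float = 0.1
    read_length: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    long_read_mean_len: int = 8_000
    coverage: float = 25.0
    error_rate: float = 0.0
    seed: int = 0
    chrom: str = "chr1"

    MAX_INDEL: int = field(default=20, repr=False)

    def __post_init__(self):
        for name in ("het_density", "indel_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} must be in [0, 1]")
        for name in (
            "region_length",
            "read_length",
            "long_read_mean_len",
        ):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.insert_mean <= 0 or self.insert_sd < 0:
            raise SimulationError("insert_mean/insert_sd invalid")


@dataclass(frozen=True)
class TruthVariant:
    """A simulated heterozygous site with its true phase.

    ``hap_a`` is the allele index (0 = REF, 1 = ALT) carried by haplotype
    A; haplotype B carries the other allele.
    """

    pos: int  # 1-based, VCF convention (anchor base for INDELs)
    ref: str
    alt: str
    hap_a: int


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------


def simulate_truth(
    config: SimulationConfig,
) -> tuple[str, list[TruthVariant]]:
    """Random reference plus truth-phased heterozygous variants.

    Sites arrive by a (discrete) Poisson process at ``het_density``, with
    a small exclusion zone so INDEL events never overlap; each site is a
    substitution or, with probability ``indel_fraction``, a 1-20 bp
    insertion or deletion.  The phase of every site is a fair coin.
    """
    rng = np.random.default_rng(config.seed)
    n = config.region_length
    reference = "".join(rng.choice(_BASES, size=n))

    variants: list[TruthVariant] = []
    if config.het_density > 0:
        margin = config.MAX_INDEL + 2
        if n <= 2 * margin:
            raise SimulationError(
                f"region_length={n} too short for any variant"
            )
        min_gap = config.MAX_INDEL + 5  # keep events disjoint
        pos = 1 + int(rng.geometric(config.het_density))
        while pos <= n - margin:
            ref_base = reference[pos - 1]
            if rng.random() < config.indel_fraction:
                length = int(rng.integers(1, config.MAX_INDEL + 1))
                if rng.random() < 0.5:  # insertion
                    ins = "".join(rng.choice(_BASES, size=length))
                    ref_a, alt_a = ref_base, ref_base + ins
                else:  # deletion
                    ref_a = reference[pos - 1 : pos + length]
                    alt_a = ref_base
            else:
                others = [b for b in "ACGT" if b != ref_base]
                ref_a, alt_a = ref_base, others[int(rng.integers(3))]
            variants.append(
                TruthVariant(
                    pos=pos,
                    ref=ref_a,
                    alt=alt_a,
                    hap_a=int(rng.integers(2)),
                )
            )
            gap = max(int(rng.geometric(config.het_density)), min_gap)
            pos += gap
    return reference, variants


def write_reference_fasta(reference: str, chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")


def write_truth_vcf(
    truth: list[TruthVariant],
    chrom: str,
    region_length: int,
    path: str,
) -> None:
    """Truth variants as a phased single-sample VCF (GT ``a|b``)."""
    header = pysam.VariantHeader()
    header.contigs.add(chrom, length=region_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SIM")
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in truth:
            rec = out.new_record(
                contig=chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
            )
            rec.samples["SIM"]["GT"] = (v.hap_a, 1 - v.hap_a)
            rec.samples["SIM"].phased = True
            out.write(rec)


# ---------------------------------------------------------------------------
# haplotype sequences and read projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _AlnBlock:
    op: str  # M | I | D
    ref_start: int  # 0-based
    hap_start: int
    length: int  # hap length for M/I, ref length for D


def _haplotype(
    reference: str, truth: list[TruthVariant], hap: int
) -> tuple[str, list[_AlnBlock]]:
    """Apply one haplotype's alleles; return its sequence plus the exact
    alignment of that sequence back to the reference."""
    parts: list[str] = []
    blocks: list[_AlnBlock] = []
    ref_cur = 0  # 0-based
    hap_cur = 0

    def emit_match(ref_from: int, ref_to: int, seq: str) -> None:
        nonlocal hap_cur
        if ref_to <= ref_from:
            return
        blocks.append(
            _AlnBlock("M", ref_from, hap_cur, ref_to - ref_from)
        )
        parts.append(seq)
        hap_cur += ref_to - ref_from

    for v in truth:
        p0 = v.pos - 1
        emit_match(ref_cur, p0, reference[ref_cur:p0])
        allele = v.ref if (v.hap_a if hap == 0 else 1 - v.hap_a) == 0 else v.alt
        if len(v.ref) == len(v.alt) == 1:  # SNP (possibly = ref on this hap)
            emit_match(p0, p0 + 1, allele)
            ref_cur = p0 + 1
        elif len(v.alt) > len(v.ref):  # insertion site
            emit_match(p0, p0 + 1, allele[0])
            if len(allele) > 1:
                blocks.append(
                    _AlnBlock("I", p0 + 1, hap_cur, len(allele) - 1)
                )
                parts.append(allele[1:])
                hap_cur += len(allele) - 1
            ref_cur = p0 + 1
        else:  # deletion site
            emit_match(p0, p0 + 1, v.ref[0])
            if len(allele) == 1:  # deletion present on this haplotype
                blocks.append(
                    _AlnBlock("D", p0 + 1, hap_cur, len(v.ref) - 1)
                )
                ref_cur = p0 + len(v.ref)
            else:  # carries REF: copy the would-be-deleted bases
                emit_match(
                    p0 + 1, p0 + len(v.ref), reference[p0 + 1 : p0 + len(v.ref)]
                )
                ref_cur = p0 + len(v.ref)
    emit_match(ref_cur, len(reference), reference[ref_cur:])
    return "".join(parts), blocks


def _merge_blocks(blocks: list[_AlnBlock]) -> list[_AlnBlock]:
    merged: list[_AlnBlock] = []
    for b in blocks:
        if (
            merged
            and b.op == "M"
            and merged[-1].op == "M"
            and merged[-1].ref_start + merged[-1].length == b.ref_start
            and merged[-1].hap_start + merged[-1].length == b.hap_start
        ):
            last = merged.pop()
            merged.append(
                _AlnBlock("M", last.ref_start, last.hap_start, last.length + b.length)
            )
        else:
            merged.append(b)
    return merged


def _project_read(
    blocks: list[_AlnBlock], s: int, e: int
) -> tuple[int, list[tuple[str, int]]] | None:
    """CIGAR and 0-based reference start for hap interval [s, e).

    Insertions clipped by a read boundary become soft clips; deletions are
    kept only strictly inside the read.  Returns None when the read holds
    no reference-aligned base at all.
    """
    cigar: list[tuple[str, int]] = []
    ref_start: int | None = None
    for b in blocks:
        if b.op == "D":
            if s < b.hap_start < e:
                cigar.append(("D", b.length))
            continue
        ov_s = max(s, b.hap_start)
        ov_e = min(e, b.hap_start + b.length)
        if ov_s >= ov_e:
            continue
        if b.op == "M":
            if ref_start is None:
                ref_start = b.ref_start + (ov_s - b.hap_start)
            cigar.append(("M", ov_e - ov_s))
        else:
            cigar.append(("I", ov_e - ov_s))
    if ref_start is None:
        return None
    # boundary insertions cannot be represented as I; soft-clip them
    while cigar and cigar[0][0] == "D":
        cigar.pop(0)
    while cigar and cigar[-1][0] == "D":
        cigar.pop()
    if cigar and cigar[0][0] == "I":
        cigar[0] = ("S", cigar[0][1])
    if cigar and cigar[-1][0] == "I":
        cigar[-1] = ("S", cigar[-1][1])
    return ref_start, cigar


_OP_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _apply_errors(rng, seq: str, error_rate: float) -> tuple[str, list[int]]:
    if error_rate <= 0:
        return seq, []
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq, []
    out = list(seq)
    for i in hits:
        others = [b for b in "ACGT" if b != out[i]]
        out[i] = others[int(rng.integers(3))]
    return "".join(out), [int(i) for i in hits]


def simulate_reads(
    config: SimulationConfig,
    reference: str,
    truth: list[TruthVariant],
    out_path: str,
    mode: str = "paired",
    sidecar_path: str | None = None,
) -> int:
    """Draw reads from the two truth haplotypes and write a sorted SAM.

    ``mode`` is ``paired`` (two reads per fragment, insert length from a
    Normal) or ``long`` (single reads, exponential length).  Returns the
    number of reads written.  The sidecar JSON records, per read, its
    source haplotype and injected error positions.
    """
    if config.coverage <= 0:
        raise SimulationError("coverage must be positive")
    if mode not in ("paired", "long"):
        raise SimulationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1])
    )
    haps = [_merge_blocks_pair(reference, truth, h) for h in (0, 1)]

    records: list[dict] = []
    truth_log: dict[str, dict] = {}
    rl = config.read_length

    def add_read(name, flag, hap_idx, hap_seq, blocks, s, e, mate=None):
        proj = _project_read(blocks, s, e)
        if proj is None:
            return None
        ref_start, cigar = proj
        seq, errs = _apply_errors(rng, hap_seq[s:e], config.error_rate)
        rec = {
            "name": name,
            "flag": flag,
            "ref_start": ref_start,
            "cigar": [(_OP_CODE[op], ln) for op, ln in cigar],
            "seq": seq,
        }
        truth_log[f"{name}/{1 if flag & 0x40 or not flag & 0x1 else 2}"] = {
            "hap": hap_idx,
            "hap_start": s,
            "errors": errs,
        }
        records.append(rec)
        return rec

    if mode == "paired":
        n_frag = int(
            math.ceil(config.coverage * len(reference) / (2 * rl))
        )
        for i in range(n_frag):
            h = int(rng.integers(2))
            hap_seq, blocks = haps[h]
            flen = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            flen = max(rl, min(flen, len(hap_seq)))
            s = int(rng.integers(0, len(hap_seq) - flen + 1))
            name = f"frag{i:07d}"
            r1 = add_read(
                name, 99, h, hap_seq, blocks, s, min(s + rl, s + flen)
            )
            r2 = add_read(
                name, 147, h, hap_seq, blocks, max(s, s + flen - rl), s + flen
            )
            for a, b in ((r1, r2), (r2, r1)):
                if a is not None:
                    a["mate_start"] = b["ref_start"] if b else a["ref_start"]
    else:
        n_reads = int(
            math.ceil(
                config.coverage * len(reference) / config.long_read_mean_len
            )
        )
        for i in range(n_reads):
            h = int(rng.integers(2))
            hap_seq, blocks = haps[h]
            length = int(rng.exponential(config.long_read_mean_len))
            length = max(500, min(length, len(hap_seq)))
            s = int(rng.integers(0, len(hap_seq) - length + 1))
            add_read(f"long{i:07d}", 0, h, hap_seq, blocks, s, s + length)

    records.sort(key=lambda r: (r["ref_start"], r["name"], r["flag"]))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": len(reference)}],
    }
    write_mode = "wb" if str(out_path).endswith(".bam") else "w"
    with pysam.AlignmentFile(out_path, write_mode, header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            a.flag = r["flag"]
            a.reference_id = 0
            a.reference_start = r["ref_start"]
            a.mapping_quality = 60
            a.cigartuples = r["cigar"]
            a.query_sequence = r["seq"]
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(r["seq"])
            )
            if r["flag"] & 0x1:
                a.next_reference_id = 0
                a.next_reference_start = r.get("mate_start", r["ref_start"])
            out.write(a)
    if write_mode == "wb":
        pysam.index(str(out_path))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(truth_log, fh, indent=0, sort_keys=True)
    return len(records)


def _merge_blocks_pair(reference, truth, hap):
    seq, blocks = _haplotype(reference, truth, hap)
    return seq, _merge_blocks(blocks)


# ---------------------------------------------------------------------------
# fixture orchestration
# ---------------------------------------------------------------------------


def simulate_fixture(
    config: SimulationConfig, out_dir: str, mode: str = "paired"
) -> dict[str, str]:
    """Write reference FASTA, truth VCF, reads SAM and sidecar JSON.

    Returns the paths keyed by role; this is the one-stop entry point used
    by the CLI and the test suite.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": str(out / "reference.fa"),
        "truth_vcf": str(out / "truth.vcf"),
        "reads": str(out / "reads.sam"),
        "sidecar": str(out / "reads.truth.json"),
    }
    reference, truth = simulate_truth(config)
    write_reference_fasta(reference, config.chrom, paths["reference"])
    write_truth_vcf(
        truth, config.chrom, config.region_length, paths["truth_vcf"]
    )
    simulate_reads(
        config,
        reference,
        truth,
        paths["reads"],
        mode=mode,
        sidecar_path=paths["sidecar"],
    )
    return paths
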
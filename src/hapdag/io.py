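"""Variant and alignment I/O: heterozygous sites, per-fragment allele
observations, and phased output.

VCF and SAM coordinates stay 1-based/0-based per their own conventions at
the boundary; internally every site is addressed by its 0-based *level*
within the chromosome's ordered heterozygous variant list.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

SNP = "SNP"
INDEL = "INDEL"

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_BASEQ = 13


class InputError(ValueError):
    """Malformed or inconsistent user input (VCF/alignment)."""


class ConsistencyError(RuntimeError):
    """Internal contract violation between pipeline stages."""


@dataclass(frozen=True)
class HetVariant:
    """One biallelic heterozygous site (one H-DAG level).

    ``pos`` is the 1-based VCF coordinate; ``level`` the 0-based index in
    the chromosome's position-sorted heterozygous variant list.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    level: int
    kind: str  # SNP | INDEL

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise InputError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref_allele == self.alt_allele:
            raise InputError(
                f"identical REF/ALT at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class AlleleObservation:
    """One read-backed allele call: which member of the site's pair
    (0 = REF, 1 = ALT) a molecule supports, with its Phred confidence."""

    level: int
    allele_index: int
    base_quality: int


@dataclass(frozen=True)
class Fragment:
    """One DNA molecule's allele observations across levels.

    A fragment is a single long read or a merged read pair; observations
    are sorted by level, at most one per level, and fragments with fewer
    than two observations are never materialised (they carry no phase
    information).
    """

    fragment_id: str
    observations: tuple[AlleleObservation, ...]
    source: str = "paired-end"  # paired-end | long-read

    def __post_init__(self):
        levels = [o.level for o in self.observations]
        if len(self.observations) < 2:
            raise ValueError("fragment needs >=2 observations")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("observation levels must strictly increase")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(o.level for o in self.observations)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _classify_alleles(ref: str, alt: str) -> str | None:
    """SNP, simple INDEL, or None for complex records we do not phase."""
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    if len(ref) == 1 or len(alt) == 1:
        return INDEL
    return None  # MNP / complex substitution


def read_het_variants(
    vcf_path: str, chrom: str | None = None
) -> tuple[dict[str, list[HetVariant]], Counter]:
    """Position-sorted biallelic heterozygous variants per chromosome.

    Homozygous, multiallelic, missing-genotype and complex records are
    skipped and tallied in the returned skip report.  Two heterozygous
    records at the same position are an input error: levels must map
    one-to-one onto positions.
    """
    by_chrom: dict[str, list[HetVariant]] = defaultdict(list)
    skips: Counter = Counter()
    try:
        vcf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {vcf_path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if chrom is not None and rec.chrom != chrom:
                continue
            if rec.alts is None or len(rec.alts) == 0:
                skips["no_alt"] += 1
                continue
            if len(rec.alts) > 1:
                skips["multiallelic"] += 1
                continue
            if not rec.samples:
                raise InputError(
                    f"VCF record {rec.chrom}:{rec.pos} has no sample column"
                )
            gt = rec.samples[0].get("GT")
            if gt is None or None in gt or len(gt) != 2:
                skips["missing_genotype"] += 1
                continue
            if set(gt) != {0, 1}:
                skips["homozygous"] += 1
                continue
            kind = _classify_alleles(rec.ref, rec.alts[0])
            if kind is None:
                skips["complex"] += 1
                continue
            dest = by_chrom[rec.chrom]
            if dest and dest[-1].pos == rec.pos:
                raise InputError(
                    f"two heterozygous records at {rec.chrom}:{rec.pos}"
                )
            if dest and dest[-1].pos > rec.pos:
                raise InputError(
                    f"VCF not position-sorted at {rec.chrom}:{rec.pos}"
                )
            dest.append(
                HetVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    level=len(dest),
                    kind=kind,
                )
            )
    if skips:
        logger.info("skipped VCF records: %s", dict(skips))
    return dict(by_chrom), skips


# ---------------------------------------------------------------------------
# fragment extraction from alignments
# ---------------------------------------------------------------------------


def _alignment_maps(read: pysam.AlignedSegment):
    """Walk the CIGAR once: ref->query map, deleted ref positions, and
    insertions keyed by the ref position they follow."""
    aligned: dict[int, int] = {}
    deleted: set[int] = set()
    insertions: dict[int, tuple[int, int]] = {}
    qpos = 0
    rpos = read.reference_start
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            for k in range(ln):
                aligned[rpos + k] = qpos + k
            qpos += ln
            rpos += ln
        elif op == 1:  # I
            insertions[rpos - 1] = (qpos, ln)
            qpos += ln
        elif op == 2:  # D
            deleted.update(range(rpos, rpos + ln))
            rpos += ln
        elif op == 3:  # N
            rpos += ln
        elif op == 4:  # S
            qpos += ln
        # H/P consume nothing we need
    return aligned, deleted, insertions


def _observe_site(
    read_maps, seq: str, quals, variant: HetVariant, min_baseq: int
) -> tuple[int, int] | None:
    """Decide which allele (if either) a read supports at one site.

    SNPs need the aligned base to equal REF or ALT at adequate quality.
    INDELs need the read to span the *full* REF-or-ALT event: an exact
    insertion/deletion of the right sequence and length in the CIGAR, with
    the alignment continuing past the event on both sides.  Anything else
    yields no observation.
    """
    aligned, deleted, insertions = read_maps
    p0 = variant.pos - 1  # 0-based anchor
    ref, alt = variant.ref_allele, variant.alt_allele

    if variant.kind == SNP:
        qi = aligned.get(p0)
        if qi is None:
            return None
        if quals[qi] < min_baseq:
            return None
        base = seq[qi]
        if base == ref:
            return (0, quals[qi])
        if base == alt:
            return (1, quals[qi])
        return None

    anchor = aligned.get(p0)
    if anchor is None or quals[anchor] < min_baseq:
        return None
    if len(alt) > len(ref):  # insertion (REF is the anchor base)
        ins_seq = alt[1:]
        ins = insertions.get(p0)
        if ins is not None:
            qstart, ln = ins
            if (
                ln == len(ins_seq)
                and seq[qstart : qstart + ln] == ins_seq
                and p0 + 1 in aligned
            ):
                q = min([quals[anchor]] + list(quals[qstart : qstart + ln]))
                if q >= min_baseq:
                    return (1, q)
            return None
        if p0 + 1 in aligned:  # spans the junction with no insertion
            return (0, quals[anchor])
        return None
    # deletion (ALT is the anchor base)
    del_span = range(p0 + 1, p0 + len(ref))
    if all(r in deleted for r in del_span):
        # exact event: alignment resumes right after the deleted bases
        if p0 + len(ref) in aligned:
            return (1, quals[anchor])
        return None
    if all(r in aligned for r in del_span):
        bases = "".join(seq[aligned[r]] for r in del_span)
        if bases == ref[1:]:
            return (0, quals[anchor])
    return None


def _check_alignment_header(af: pysam.AlignmentFile, chrom: str) -> None:
    header = af.header.to_dict()
    hd = header.get("HD", {})
    so = hd.get("SO")
    if so is not None and so != "coordinate":
        raise InputError(f"alignment file is not coordinate-sorted (SO={so})")
    contigs = {sq["SN"] for sq in header.get("SQ", [])}
    if chrom not in contigs:
        raise InputError(
            f"chromosome {chrom!r} absent from alignment header "
            f"(contigs: {sorted(contigs)[:5]}...)"
        )


def extract_fragments(
    bam_path: str,
    variants: Sequence[HetVariant],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> list[Fragment]:
    """Per-molecule allele observations over one chromosome's variants.

    Primary alignments sharing a query name are merged into one fragment
    (the two mates of a pair); if both mates cover the same variant with
    conflicting alleles the observation at that level is dropped, since
    conflicting evidence within one molecule is uninformative.  Secondary,
    supplementary and duplicate alignments are excluded.  Fragments with
    fewer than two observations are discarded.
    """
    if not variants:
        return []
    chrom = variants[0].chrom
    positions = [v.pos - 1 for v in variants]
    max_event = max(len(v.ref_allele) for v in variants) + 1

    import bisect

    # per molecule: level -> (allele_index, qual) or None after conflict
    molecules: dict[str, dict[int, tuple[int, int] | None]] = defaultdict(dict)
    sources: dict[str, str] = {}

    try:
        af = pysam.AlignmentFile(bam_path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read alignments {bam_path}: {exc}") from exc
    with af:
        _check_alignment_header(af, chrom)
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            if read.reference_name != chrom:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.cigartuples is None or read.query_sequence is None:
                continue
            lo = bisect.bisect_left(
                positions, read.reference_start - max_event
            )
            hi = bisect.bisect_right(positions, read.reference_end)
            if hi - lo == 0:
                continue
            maps = _alignment_maps(read)
            seq = read.query_sequence
            quals = read.query_qualities
            if quals is None:
                quals = [min_baseq] * len(seq)
            obs = molecules[read.query_name]
            sources[read.query_name] = (
                "paired-end" if read.is_paired else "long-read"
            )
            for idx in range(lo, hi):
                call = _observe_site(maps, seq, quals, variants[idx], min_baseq)
                if call is None:
                    continue
                level = variants[idx].level
                if level in obs:
                    prev = obs[level]
                    if prev is not None and prev[0] != call[0]:
                        obs[level] = None  # intra-molecule conflict
                else:
                    obs[level] = call

    fragments = []
    for name, obs in molecules.items():
        kept = sorted(
            (lv, c) for lv, c in obs.items() if c is not None
        )
        if len(kept) < 2:
            continue
        fragments.append(
            Fragment(
                fragment_id=name,
                observations=tuple(
                    AlleleObservation(lv, a, q) for lv, (a, q) in kept
                ),
                source=sources[name],
            )
        )
    fragments.sort(key=lambda f: (f.observations[0].level, f.fragment_id))
    logger.info(
        "%s: %d fragments with >=2 observations", chrom, len(fragments)
    )
    return fragments


# ---------------------------------------------------------------------------
# phased output
# ---------------------------------------------------------------------------


def write_phased_output(
    blocks,
    variants_by_chrom: Mapping[str, Sequence[HetVariant]],
    vcf_in: str,
    out_vcf: str,
    out_blocks: str,
) -> None:
    """Write a phased VCF (``a|b`` + PS tag) and a plain-text block file.

    PS is the 1-based position of the block's first variant (the phase-set
    convention shared with other read-backed phasers).  The block file is
    the evaluation module's input: one BLOCK header line per block, then
    one line per variant with level, pos, and the two haplotype alleles.
    """
    # map (chrom, level) -> (block_first_pos, hap1 allele, hap2 allele)
    phased: dict[tuple[str, int], tuple[int, str, str]] = {}
    for pb in blocks:
        chrom = pb.block.parent.chrom
        variants = variants_by_chrom[chrom]
        first = pb.block.first_level
        if pb.block.last_level >= len(variants):
            raise ConsistencyError(
                f"block references level {pb.block.last_level} beyond "
                f"{len(variants)} variants on {chrom}"
            )
        ps = variants[first].pos
        for offset, level in enumerate(pb.block.levels):
            phased[(chrom, level)] = (ps, pb.hap1[offset], pb.hap2[offset])

    with pysam.VariantFile(vcf_in) as vin:
        header = vin.header.copy()
        if "PS" not in header.formats:
            header.formats.add(
                "PS", 1, "Integer", "Phase set (position of first variant)"
            )
        level_of: dict[tuple[str, int], int] = {}
        for chrom, variants in variants_by_chrom.items():
            for v in variants:
                level_of[(chrom, v.pos)] = v.level
        with pysam.VariantFile(out_vcf, "w", header=header) as vout:
            for rec in vin:
                rec.translate(header)
                level = level_of.get((rec.chrom, rec.pos))
                key = (rec.chrom, level)
                if level is not None and key in phased:
                    ps, hap1, _ = phased[key]
                    variants = variants_by_chrom[rec.chrom]
                    ref = variants[level].ref_allele
                    gt = (0, 1) if hap1 == ref else (1, 0)
                    sample = rec.samples[0]
                    sample["GT"] = gt
                    sample.phased = True
                    sample["PS"] = ps
                vout.write(rec)

    with open(out_blocks, "w") as fh:
        fh.write("#BLOCK\tchrom\tfirst_pos\tlast_pos\tn_variants\tspan_bp\n")
        fh.write("#VAR\tlevel\tpos\thap1\thap2\n")
        for pb in blocks:
            chrom = pb.block.parent.chrom
            variants = variants_by_chrom[chrom]
            first_pos = variants[pb.block.first_level].pos
            last_pos = variants[pb.block.last_level].pos
            fh.write(
                f"BLOCK\t{chrom}\t{first_pos}\t{last_pos}\t"
                f"{pb.block.n_levels}\t{last_pos - first_pos + 1}\n"
            )
            for offset, level in enumerate(pb.block.levels):
                fh.write(
                    f"VAR\t{level}\t{variants[level].pos}\t"
                    f"{pb.hap1[offset]}\t{pb.hap2[offset]}\n"
                )


@dataclass(frozen=True)
class BlockRecord:
    """One phased block as re-read from the block file."""

    chrom: str
    first_pos: int
    last_pos: int
    entries: tuple[tuple[int, int, str, str], ...]  # (level, pos, hap1, hap2)

    @property
    def span_bp(self) -> int:
        return self.last_pos - self.first_pos + 1


def read_block_file(path: str) -> list[BlockRecord]:
    """Parse the tab-separated block file written by write_phased_output."""
    records: list[BlockRecord] = []
    current: dict | None = None

    def _flush():
        nonlocal current
        if current is not None:
            records.append(
                BlockRecord(
                    chrom=current["chrom"],
                    first_pos=current["first_pos"],
                    last_pos=current["last_pos"],
                    entries=tuple(current["entries"]),
                )
            )
            current = None

    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "BLOCK":
                _flush()
                current = {
                    "chrom": fields[1],
                    "first_pos": int(fields[2]),
                    "last_pos": int(fields[3]),
                    "entries": [],
                }
            elif fields[0] == "VAR":
                if current is None:
                    raise InputError(f"VAR line before BLOCK in {path}")
                current["entries"].append(
                    (int(fields[1]), int(fields[2]), fields[3], fields[4])
                )
    _flush()
    return records


def read_phased_vcf(
    path: str, chrom: str | None = None
) -> dict[str, dict[int, tuple[str, str, int]]]:
    """Phased genotypes keyed by position: pos -> (hapA, hapB, phase set).

    Used for truth haplotypes during evaluation; unphased or homozygous
    records are ignored.
    """
    out: dict[str, dict[int, tuple[str, str, int]]] = defaultdict(dict)
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if chrom is not None and rec.chrom != chrom:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or None in gt or len(gt) != 2:
                continue
            if not sample.phased or set(gt) != {0, 1}:
                continue
            alleles = (rec.ref, rec.alts[0])
            ps = sample.get("PS")
            out[rec.chrom][rec.pos] = (
                alleles[gt[0]],
                alleles[gt[1]],
                int(ps) if ps is not None else 0,
            )
    return dict(out)
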
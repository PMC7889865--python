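"""Assembly-based variant discovery, zygosity inference and phasing.

Each haplotype's contigs are aligned back to the reference; every edit
operation of a passing alignment (contig > 1 kb, MAPQ >= 20) becomes a
variant candidate.  Candidates from the two haploid callsets are compared
to infer zygosity (alt on both haplotypes = homozygous, alt on one with
reference support on the other = heterozygous), merged with the read-based
SNP callset, phased against the phase-block scaffold by majority vote of
matching SNPs, and written as a phased VCF.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import edlib

from .assembly import ContigName, parse_contig_header
from .haplotyping import PhaseBlock

DEFAULT_MIN_CONTIG_LEN = 1000
DEFAULT_MIN_MAPQ = 20
DEFAULT_INS_BP_TOL = 20
SV_MIN_SIZE = 50


@dataclass(slots=True)
class ContigAlignment:
    """One contig-to-reference alignment with extended edit operations.

    ``ops`` is a list of (op, length) with op in {'=', 'X', 'I', 'D'};
    query/target sequences let variant extraction recover alleles.
    """

    contig_id: str
    contig_len: int
    chrom: str
    t_start: int  # 0-based on reference
    t_end: int
    mapq: int
    ops: list[tuple[str, int]]
    query: str
    target: str  # reference slice [t_start, t_end)
    name: ContigName | None = None


CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def parse_extended_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = []
    consumed = 0
    for m in CIGAR_RE.finditer(cigar):
        if m.start() != consumed:
            break
        ops.append((m.group(2), int(m.group(1))))
        consumed = m.end()
    if consumed != len(cigar):
        raise ValueError(f"malformed cigar/difference string at offset {consumed}: {cigar!r}")
    return ops


def align_contig(
    contig_id: str,
    contig_seq: str,
    ref_seq: str,
    chrom: str,
    region: tuple[int, int] | None = None,
    mapq: int = 60,
) -> ContigAlignment | None:
    """Align a contig to the reference (or a region of it) with edlib.

    This built-in affine-free aligner covers toy genomes; for real data an
    external aligner's PAF with cs difference strings can be parsed instead
    (:func:`read_paf`), feeding the identical downstream code path.
    """
    s, e = region if region is not None else (0, len(ref_seq))
    target = ref_seq[s:e]
    res = edlib.align(contig_seq, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc_s, loc_e = res["locations"][0]
    ops = parse_extended_cigar(res["cigar"])
    return ContigAlignment(
        contig_id=contig_id,
        contig_len=len(contig_seq),
        chrom=chrom,
        t_start=s + loc_s,
        t_end=s + loc_e + 1,
        mapq=mapq,
        ops=ops,
        query=contig_seq,
        target=target[loc_s : loc_e + 1],
    )


_CS_RE = re.compile(r"(:\d+|\*[a-zA-Z]{2}|\+[a-zA-Z]+|-[a-zA-Z]+)")


def read_paf(path, ref_by_chrom: dict[str, str]) -> list[ContigAlignment]:
    """Parse PAF records with cs:Z difference strings into alignments."""
    out: list[ContigAlignment] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            cs = next((x[5:] for x in f[12:] if x.startswith("cs:Z:")), None)
            if cs is None:
                continue
            ops: list[tuple[str, int]] = []
            consumed = 0
            for m in _CS_RE.finditer(cs):
                tok = m.group(0)
                if m.start() != consumed:
                    raise ValueError(f"malformed cs string at offset {consumed}: {cs!r}")
                consumed = m.end()
                if tok[0] == ":":
                    ops.append(("=", int(tok[1:])))
                elif tok[0] == "*":
                    ops.append(("X", 1))
                elif tok[0] == "+":
                    ops.append(("I", len(tok) - 1))
                else:
                    ops.append(("D", len(tok) - 1))
            if consumed != len(cs):
                raise ValueError(f"malformed cs string at offset {consumed}: {cs!r}")
            chrom, t_start, t_end = f[5], int(f[7]), int(f[8])
            ref = ref_by_chrom[chrom]
            out.append(ContigAlignment(
                contig_id=f[0], contig_len=int(f[1]), chrom=chrom,
                t_start=t_start, t_end=t_end, mapq=int(f[11]),
                ops=ops, query="", target=ref[t_start:t_end],
            ))
    return out


@dataclass(slots=True)
class VariantCandidate:
    haplotype: int
    chrom: str
    pos: int  # 1-based, anchored for indels (VCF convention)
    ref: str
    alt: str

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def size(self) -> int:
        return abs(len(self.alt) - len(self.ref)) or 1

    @property
    def end(self) -> int:
        """1-based inclusive end of the REF span."""
        return self.pos + len(self.ref) - 1


def left_align(cand: VariantCandidate, ref_seq: str) -> VariantCandidate:
    """Left-normalise an indel against the reference (SNPs pass through)."""
    if cand.vtype == "SNP":
        return cand
    pos = cand.pos  # 1-based anchor
    seq = cand.alt[1:] if cand.vtype == "INS" else cand.ref[1:]
    if not seq:
        return cand
    # the event can shift one base left when its last base equals the anchor
    # base; the event sequence is then rotated through the anchor
    while pos > 1 and seq[-1] == ref_seq[pos - 1]:
        seq = ref_seq[pos - 1] + seq[:-1]
        pos -= 1
    anchor = ref_seq[pos - 1]
    if cand.vtype == "INS":
        ref, alt = anchor, anchor + seq
    else:
        ref, alt = anchor + seq, anchor
    return VariantCandidate(cand.haplotype, cand.chrom, pos, ref, alt)


def extract_variants(
    alns: list[ContigAlignment],
    ref_seq: str,
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    merge_gap: int = 10,
) -> dict[int, list[VariantCandidate]]:
    """Collect per-haplotype variant candidates from contig alignments.

    Alignments of contigs of at most ``min_contig_len`` bp or below
    ``min_mapq`` contribute nothing; every edit operation of 1 bp or more
    is reported.  A unit-cost aligner may split one indel into co-optimal
    pieces separated by short accidental matches, so edit operations closer
    than ``merge_gap`` are re-normalised together: the spanned reference and
    query windows are trimmed to their minimal difference and the result is
    left-aligned.  Returns haplotype -> candidates.
    """
    out: dict[int, list[VariantCandidate]] = {1: [], 2: []}
    for aln in alns:
        if aln.contig_len <= min_contig_len or aln.mapq < min_mapq:
            continue
        name = aln.name or parse_contig_header(aln.contig_id)
        hp = name.haplotype
        # walk ops into events carrying (t_start, t_end, q_start, q_end)
        events: list[tuple[int, int, int, int]] = []
        t = aln.t_start
        q = 0
        for op, ln in aln.ops:
            if op == "S":
                q += ln
            elif op in ("=", "M"):
                t += ln
                q += ln
            elif op == "X":
                events.append((t, t + ln, q, q + ln))
                t += ln
                q += ln
            elif op == "I":
                events.append((t, t, q, q + ln))
                q += ln
            elif op == "D":
                events.append((t, t + ln, q, q))
                t += ln
        # cluster events separated by matches shorter than merge_gap
        i = 0
        while i < len(events):
            j = i
            while j + 1 < len(events) and events[j + 1][0] - events[j][1] < merge_gap:
                j += 1
            t0, t1 = events[i][0], events[j][1]
            q0, q1 = events[i][2], events[j][3]
            i = j + 1
            if t0 == 0 or q0 == 0:
                continue  # cannot anchor at the very edge
            ref_w = ref_seq[t0 - 1 : t1]
            alt_w = aln.query[q0 - 1 : q1]
            pos = t0  # 1-based position of the anchor base
            while len(ref_w) > 1 and len(alt_w) > 1 and ref_w[-1] == alt_w[-1]:
                ref_w, alt_w = ref_w[:-1], alt_w[:-1]
            while len(ref_w) > 1 and len(alt_w) > 1 and ref_w[0] == alt_w[0]:
                ref_w, alt_w = ref_w[1:], alt_w[1:]
                pos += 1
            if ref_w == alt_w:
                continue
            cand = VariantCandidate(hp, aln.chrom, pos, ref_w, alt_w)
            if cand.vtype != "SNP" and ref_w[0] == alt_w[0]:
                cand = left_align(cand, ref_seq)
            out[hp].append(cand)
    return out


@dataclass(slots=True)
class FinalVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # het or hom
    haplotype: int | None = None  # hap carrying the alt (het assembly calls)
    phase: tuple[int, int, int] | None = None  # (hap1 allele, hap2 allele, PS)
    source: str = "assembly"  # assembly, read_based, both
    flags: set[str] = field(default_factory=set)

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def size(self) -> int:
        return abs(len(self.alt) - len(self.ref)) or 1

    @property
    def is_sv(self) -> bool:
        return self.vtype != "SNP" and self.size >= SV_MIN_SIZE


def _coverage_intervals(alns: list[ContigAlignment], min_contig_len: int, min_mapq: int,
                        hap: int) -> list[tuple[int, int]]:
    ivs = []
    for a in alns:
        if a.contig_len <= min_contig_len or a.mapq < min_mapq:
            continue
        name = a.name or parse_contig_header(a.contig_id)
        if name.haplotype == hap:
            ivs.append((a.t_start, a.t_end))
    return sorted(ivs)


def _covers(ivs: list[tuple[int, int]], pos0: int, end0: int | None = None) -> bool:
    end0 = pos0 + 1 if end0 is None else end0
    return any(s <= pos0 and end0 <= e for s, e in ivs)


def infer_snp_zygosity(
    hap1_snps: list[VariantCandidate],
    hap2_snps: list[VariantCandidate],
    coverage: dict[int, list[tuple[int, int]]],
) -> list[FinalVariant]:
    """Cross the two haploid SNP callsets into genotyped variants.

    A site with the same alternate allele on both haplotypes is homozygous;
    alt on one haplotype with the other's contig covering the site (hence
    showing the reference base) is heterozygous; alt on one haplotype with
    no coverage on the other is heterozygous with a low-confidence flag.
    Different alternate alleles at one site become two het records flagged
    multiallelic.
    """
    by_site: dict[tuple[int, str], dict[int, str]] = defaultdict(dict)
    chrom = None
    for c in hap1_snps + hap2_snps:
        by_site[(c.pos, c.ref)][c.haplotype] = c.alt
        chrom = c.chrom
    out: list[FinalVariant] = []
    for (pos, ref), alts in sorted(by_site.items()):
        a1, a2 = alts.get(1), alts.get(2)
        if a1 is not None and a2 is not None:
            if a1 == a2:
                out.append(FinalVariant(chrom, pos, ref, a1, "hom"))
            else:
                for hp, alt in ((1, a1), (2, a2)):
                    out.append(FinalVariant(chrom, pos, ref, alt, "het", haplotype=hp,
                                            flags={"multiallelic"}))
        else:
            hp = 1 if a1 is not None else 2
            other = 2 if hp == 1 else 1
            flags = set() if _covers(coverage[other], pos - 1) else {"low_confidence"}
            out.append(FinalVariant(chrom, pos, ref, a1 or a2, "het", haplotype=hp, flags=flags))
    return out


def _same_indel(a: VariantCandidate, b: VariantCandidate, ins_bp_tol: int) -> bool:
    if a.vtype != b.vtype:
        return False
    if a.vtype == "DEL":
        # deleted intervals (1-based, excluding anchor) overlap by >= 1 bp
        return a.pos + 1 <= b.end and b.pos + 1 <= a.end
    return abs(a.pos - b.pos) <= ins_bp_tol


def infer_indel_sv_zygosity(
    hap1_cands: list[VariantCandidate],
    hap2_cands: list[VariantCandidate],
    coverage: dict[int, list[tuple[int, int]]],
    ins_bp_tol: int = DEFAULT_INS_BP_TOL,
) -> list[FinalVariant]:
    """Genotype indel/SV candidates by matching them across haplotypes.

    Two deletions are the same event when their intervals overlap; two
    insertions when their breakpoints lie within ``ins_bp_tol`` (20 bp).
    Matched events are homozygous (the haplotype-1 allele is reported);
    unmatched events with reference coverage on the other haplotype are
    heterozygous.
    """
    used2: set[int] = set()
    out: list[FinalVariant] = []
    for c1 in hap1_cands:
        match = None
        for j, c2 in enumerate(hap2_cands):
            if j not in used2 and _same_indel(c1, c2, ins_bp_tol):
                match = j
                break
        if match is not None:
            used2.add(match)
            out.append(FinalVariant(c1.chrom, c1.pos, c1.ref, c1.alt, "hom"))
        else:
            flags = set() if _covers(coverage[2], c1.pos - 1, c1.end) else {"low_confidence"}
            out.append(FinalVariant(c1.chrom, c1.pos, c1.ref, c1.alt, "het", haplotype=1,
                                    flags=flags))
    for j, c2 in enumerate(hap2_cands):
        if j in used2:
            continue
        flags = set() if _covers(coverage[1], c2.pos - 1, c2.end) else {"low_confidence"}
        out.append(FinalVariant(c2.chrom, c2.pos, c2.ref, c2.alt, "het", haplotype=2,
                                flags=flags))
    out.sort(key=lambda v: v.pos)
    return out


class ReferenceMismatchError(ValueError):
    pass


def merge_snp_calls(
    assembly_vars: list[FinalVariant],
    read_based: list[tuple[str, int, str, str, str]],
) -> list[FinalVariant]:
    """Union assembly SNPs with the read-based (mapping) callset.

    ``read_based`` rows are (chrom, pos, ref, alt, genotype).  Sites present
    in both keep source="both"; genotype conflicts resolve in favour of the
    read-based genotype, keeping the assembly call as an annotation.
    Contradictory reference alleles at a site indicate a reference mismatch
    and raise.
    """
    by_pos: dict[int, FinalVariant] = {v.pos: v for v in assembly_vars}
    out = dict(by_pos)
    for chrom, pos, ref, alt, gt in read_based:
        have = by_pos.get(pos)
        if have is None:
            out[pos] = FinalVariant(chrom, pos, ref, alt, gt, source="read_based")
            continue
        if have.ref != ref:
            raise ReferenceMismatchError(
                f"reference allele mismatch at {chrom}:{pos}: {have.ref} vs {ref}")
        have.source = "both"
        if have.genotype != gt or have.alt != alt:
            have.flags.add(f"assembly_call={have.alt}:{have.genotype}")
            have.genotype = gt
            have.alt = alt
    return [out[p] for p in sorted(out)]


def phase_variants(
    final_variants: list[FinalVariant],
    blocks: list[PhaseBlock],
    var_pos: dict[int, int],
    contig_lineage: dict[int, tuple[int, int]] | None = None,
) -> list[FinalVariant]:
    """Phase het variants against the phase-block scaffold.

    For every (block, contig-haplotype) the orientation relative to the
    scaffold is decided by majority vote over assembly SNPs that coincide
    with scaffold-phased SNPs; all het variants of that contig haplotype are
    then oriented accordingly with PS = block id.  Tied votes (or no
    informative overlap) leave the variants unphased.  Homozygous variants
    are reported as 1|1 without a phase set.
    """
    scaffold: dict[int, tuple[int, int]] = {}  # pos -> (hap1 allele, block_id)
    block_for_pos: dict[int, int] = {}
    for b in blocks:
        for vid, allele in b.variants.items():
            pos = var_pos[vid]
            scaffold[pos] = (allele, b.block_id)
            block_for_pos[pos] = b.block_id
    spans = {b.block_id: b.span for b in blocks}

    votes: dict[int, int] = defaultdict(int)  # block_id -> straight - crossed
    for v in final_variants:
        if v.genotype != "het" or v.haplotype is None or v.vtype != "SNP":
            continue
        sc = scaffold.get(v.pos)
        if sc is None:
            continue
        hap1_has_alt, bid = sc[0] == 1, sc[1]
        straight = (v.haplotype == 1) == hap1_has_alt
        votes[bid] += 1 if straight else -1

    def block_of(pos: int) -> int | None:
        for bid, (s, e) in spans.items():
            if s <= pos <= e:
                return bid
        return None

    for v in final_variants:
        if v.genotype == "hom":
            v.phase = (1, 1, 0)
            continue
        if v.haplotype is not None:
            bid = block_of(v.pos)
            if bid is None or votes.get(bid, 0) == 0:
                continue
            straight = votes[bid] > 0
            on_hap1 = (v.haplotype == 1) == straight
            v.phase = ((1, 0, bid) if on_hap1 else (0, 1, bid))
        else:
            sc = scaffold.get(v.pos)
            if sc is not None:
                allele, bid = sc
                v.phase = ((1, 0, bid) if allele == 1 else (0, 1, bid))
    return final_variants


def write_vcf(path, final_variants: list[FinalVariant], contigs_meta: dict[str, int],
              sample: str = "sample") -> None:
    """Write a phased VCF v4.2 ('|' genotypes with PS when phased)."""
    last = -1
    for v in final_variants:
        if v.pos < last:
            raise ValueError("variants must be sorted by position before writing")
        last = v.pos
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs_meta.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SRC,Number=1,Type=String,Description="Call source">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in final_variants:
            if v.genotype == "hom":
                fmt, val = "GT", "1/1"
            elif v.phase is not None:
                fmt, val = "GT:PS", f"{v.phase[0]}|{v.phase[1]}:{v.phase[2]}"
            else:
                fmt, val = "GT", "0/1"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t60\tPASS\t"
                     f"SRC={v.source}\t{fmt}\t{val}\n")


def read_vcf_simple(path) -> list[tuple[str, int, str, str, str]]:
    """Read (chrom, pos, ref, alt, genotype) rows from a VCF."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            gt = f[9].split(":")[0] if len(f) > 9 else "0/1"
            alleles = gt.replace("|", "/").split("/")
            zyg = "hom" if alleles == ["1", "1"] else "het"
            rows.append((f[0], int(f[1]), f[3], f[4], zyg))
    return rows
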
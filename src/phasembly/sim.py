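"""Synthetic diploid linked-read simulator.

Generates a random reference, plants SNPs/indels/SVs on two haplotypes,
draws long molecules with an exponential-like length distribution, and
emits barcoded read pairs at known placements together with truth files
(phased VCF, molecule table).  Alignments are emitted directly at their
true coordinates so that the downstream modules can be exercised without
an external read mapper; FASTQ output is available for end-to-end runs
with a real one.

Default parameters emulate a deep linked-read library on a small genome:
~50 kb molecules at ~100x physical coverage (C_F) with ~0.4x read coverage
per molecule (C_R), read pairs of 2 x 100 bp, and a 1e-3 per-base error
rate.  Base qualities are Q30, with Q10 at simulated error positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import ReadAlignment, HetVariant

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

QUAL_OK = 30
QUAL_ERR = 10

# planted variants keep this many bases between their footprints so each one
# is a distinct, unambiguously representable event
MIN_VARIANT_GAP = 60


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMP[arr][::-1].tobytes().decode()


@dataclass(slots=True)
class SVSpec:
    svtype: str  # INS or DEL
    size: int
    zygosity: str  # het or hom
    pos: int | None = None  # anchor on reference; random if None


@dataclass(slots=True)
class SimConfig:
    genome_length: int = 1_000_000
    chrom: str = "chrS"
    het_snp_rate: float = 1e-3
    hom_snp_rate: float = 5e-4
    indel_rate: float = 5e-5
    indel_size_geom_p: float = 0.35  # sizes ~ 1 + Geometric(p), capped
    indel_max_size: int = 10
    sv_spec: list[SVSpec] = field(default_factory=list)
    molecule_mean_length: int = 50_000
    molecule_min_length: int = 1_000
    n_barcodes: int = 2_500
    molecules_per_barcode: int = 2
    barcode_min_spacing: int = 200_000  # same-barcode molecules at least this far apart
    read_length: int = 100
    read_pairs_per_kb_of_molecule: float = 2.0  # sets C_R = 2*read_length*density/1000
    insert_size_mean: int = 420
    insert_size_sd: int = 40
    base_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_snp_rate", "hom_snp_rate", "indel_rate", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} = {v} must be in [0, 1)")
        if self.genome_length < 10 * self.molecule_mean_length:
            raise ValueError("genome_length must be >= 10 * molecule_mean_length")
        if self.read_length < 20:
            raise ValueError("read_length too small")

    @property
    def expected_c_r(self) -> float:
        return 2.0 * self.read_length * self.read_pairs_per_kb_of_molecule / 1000.0

    @property
    def expected_c_f(self) -> float:
        n_mol = self.n_barcodes * self.molecules_per_barcode
        return n_mol * self.molecule_mean_length / self.genome_length


@dataclass(slots=True)
class TruthVariant:
    """A planted variant in VCF-like representation (0-based anchored pos)."""

    pos: int  # 0-based position of the first REF base
    ref: str
    alt: str
    vtype: str  # SNP, INS, DEL
    zygosity: str  # het or hom
    hap: int | None  # haplotype carrying the alt (het only); None for hom

    @property
    def size(self) -> int:
        return abs(len(self.alt) - len(self.ref)) or 1

    def on_hap(self, hap: int) -> bool:
        return self.zygosity == "hom" or self.hap == hap


@dataclass(slots=True)
class HaplotypeMap:
    """Coordinate map between the reference and one haplome.

    Stored as parallel arrays of collinear match blocks: block i aligns
    ref[ref_starts[i] : ref_starts[i] + lens[i]] to
    hap[hap_starts[i] : hap_starts[i] + lens[i]].
    """

    seq: str
    ref_starts: np.ndarray
    hap_starts: np.ndarray
    lens: np.ndarray

    def ref_to_hap(self, pos: int) -> int:
        i = int(np.searchsorted(self.ref_starts, pos, side="right")) - 1
        i = max(i, 0)
        off = min(max(pos - self.ref_starts[i], 0), self.lens[i])
        return int(self.hap_starts[i] + off)

    def hap_to_ref(self, pos: int) -> int:
        i = int(np.searchsorted(self.hap_starts, pos, side="right")) - 1
        i = max(i, 0)
        off = min(max(pos - self.hap_starts[i], 0), self.lens[i])
        return int(self.ref_starts[i] + off)

    def hap_interval_to_cigar(self, a: int, b: int) -> tuple[int, list[tuple[str, int]]]:
        """Map hap-space interval [a, b) to (ref_start, cigar ops).

        Ops use M (aligned), I (present only in hap/read), D (deleted from
        ref); leading/trailing I are returned as S (soft clip).
        """
        ops: list[tuple[str, int]] = []
        ref_start = None
        n = len(self.lens)
        i = max(int(np.searchsorted(self.hap_starts, a, side="right")) - 1, 0)
        pos = a
        while pos < b and i < n:
            h0, r0, ln = int(self.hap_starts[i]), int(self.ref_starts[i]), int(self.lens[i])
            if pos < h0:  # inside an insertion preceding block i
                take = min(h0, b) - pos
                ops.append(("I", take))
                pos += take
                continue
            if pos < h0 + ln:
                take = min(h0 + ln, b) - pos
                if ref_start is None:
                    ref_start = r0 + (pos - h0)
                elif ops and ops[-1][0] != "D" and r0 + (pos - h0) > _ref_cursor(ref_start, ops):
                    ops.append(("D", r0 + (pos - h0) - _ref_cursor(ref_start, ops)))
                ops.append(("M", take))
                pos += take
            else:
                i += 1
        if pos < b:  # ran past last block (trailing insertion)
            ops.append(("I", b - pos))
        # collapse and convert edge I to S
        ops = _collapse(ops)
        if ops and ops[0][0] == "I":
            ops[0] = ("S", ops[0][1])
        if ops and ops[-1][0] == "I":
            ops[-1] = ("S", ops[-1][1])
        if ref_start is None:
            ref_start = self.hap_to_ref(a)
            ops = [("S", b - a)] if not ops else ops
        return ref_start, ops


def _ref_cursor(ref_start: int, ops: list[tuple[str, int]]) -> int:
    return ref_start + sum(ln for op, ln in ops if op in ("M", "D"))


def _collapse(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


@dataclass(slots=True)
class TruthMolecule:
    molecule_id: int
    barcode: str
    hap: int
    start: int  # reference coordinates
    end: int


@dataclass(slots=True)
class DiploidTruth:
    cfg: SimConfig
    ref_seq: str
    variants: list[TruthVariant]
    hap_maps: dict[int, HaplotypeMap]
    molecule_table: list[TruthMolecule]

    @property
    def het_snvs(self) -> list[TruthVariant]:
        return [v for v in self.variants if v.vtype == "SNP" and v.zygosity == "het"]

    def hap_variants(self, hap: int) -> list[TruthVariant]:
        return [v for v in self.variants if v.on_hap(hap)]

    @property
    def truth_phase(self) -> dict[int, int]:
        """Het-SNP variant id (index into het_snvs) -> haplotype of origin."""
        return {i: v.hap for i, v in enumerate(self.het_snvs)}


class SVPlacementError(ValueError):
    """Raised when requested SVs cannot be placed without overlap."""


def _draw_variant_positions(rng, length, n, occupied, footprint, margin=150, tries=50):
    """Sample n positions whose [pos, pos+footprint) avoids occupied intervals."""
    chosen = []
    for _ in range(n):
        for _t in range(tries):
            p = int(rng.integers(margin, length - margin - footprint))
            if all(p + footprint + MIN_VARIANT_GAP <= s or p >= e + MIN_VARIANT_GAP for s, e in occupied):
                occupied.append((p, p + footprint))
                chosen.append(p)
                break
        else:
            raise SVPlacementError("could not place variant without overlap")
    return chosen


def simulate_truth(cfg: SimConfig) -> DiploidTruth:
    """Draw a reference, plant variants and place molecules.

    Variant counts are Poisson-like (binomial over genome positions); no two
    planted variants overlap on either haplotype, and requested SVs that
    cannot be placed raise :class:`SVPlacementError`.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = random_sequence(rng, cfg.genome_length)
    occupied: list[tuple[int, int]] = []
    variants: list[TruthVariant] = []

    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)

    # SVs first (largest footprint)
    for sv in cfg.sv_spec:
        if sv.pos is not None:
            footprint = sv.size + 1 if sv.svtype == "DEL" else 1
            if not all(sv.pos + footprint + MIN_VARIANT_GAP <= s or sv.pos >= e + MIN_VARIANT_GAP for s, e in occupied):
                raise SVPlacementError(f"requested SV at {sv.pos} overlaps another variant")
            occupied.append((sv.pos, sv.pos + footprint))
            pos = sv.pos
        else:
            footprint = sv.size + 1 if sv.svtype == "DEL" else 1
            pos = _draw_variant_positions(rng, cfg.genome_length, 1, occupied, footprint)[0]
        anchor = ref[pos]
        if sv.svtype == "DEL":
            tv = TruthVariant(pos, ref[pos : pos + sv.size + 1], anchor, "DEL", sv.zygosity,
                              int(rng.integers(1, 3)) if sv.zygosity == "het" else None)
        elif sv.svtype == "INS":
            ins = random_sequence(rng, sv.size)
            tv = TruthVariant(pos, anchor, anchor + ins, "INS", sv.zygosity,
                              int(rng.integers(1, 3)) if sv.zygosity == "het" else None)
        else:
            raise ValueError(f"unsupported SV type {sv.svtype}")
        variants.append(tv)

    # small indels
    n_indel = rng.binomial(cfg.genome_length, cfg.indel_rate)
    for pos in _draw_variant_positions(rng, cfg.genome_length, n_indel, occupied,
                                       cfg.indel_max_size + 1):
        size = min(1 + int(rng.geometric(cfg.indel_size_geom_p)), cfg.indel_max_size)
        zyg = "het" if rng.random() < 0.6 else "hom"
        hap = int(rng.integers(1, 3)) if zyg == "het" else None
        anchor = ref[pos]
        if rng.random() < 0.5:
            variants.append(TruthVariant(pos, ref[pos : pos + size + 1], anchor, "DEL", zyg, hap))
        else:
            variants.append(TruthVariant(pos, anchor, anchor + random_sequence(rng, size),
                                         "INS", zyg, hap))

    # SNPs: draw counts then positions avoiding occupied intervals
    for rate, zyg in ((cfg.het_snp_rate, "het"), (cfg.hom_snp_rate, "hom")):
        n = rng.binomial(cfg.genome_length, rate)
        for pos in _draw_variant_positions(rng, cfg.genome_length, n, occupied, 1):
            refb = ref[pos]
            alt = refb
            while alt == refb:
                alt = chr(BASES[rng.integers(4)])
            hap = int(rng.integers(1, 3)) if zyg == "het" else None
            variants.append(TruthVariant(pos, refb, alt, "SNP", zyg, hap))

    variants.sort(key=lambda v: v.pos)
    hap_maps = {h: _build_haplome(ref_arr, [v for v in variants if v.on_hap(h)]) for h in (1, 2)}

    molecules = _place_molecules(rng, cfg)
    return DiploidTruth(cfg=cfg, ref_seq=ref, variants=variants, hap_maps=hap_maps,
                        molecule_table=molecules)


def _build_haplome(ref_arr: np.ndarray, variants: list[TruthVariant]) -> HaplotypeMap:
    """Apply sorted, non-overlapping variants to the reference."""
    snp_pos = np.array([v.pos for v in variants if v.vtype == "SNP"], dtype=np.int64)
    snp_alt = np.frombuffer("".join(v.alt for v in variants if v.vtype == "SNP").encode(),
                            dtype=np.uint8)
    arr = ref_arr.copy()
    if len(snp_pos):
        arr[snp_pos] = snp_alt
    pieces: list[np.ndarray] = []
    ref_starts, hap_starts, lens = [0], [0], []
    cur_ref = 0
    cur_hap = 0
    for v in variants:
        if v.vtype == "SNP":
            continue
        # match block up to and including the anchor base
        blk = arr[cur_ref : v.pos + 1]
        pieces.append(blk)
        lens.append(len(blk))
        cur_hap += len(blk)
        if v.vtype == "DEL":
            cur_ref = v.pos + len(v.ref)
        else:  # INS
            ins = np.frombuffer(v.alt[1:].encode(), dtype=np.uint8)
            pieces.append(ins)
            cur_ref = v.pos + 1
            cur_hap += len(ins)
        ref_starts.append(cur_ref)
        hap_starts.append(cur_hap)
    tail = arr[cur_ref:]
    pieces.append(tail)
    lens.append(len(tail))
    seq = np.concatenate(pieces).tobytes().decode() if pieces else ""
    return HaplotypeMap(seq=seq,
                        ref_starts=np.asarray(ref_starts, dtype=np.int64),
                        hap_starts=np.asarray(hap_starts, dtype=np.int64),
                        lens=np.asarray(lens, dtype=np.int64))


def _place_molecules(rng: np.random.Generator, cfg: SimConfig) -> list[TruthMolecule]:
    mols: list[TruthMolecule] = []
    mid = 0
    G = cfg.genome_length
    for b in range(cfg.n_barcodes):
        barcode = f"BX{b:06d}"
        placed: list[tuple[int, int]] = []
        for _ in range(cfg.molecules_per_barcode):
            length = 0
            while not (cfg.molecule_min_length <= length <= 5 * cfg.molecule_mean_length):
                length = int(rng.exponential(cfg.molecule_mean_length))
            for _try in range(30):
                # starts may hang off the left edge so edge coverage stays uniform
                start = int(rng.integers(-length + 1, G))
                # spacing between molecule INTERVALS, so the split-gap rule can
                # always separate same-barcode molecules (no chimeric merges)
                if all(start >= pe + cfg.barcode_min_spacing
                       or start + length <= ps - cfg.barcode_min_spacing
                       for ps, pe in placed):
                    break
            else:
                continue
            placed.append((start, start + length))
            s, e = max(start, 0), min(start + length, G)
            if e - s < cfg.molecule_min_length:
                continue
            hap = int(rng.integers(1, 3))
            mols.append(TruthMolecule(mid, barcode, hap, s, e))
            mid += 1
    return mols


@dataclass(slots=True)
class ReadSimResult:
    truth: DiploidTruth
    alignments: list[ReadAlignment]  # sorted by (barcode, chrom, start)
    het_variants: list[HetVariant]  # read-based het-SNP callset with depth/qual stats


def simulate_reads(truth: DiploidTruth, cfg: SimConfig | None = None) -> ReadSimResult:
    """Emit barcoded read pairs for every molecule at known placements.

    Reads are drawn in haplome coordinates inside each molecule's span,
    sequencing errors are injected at ``base_error_rate``, and each read's
    alignment is mapped back to reference coordinates through the haplotype
    coordinate map.  Het-SNP base calls (allele plus base quality) are
    recorded per read for the haplotyping stage, and a read-based het-SNP
    callset with realistic depth/alt-fraction statistics is derived.
    """
    cfg = cfg or truth.cfg
    rng = np.random.default_rng(cfg.seed + 1)
    rl = cfg.read_length
    het = truth.het_snvs
    het_pos_hap = {h: np.array([truth.hap_maps[h].ref_to_hap(v.pos) for v in het], dtype=np.int64)
                   for h in (1, 2)}
    het_is_alt = {h: np.array([v.hap == h for v in het], dtype=bool) for h in (1, 2)}

    alignments: list[ReadAlignment] = []
    depth = np.zeros(len(het), dtype=np.int64)
    alt_count = np.zeros(len(het), dtype=np.int64)
    q_ok_str = chr(QUAL_OK + 33) * rl

    for mol in truth.molecule_table:
        hmap = truth.hap_maps[mol.hap]
        hs, he = hmap.ref_to_hap(mol.start), hmap.ref_to_hap(mol.end)
        L = he - hs
        if L < 2 * rl + 10:
            continue
        n_pairs = rng.poisson(L / 1000.0 * cfg.read_pairs_per_kb_of_molecule)
        if n_pairs == 0:
            continue
        inserts = np.clip(rng.normal(cfg.insert_size_mean, cfg.insert_size_sd, n_pairs),
                          2 * rl, max(2 * rl, min(L, 800))).astype(np.int64)
        starts = (hs + (rng.random(n_pairs) * (L - inserts)).astype(np.int64))
        site_lo = int(np.searchsorted(het_pos_hap[mol.hap], hs))
        site_hi = int(np.searchsorted(het_pos_hap[mol.hap], he))
        sites = het_pos_hap[mol.hap][site_lo:site_hi]
        sites_alt = het_is_alt[mol.hap][site_lo:site_hi]
        for p in range(n_pairs):
            for mate, (a, b) in enumerate(
                ((int(starts[p]), int(starts[p]) + rl),
                 (int(starts[p] + inserts[p]) - rl, int(starts[p] + inserts[p]))),
            ):
                seq = hmap.seq[a:b]
                quals = q_ok_str
                err_off: np.ndarray | None = None
                if cfg.base_error_rate > 0:
                    n_err = rng.binomial(rl, cfg.base_error_rate)
                    if n_err:
                        err_off = rng.choice(rl, size=n_err, replace=False)
                        sarr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                        qarr = np.frombuffer(quals.encode(), dtype=np.uint8).copy()
                        for o in err_off:
                            cur = sarr[o]
                            nb = cur
                            while nb == cur:
                                nb = BASES[rng.integers(4)]
                            sarr[o] = nb
                        qarr[err_off] = QUAL_ERR + 33
                        seq = sarr.tobytes().decode()
                        quals = qarr.tobytes().decode()
                lo = int(np.searchsorted(sites, a))
                hi = int(np.searchsorted(sites, b))
                calls: dict[int, tuple[int, int]] = {}
                for si in range(lo, hi):
                    off = int(sites[si] - a)
                    allele = int(sites_alt[si])
                    q = QUAL_OK
                    if err_off is not None and off in set(int(x) for x in err_off):
                        # an error at the site: the observed base matches the
                        # other allele only 1/3 of the time; otherwise the call
                        # is a non-allelic base and would be discarded upstream
                        if rng.random() < 1.0 / 3.0:
                            allele = 1 - allele
                            q = QUAL_ERR
                        else:
                            continue
                    vid = site_lo + si
                    calls[vid] = (allele, q)
                    depth[vid] += 1
                    alt_count[vid] += allele
                ref_start, ops = hmap.hap_interval_to_cigar(a, b)
                ref_end = ref_start + sum(ln for op, ln in ops if op in ("M", "D"))
                alignments.append(ReadAlignment(
                    read_id=f"m{mol.molecule_id}p{p}_{mate + 1}",
                    barcode=mol.barcode,
                    chrom=cfg.chrom,
                    start=ref_start,
                    end=max(ref_end, ref_start + 1),
                    mapq=60,
                    base_calls=calls,
                    seq=seq,
                    quals=quals,
                    truth_hap=mol.hap,
                    truth_molecule=mol.molecule_id,
                ))

    alignments.sort(key=lambda r: (r.barcode, r.chrom, r.start))
    het_variants = [
        HetVariant(variant_id=i, chrom=cfg.chrom, pos=v.pos + 1,
                   ref_allele=v.ref, alt_allele=v.alt,
                   qual=50.0, depth=int(depth[i]), alt_count=int(alt_count[i]))
        for i, v in enumerate(het)
    ]
    return ReadSimResult(truth=truth, alignments=alignments, het_variants=het_variants)


def simulate(cfg: SimConfig) -> ReadSimResult:
    """Convenience: simulate_truth followed by simulate_reads."""
    return simulate_reads(simulate_truth(cfg), cfg)


# ---------------------------------------------------------------------------
# writers

def write_fasta(path, records: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path, alignments: list[ReadAlignment]) -> None:
    with open(path, "w") as fh:
        for r in alignments:
            fh.write(f"@{r.read_id} BX:Z:{r.barcode}\n{r.seq}\n+\n{r.quals}\n")


def write_sam(path, result: ReadSimResult) -> None:
    """Write truth-placed alignments as SAM with BX barcode tags, MAPQ 60."""
    cfg = result.truth.cfg
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{cfg.genome_length}\n")
        for r in result.alignments:
            if r.truth_hap is not None and r.end - r.start != len(r.seq):
                cigar = _cigar_for(result, r)
            else:
                cigar = f"{len(r.seq)}M"
            fh.write("\t".join([
                r.read_id, "0", r.chrom, str(r.start + 1), str(r.mapq), cigar,
                "*", "0", "0", r.seq or "*", r.quals or "*", f"BX:Z:{r.barcode}",
            ]) + "\n")


def _cigar_for(result: ReadSimResult, r: ReadAlignment) -> str:
    hmap = result.truth.hap_maps[r.truth_hap]
    a = hmap.ref_to_hap(r.start)
    _, ops = hmap.hap_interval_to_cigar(a, a + len(r.seq))
    return "".join(f"{ln}{op}" for op, ln in ops)


def write_truth_vcf(path, truth: DiploidTruth) -> None:
    """Phased truth VCF v4.2 (GT with '|', PS=1 for the whole chromosome)."""
    cfg = truth.cfg
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={cfg.genome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttruth\n")
        for v in truth.variants:
            if v.zygosity == "hom":
                gt, fmt, sample = "1|1", "GT", "1|1"
            else:
                gt = "1|0" if v.hap == 1 else "0|1"
                fmt, sample = "GT:PS", f"{gt}:1"
            fh.write(f"{cfg.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t60\tPASS\t.\t{fmt}\t{sample}\n")


def write_molecule_truth(path, truth: DiploidTruth) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tbarcode\thap\tstart\tend\n")
        for m in truth.molecule_table:
            fh.write(f"{m.molecule_id}\t{m.barcode}\t{m.hap}\t{m.start}\t{m.end}\n")
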
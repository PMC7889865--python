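"""Structural-variant post-analysis.

Covers cross-callset SV merging, Alu/tandem-repeat classification,
ancestral-state inference from outgroup flank alignments (deciding whether
a reference-relative insertion or deletion call is an *actual* molecular
insertion or deletion), and enumeration of derived-allele segregation
patterns across two individuals plus the reference haplome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product

from Bio import Align

DEFAULT_INS_TOL = 20
ALU_MIN_SIZE = 250
ALU_MAX_SIZE = 350
ALU_MIN_IDENTITY = 0.80
ANCESTRAL_ADJACENCY_TOL = 2
ANCESTRAL_SIZE_WINDOW = (0.9, 1.1)  # inclusive at both ends

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(slots=True)
class SVCall:
    """A structural variant (>= 50 bp) with its event sequence.

    For deletions ``sequence`` is the deleted reference sequence and
    end - start = size; insertions have end = start and carry the inserted
    sequence.
    """

    chrom: str
    start: int
    end: int
    svtype: str  # INS or DEL
    size: int
    genotype: str = "het"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.svtype == "DEL" and self.end - self.start != self.size:
            raise ValueError("DEL requires end - start == size")
        if self.svtype == "INS" and self.end != self.start:
            raise ValueError("INS requires end == start")


@dataclass(slots=True)
class MergedSV:
    representative: SVCall
    presence: list[bool]
    members: list[SVCall] = field(default_factory=list)


def _same_sv(a: SVCall, b: SVCall, ins_tol: int) -> bool:
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    if a.svtype == "DEL":
        return a.start < b.end and b.start < a.end
    return abs(a.start - b.start) <= ins_tol


def merge_sv_callsets(callsets: list[list[SVCall]], ins_tol: int = DEFAULT_INS_TOL) -> list[MergedSV]:
    """Merge SVs across callsets, recording per-callset presence.

    Deletions are the same event when their intervals overlap; insertions
    when their breakpoints lie within ``ins_tol`` bp (20 by default).  The
    merge is a transitive closure, so the result does not depend on the
    order callsets are given in.
    """
    items = [(ci, sv) for ci, cs in enumerate(callsets) for sv in cs]
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _same_sv(items[i][1], items[j][1], ins_tol):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for idxs in groups.values():
        members = [items[i][1] for i in idxs]
        presence = [False] * len(callsets)
        for i in idxs:
            presence[items[i][0]] = True
        rep = min(members, key=lambda s: (s.start, s.end))
        merged.append(MergedSV(representative=rep, presence=presence, members=members))
    merged.sort(key=lambda m: (m.representative.chrom, m.representative.start))
    return merged


# ---------------------------------------------------------------------------
# repeat classification

def load_alu_consensus() -> str:
    """The bundled Alu consensus sequence (synthetic stand-in, see data file)."""
    text = resources.files("phasembly.data").joinpath("alu_consensus_synthetic.fasta").read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


def _global_identity(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    matches = columns = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
    columns = aln.length
    return matches / columns if columns else 0.0


def classify_alu(sv: SVCall, consensus: str | None = None,
                 min_identity: float = ALU_MIN_IDENTITY) -> bool:
    """True when the SV is 250-350 bp and >= 80% identical to the Alu consensus.

    Identity is matches over alignment columns of a global affine-gap
    alignment; both strands are checked.
    """
    if sv.sequence is None:
        raise ValueError("classify_alu requires the SV sequence")
    if not ALU_MIN_SIZE <= sv.size <= ALU_MAX_SIZE:
        return False
    consensus = consensus or load_alu_consensus()
    fwd = _global_identity(sv.sequence, consensus)
    if fwd >= min_identity:
        return True
    rev = _global_identity(sv.sequence.translate(_COMP)[::-1], consensus)
    return rev >= min_identity


def has_tandem_repeat(seq: str, max_period: int = 6, min_copies: int = 3,
                      min_cover: float = 0.5) -> bool:
    """Naive tandem-repeat detector: a period <= ``max_period`` motif repeated
    >= ``min_copies`` times covering >= ``min_cover`` of the sequence."""
    n = len(seq)
    if n == 0:
        return False
    for p in range(1, max_period + 1):
        best = run = 0
        for i in range(n - p):
            if seq[i] == seq[i + p]:
                run += 1
                best = max(best, run)
            else:
                run = 0
        total = best + p  # length of the repeated tract
        if total >= p * min_copies and total >= min_cover * n:
            return True
    return False


def classify_repeat(
    sv: SVCall,
    consensus: str | None = None,
    repeat_annotation: list[tuple[str, int, int]] | None = None,
) -> str:
    """Classify an SV as 'Alu', 'Repeat' or 'Other'.

    Alu wins outright; otherwise an overlap with the repeat annotation (BED
    intervals) or a naive tandem-repeat hit yields 'Repeat'.
    """
    if classify_alu(sv, consensus):
        return "Alu"
    if repeat_annotation is not None:
        for chrom, s, e in repeat_annotation:
            if chrom == sv.chrom and s < max(sv.end, sv.start + 1) and sv.start < e:
                return "Repeat"
    if sv.sequence and has_tandem_repeat(sv.sequence):
        return "Repeat"
    return "Other"


# ---------------------------------------------------------------------------
# ancestral analysis

@dataclass(slots=True)
class FlankAlignment:
    """Placements of the SV's 500 bp flanks on one outgroup genome.

    ``gap`` is the distance on the outgroup between the end of the left
    flank and the start of the right flank.
    """

    outgroup: str
    chrom_left: str
    chrom_right: str
    strand: str
    left_end: int
    right_start: int

    @property
    def gap(self) -> int:
        return self.right_start - self.left_end


@dataclass(slots=True)
class AncestralAnnotation:
    label: str  # Ins_Ref, Del_Tar, Ins_Tar, Del_Ref, unresolved
    actual_type: str  # actual_insertion, actual_deletion, unresolved

    @classmethod
    def unresolved(cls) -> "AncestralAnnotation":
        return cls("unresolved", "unresolved")


_LABEL_TO_ACTUAL = {
    "Ins_Ref": "actual_insertion",
    "Ins_Tar": "actual_insertion",
    "Del_Tar": "actual_deletion",
    "Del_Ref": "actual_deletion",
}


def infer_ancestral(
    sv: SVCall,
    flank: FlankAlignment,
    adjacency_tol: int = ANCESTRAL_ADJACENCY_TOL,
) -> AncestralAnnotation:
    """Decide the molecular direction of an SV from its outgroup flank gap.

    For a deletion call: adjacent flanks on the outgroup (gap within 2 bp)
    mean the outgroup also lacks the sequence, so the reference gained it —
    "Ins_Ref", an actual insertion; a gap of roughly the deletion size
    (0.9-1.1x, inclusive) means the outgroup carries it — "Del_Tar", an
    actual deletion in the sequenced genome.  Insertion calls mirror this
    ("Ins_Tar" / "Del_Ref").  Anything else, including flanks on different
    outgroup chromosomes, is unresolved.
    """
    if flank.chrom_left != flank.chrom_right:
        return AncestralAnnotation.unresolved()
    gap = abs(flank.gap)
    lo, hi = ANCESTRAL_SIZE_WINDOW[0] * sv.size, ANCESTRAL_SIZE_WINDOW[1] * sv.size
    if gap <= adjacency_tol:
        label = "Ins_Ref" if sv.svtype == "DEL" else "Ins_Tar"
    elif lo <= gap <= hi:
        label = "Del_Tar" if sv.svtype == "DEL" else "Del_Ref"
    else:
        return AncestralAnnotation.unresolved()
    return AncestralAnnotation(label, _LABEL_TO_ACTUAL[label])


def combine_outgroups(annos: list[AncestralAnnotation]) -> AncestralAnnotation:
    """Reconcile annotations from several outgroups; disagreement -> unresolved."""
    resolved = [a for a in annos if a.label != "unresolved"]
    if not resolved:
        return AncestralAnnotation.unresolved()
    if len({a.actual_type for a in resolved}) > 1:
        return AncestralAnnotation.unresolved()
    return resolved[0]


# ---------------------------------------------------------------------------
# segregation patterns

@dataclass(frozen=True, slots=True)
class SegregationPattern:
    """Joint ancestral/derived configuration at one SV locus.

    Five chromosomes are observed: two per sequenced individual plus the
    reference haplome.  Genotypes count derived alleles (0-2) and
    ``ref_state`` says whether the reference carries the ancestral or the
    derived allele.
    """

    genotype_a: int
    genotype_b: int
    ref_state: str  # ancestral or derived

    @property
    def derived_total(self) -> int:
        return self.genotype_a + self.genotype_b + (1 if self.ref_state == "derived" else 0)


def enumerate_segregation_patterns() -> dict[str, list[SegregationPattern]]:
    """Catalogue the ancestral/derived configurations of the five chromosomes.

    There are 2 x 3 x 3 = 18 raw combinations; the two all-identical ones
    (all ancestral, all derived) are unobservable, leaving 16 patterns with
    one to four derived alleles.  The 12 patterns in which the two
    individuals' genotypes differ pair up into 6 equivalence classes under
    swapping the individuals.
    """
    raw = [SegregationPattern(a, b, r)
           for r, a, b in product(("ancestral", "derived"), range(3), range(3))]
    observable = [p for p in raw if 1 <= p.derived_total <= 4]
    differing = [p for p in observable if p.genotype_a != p.genotype_b]
    pairs: dict[tuple, list[SegregationPattern]] = {}
    for p in differing:
        key = (tuple(sorted((p.genotype_a, p.genotype_b))), p.ref_state)
        pairs.setdefault(key, []).append(p)
    return {
        "raw": raw,
        "observable": observable,
        "differing": differing,
        "pairs": list(pairs.values()),
    }


def classify_locus(gt_a: int, gt_b: int, annotation: AncestralAnnotation,
                   svtype: str, alt_is: str = "presence") -> tuple[SegregationPattern, str]:
    """Map an annotated SV locus to its segregation pattern and class id.

    ``gt_a``/``gt_b`` count ALT alleles (reference-relative) per individual.
    The ancestral annotation orients them: when the reference allele is the
    derived one, each individual's derived-allele count is 2 minus its ALT
    count.  Returns (pattern, class id); class ids distinguish actual
    insertions from actual deletions, giving the 12 classes over the 6
    differing-genotype equivalence pairs.
    """
    if annotation.label == "unresolved":
        raise ValueError("cannot classify a locus with unresolved ancestry")
    # which allele is ancestral? Ins_Ref/Del_Ref: the reference allele is the
    # derived one (the reference gained/lost sequence after the split).
    ref_is_derived = annotation.label in ("Ins_Ref", "Del_Ref")
    if ref_is_derived:
        da, db = 2 - gt_a, 2 - gt_b
        ref_state = "derived"
    else:
        da, db = gt_a, gt_b
        ref_state = "ancestral"
    pattern = SegregationPattern(da, db, ref_state)
    key = (tuple(sorted((da, db))), ref_state)
    class_id = f"{annotation.actual_type}:{key[0][0]}{key[0][1]}:{ref_state}"
    return pattern, class_id
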
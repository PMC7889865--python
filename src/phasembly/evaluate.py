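"""Evaluation of pipeline output against simulator truth.

Provides variant precision/recall/F1 by class, zygosity accuracy, phasing
accuracy relative to the truth phase (up to per-block haplotype
relabelling) and the diploid fraction — the share of the genome covered by
exactly two parental contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import DiploidTruth, TruthVariant
from .variation import ContigAlignment, FinalVariant, VariantCandidate, left_align


@dataclass(slots=True)
class ClassPerformance:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _norm_truth(v: TruthVariant, ref_seq: str) -> tuple[int, str, str]:
    cand = VariantCandidate(1, "", v.pos + 1, v.ref, v.alt)
    cand = left_align(cand, ref_seq)
    return cand.pos, cand.ref, cand.alt


def _klass(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    size = abs(len(ref) - len(alt))
    return "SV" if size >= 50 else "INDEL"


def variant_performance(
    final_variants: list[FinalVariant],
    truth: DiploidTruth,
    interior: np.ndarray | None = None,
) -> dict[str, ClassPerformance | float]:
    """Compare final calls with planted variants.

    Matching is exact on (left-aligned position, ref, alt).  ``interior``
    optionally restricts both sets to a boolean per-base mask (e.g. the
    well-assembled diploid region away from chunk boundaries).  Also returns
    the fraction of matched variants whose zygosity agrees with truth.
    """
    ref_seq = truth.ref_seq

    def in_interior(pos1: int) -> bool:
        return interior is None or (0 <= pos1 - 1 < len(interior) and bool(interior[pos1 - 1]))

    truth_by_key = {}
    for v in truth.variants:
        key = _norm_truth(v, ref_seq)
        truth_by_key[key] = v
    calls = {(v.pos, v.ref, v.alt): v for v in final_variants}

    stats = {k: ClassPerformance(0, 0, 0) for k in ("SNP", "INDEL", "SV")}
    zyg_ok = zyg_total = 0
    for key, tv in truth_by_key.items():
        if not in_interior(key[0]):
            continue
        k = _klass(key[1], key[2])
        if key in calls:
            stats[k].tp += 1
            zyg_total += 1
            if calls[key].genotype == tv.zygosity:
                zyg_ok += 1
        else:
            stats[k].fn += 1
    for key, cv in calls.items():
        if not in_interior(key[0]):
            continue
        if key not in truth_by_key:
            stats[_klass(key[1], key[2])].fp += 1
    out: dict[str, ClassPerformance | float] = dict(stats)
    out["zygosity_accuracy"] = zyg_ok / zyg_total if zyg_total else 1.0
    return out


def haplotype_coverage(
    alignments: list[ContigAlignment],
    genome_length: int,
    min_contig_len: int = 1000,
) -> dict[int, np.ndarray]:
    """Per-haplotype contig coverage depth over the reference."""
    cov = {1: np.zeros(genome_length + 1, dtype=np.int32),
           2: np.zeros(genome_length + 1, dtype=np.int32)}
    for a in alignments:
        if a.contig_len <= min_contig_len or a.name is None:
            continue
        arr = cov[a.name.haplotype]
        arr[min(a.t_start, genome_length)] += 1
        arr[min(a.t_end, genome_length)] -= 1
    return {h: np.cumsum(c[:-1]) for h, c in cov.items()}


def diploid_fraction(
    alignments: list[ContigAlignment],
    genome_length: int,
    min_contig_len: int = 1000,
) -> float:
    """Fraction of the genome covered by exactly one contig per haplotype."""
    cov = haplotype_coverage(alignments, genome_length, min_contig_len)
    return float(np.mean((cov[1] == 1) & (cov[2] == 1)))


def diploid_interior_mask(
    alignments: list[ContigAlignment],
    genome_length: int,
    min_contig_len: int = 1000,
    margin: int = 1000,
) -> np.ndarray:
    """Mask of positions covered by exactly two parental contigs, eroded by
    ``margin`` bp so that contig-edge artefacts are excluded."""
    cov = haplotype_coverage(alignments, genome_length, min_contig_len)
    mask = (cov[1] == 1) & (cov[2] == 1)
    if margin > 0 and mask.any():
        kernel = np.ones(2 * margin + 1, dtype=np.int32)
        eroded = np.convolve(mask.astype(np.int32), kernel, "same") == len(kernel)
        mask = eroded
    return mask
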
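"""End-to-end orchestration of the four pipeline stages.

Stage 1 (haplotyping + partitioning): molecule reconstruction, variant
pruning, parity-based clustering, phase blocks, coverage/uniqueness
profiles, partitioning points and assembly chunks.  Stage 2 (local
assembly + concatenation): per-chunk assembly and minicontig stitching.
Stage 3/4 (variation): contig alignment, candidate extraction, zygosity,
merging with the read-based callset, phasing and VCF output.

All stage boundaries are plain data; :func:`run_pipeline` chains them in
memory, while the CLI wraps the same functions around files.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import assembly as asm
from . import contiguity as cg
from . import fragments as fr
from . import haplotyping as hap
from . import variation as var
from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class Step1Result:
    molecules: list[fr.Molecule]
    kept_variants: list[fr.HetVariant]
    blocks: list[hap.PhaseBlock]
    assignments: dict[int, tuple[int, int]]
    profile: cg.CoverageProfile
    points: np.ndarray
    chunks: list[cg.AssemblyChunk]


@dataclass(slots=True)
class Step2Result:
    stitched: list[cg.StitchedContig]
    records: list[tuple[str, str]]  # (header, sequence)
    block_spans: dict[int, tuple[int, int]]


@dataclass(slots=True)
class VarcallResult:
    alignments: list[var.ContigAlignment]
    candidates: dict[int, list[var.VariantCandidate]]
    final_variants: list[var.FinalVariant]


@dataclass(slots=True)
class PipelineResult:
    step1: Step1Result
    step2: Step2Result
    varcall: VarcallResult


def block_ownership_spans(
    blocks: list[hap.PhaseBlock], genome_length: int
) -> dict[int, tuple[int, int]]:
    """Partition the chromosome among blocks (midpoints between block spans).

    Boundary chunks are extended to these ownership limits so assembly
    coverage does not stop at the outermost phased variant.
    """
    spans: dict[int, tuple[int, int]] = {}
    ordered = sorted(blocks, key=lambda b: b.span[0])
    for i, b in enumerate(ordered):
        left = 0 if i == 0 else (ordered[i - 1].span[1] + b.span[0]) // 2
        right = genome_length if i == len(ordered) - 1 else (b.span[1] + ordered[i + 1].span[0]) // 2
        spans[b.block_id] = (left, right)
    return spans


def run_step1(
    alignments: list[fr.ReadAlignment],
    het_variants: list[fr.HetVariant],
    ref_seq: str,
    cfg: RunConfig | None = None,
) -> Step1Result:
    cfg = cfg or RunConfig()
    molecules = fr.reconstruct_fragments(alignments, split_gap=cfg.split_gap,
                                         min_mapq=cfg.min_mapq_reads)
    for m in molecules:
        fr.assign_alleles(m)
    prune_cfg = hap.PruneConfig(
        min_alt_fraction=cfg.min_alt_fraction,
        coverage_low_pct=cfg.coverage_low_pct,
        coverage_high_pct=cfg.coverage_high_pct,
        min_qual=cfg.min_snp_qual,
    )
    blocks, assignments, kept = hap.phase_molecules(
        molecules, het_variants, prune_cfg,
        merge_support=cfg.merge_support,
        overlap_support=cfg.overlap_support,
        alpha=cfg.alpha,
    )
    profile = cg.compute_profiles(alignments, molecules, len(ref_seq))
    uniq = cg.compute_uniqueness(ref_seq, k=cfg.k_uniq)
    points = cg.select_partitioning_points(profile, uniq, factor=cfg.factor)
    own = block_ownership_spans(blocks, len(ref_seq))
    chunks: list[cg.AssemblyChunk] = []
    for b in blocks:
        chunks.extend(cg.cut_phase_block(
            b, points,
            block_threshold=cfg.block_threshold,
            chunk_len=cfg.chunk_len,
            search_window=cfg.search_window,
            span=own[b.block_id],
        ))
    return Step1Result(molecules=molecules, kept_variants=kept, blocks=blocks,
                       assignments=assignments, profile=profile, points=points,
                       chunks=chunks)


def run_step2(step1: Step1Result, ref_seq: str, cfg: RunConfig | None = None) -> Step2Result:
    cfg = cfg or RunConfig()
    chunk_reads = asm.partition_reads(step1.chunks, step1.molecules, step1.assignments)
    minicontigs: dict[tuple[int, int], dict[tuple[int, int], list[str]]] = defaultdict(dict)
    for idx, ch in enumerate(step1.chunks):
        reads = chunk_reads.get(idx, [])
        seqs = asm.assemble_chunk(
            reads, backend=cfg.assembler_backend, k=cfg.assembler_k,
            min_count=cfg.assembler_min_kmer_count, external_cmd=cfg.external_cmd)
        minicontigs[(ch.block_id, ch.haplotype)][ch.interval] = seqs
    stitched: list[cg.StitchedContig] = []
    for (bid, hp), per_chunk in sorted(minicontigs.items()):
        order = sorted(per_chunk)
        group = cg.stitch_minicontigs(
            per_chunk, order, ref_seq, bid, hp, anchor_k=cfg.anchor_k)
        stitched.extend(cg.consolidate_contigs(group, anchor_k=cfg.anchor_k))
    block_spans = {b.block_id: b.span for b in step1.blocks}
    records = asm.name_contigs(stitched, block_spans)
    return Step2Result(stitched=stitched, records=records, block_spans=block_spans)


def run_varcall_and_phase(
    step1: Step1Result,
    step2: Step2Result,
    ref_seq: str,
    chrom: str,
    read_based: list[tuple[str, int, str, str, str]] | None = None,
    cfg: RunConfig | None = None,
) -> VarcallResult:
    cfg = cfg or RunConfig()
    alignments: list[var.ContigAlignment] = []
    placed: list[bool] = []
    for (header, seq), contig in zip(step2.records, step2.stitched):
        if len(seq) <= cfg.min_contig_len:
            continue
        if contig.chunks:
            lo = min(s for s, _ in contig.chunks)
            hi = max(e for _, e in contig.chunks)
            region = (max(0, lo - cfg.align_pad), min(len(ref_seq), hi + cfg.align_pad))
        else:
            region = None
        aln = var.align_contig(header, seq, ref_seq, chrom, region=region)
        if aln is not None:
            aln.name = asm.parse_contig_header(header)
            alignments.append(aln)
            placed.append(bool(contig.chunks))
    # purge redundant unplaced pieces: a leftover fragment whose reference
    # interval a placed contig of the same haplotype already covers is a
    # duplicate haplotig (typically built from both-haplotype reads of
    # unassigned molecules) and would distort the diploid assembly
    placed_ivs: dict[int, list[tuple[int, int]]] = {1: [], 2: []}
    for aln, is_placed in zip(alignments, placed):
        if is_placed:
            placed_ivs[aln.name.haplotype].append((aln.t_start, aln.t_end))
    alignments = [
        aln for aln, is_placed in zip(alignments, placed)
        if is_placed or not any(s <= aln.t_start and aln.t_end <= e
                                for s, e in placed_ivs[aln.name.haplotype])
    ]
    candidates = var.extract_variants(alignments, ref_seq,
                                      min_contig_len=cfg.min_contig_len,
                                      min_mapq=cfg.min_mapq)
    for hp in (1, 2):
        seen: set[tuple[int, str, str]] = set()
        uniq_c: list[var.VariantCandidate] = []
        for c in candidates[hp]:
            key = (c.pos, c.ref, c.alt)
            if key not in seen:
                seen.add(key)
                uniq_c.append(c)
        candidates[hp] = sorted(uniq_c, key=lambda c: c.pos)
    coverage = {h: var._coverage_intervals(alignments, cfg.min_contig_len, cfg.min_mapq, h)
                for h in (1, 2)}
    snps = {h: [c for c in candidates[h] if c.vtype == "SNP"] for h in (1, 2)}
    indels = {h: [c for c in candidates[h] if c.vtype != "SNP"] for h in (1, 2)}
    finals = var.infer_snp_zygosity(snps[1], snps[2], coverage)
    finals += var.infer_indel_sv_zygosity(indels[1], indels[2], coverage,
                                          ins_bp_tol=cfg.ins_tol)
    if read_based:
        finals = var.merge_snp_calls(finals, read_based)
    var_pos = {v.variant_id: v.pos for v in step1.kept_variants}
    finals = var.phase_variants(finals, step1.blocks, var_pos)
    finals.sort(key=lambda v: v.pos)
    return VarcallResult(alignments=alignments, candidates=candidates,
                         final_variants=finals)


def run_pipeline(
    alignments: list[fr.ReadAlignment],
    het_variants: list[fr.HetVariant],
    ref_seq: str,
    chrom: str,
    read_based: list[tuple[str, int, str, str, str]] | None = None,
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Run haplotyping, assembly and variant calling end to end in memory."""
    cfg = cfg or RunConfig()
    step1 = run_step1(alignments, het_variants, ref_seq, cfg)
    logger.info("step1: %d molecules, %d blocks, %d chunks",
                len(step1.molecules), len(step1.blocks), len(step1.chunks))
    step2 = run_step2(step1, ref_seq, cfg)
    logger.info("step2: %d contigs", len(step2.records))
    vc = run_varcall_and_phase(step1, step2, ref_seq, chrom, read_based, cfg)
    n_het = sum(v.genotype == "het" for v in vc.final_variants)
    n_hom = len(vc.final_variants) - n_het
    n_phased = sum(v.phase is not None for v in vc.final_variants)
    logger.info("varcall: %d variants (%d het / %d hom), %d phased",
                len(vc.final_variants), n_het, n_hom, n_phased)
    return PipelineResult(step1=step1, step2=step2, varcall=vc)


def write_manifest(path, cfg: RunConfig, counts: dict[str, int]) -> None:
    from dataclasses import asdict

    payload = {"config": asdict(cfg), "counts": dict(sorted(counts.items()))}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
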
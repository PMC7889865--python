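"""File-level readers connecting the pipeline to standard formats."""

from __future__ import annotations

import numpy as np
import pysam

from .fragments import HetVariant, ReadAlignment


def read_reference(path) -> dict[str, str]:
    """Load a FASTA reference as chrom -> sequence."""
    from .assembly import read_fasta

    return dict(read_fasta(path))


def read_het_vcf(path) -> list[HetVariant]:
    """Read a het-SNP callset (VCF) with depth (DP) and alt-count (AO) INFO."""
    out: list[HetVariant] = []
    vf = pysam.VariantFile(path)
    for i, rec in enumerate(vf):
        if len(rec.alts or ()) != 1:
            continue
        info = rec.info
        dp = int(info.get("DP", 0) or 0)
        ao = info.get("AO", 0)
        if isinstance(ao, tuple):
            ao = ao[0]
        out.append(HetVariant(
            variant_id=i, chrom=rec.chrom, pos=rec.pos,
            ref_allele=rec.ref, alt_allele=rec.alts[0],
            qual=float(rec.qual or 0.0), depth=dp, alt_count=int(ao or 0)))
    return out


def write_het_vcf(path, variants: list[HetVariant], chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt observations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t"
                     f"{v.qual:g}\tPASS\tDP={v.depth};AO={v.alt_count}\tGT\t0/1\n")


def read_alignments_sam(path, het_variants: list[HetVariant]) -> list[ReadAlignment]:
    """Load barcoded alignments from SAM/BAM and call het-site alleles per read.

    The barcode is taken from the BX tag, falling back to a ``_BX:...``
    suffix in the read name.  For each het site covered by a read, the
    aligned base is compared against the ref/alt alleles; non-allelic bases
    are skipped.  Returns records sorted by (barcode, chrom, start).
    """
    sites_by_chrom: dict[str, tuple[np.ndarray, list[HetVariant]]] = {}
    for chrom in {v.chrom for v in het_variants}:
        vs = sorted((v for v in het_variants if v.chrom == chrom), key=lambda v: v.pos)
        sites_by_chrom[chrom] = (np.array([v.pos - 1 for v in vs], dtype=np.int64), vs)
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            if rec.has_tag("BX"):
                barcode = rec.get_tag("BX")
            elif "_BX:" in rec.query_name:
                barcode = rec.query_name.rsplit("_BX:", 1)[1]
            else:
                continue
            calls: dict[int, tuple[int, int]] = {}
            entry = sites_by_chrom.get(rec.reference_name)
            if entry is not None:
                pos0, vs = entry
                lo = int(np.searchsorted(pos0, rec.reference_start))
                hi = int(np.searchsorted(pos0, rec.reference_end))
                if hi > lo:
                    ref2q = {rp: qp for qp, rp in rec.get_aligned_pairs(matches_only=True)}
                    quals = rec.query_qualities
                    for si in range(lo, hi):
                        qp = ref2q.get(int(pos0[si]))
                        if qp is None:
                            continue
                        base = rec.query_sequence[qp]
                        v = vs[si]
                        if base == v.alt_allele:
                            allele = 1
                        elif base == v.ref_allele:
                            allele = 0
                        else:
                            continue
                        q = int(quals[qp]) if quals is not None else 30
                        calls[v.variant_id] = (allele, q)
            out.append(ReadAlignment(
                read_id=rec.query_name, barcode=barcode, chrom=rec.reference_name,
                start=rec.reference_start, end=rec.reference_end,
                mapq=rec.mapping_quality, base_calls=calls,
                seq=rec.query_sequence,
                quals=(rec.qual if rec.qual else None)))
    out.sort(key=lambda r: (r.barcode, r.chrom, r.start))
    return out


def write_phase_block_vcf(path, blocks, variants: list[HetVariant]) -> None:
    """Write the phased het-SNP scaffold (GT a|b with PS = block start)."""
    by_id = {v.variant_id: v for v in variants}
    rows = []
    for b in blocks:
        for vid, allele in b.variants.items():
            v = by_id[vid]
            gt = f"{allele}|{1 - allele}"
            rows.append((v.chrom, v.pos, v.ref_allele, v.alt_allele, gt, b.block_id))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({r[0] for r in rows}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for chrom, pos, ref, alt, gt, ps in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\t.\tGT:PS\t{gt}:{ps}\n")
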
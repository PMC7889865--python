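"""Candidate extraction, zygosity inference, merging, phasing and VCF I/O."""

import pytest

from phasembly.haplotyping import PhaseBlock
from phasembly.sim import random_sequence
from phasembly.variation import (
    FinalVariant,
    ReferenceMismatchError,
    VariantCandidate,
    align_contig,
    extract_variants,
    infer_indel_sv_zygosity,
    infer_snp_zygosity,
    left_align,
    merge_snp_calls,
    parse_extended_cigar,
    phase_variants,
    read_paf,
    read_vcf_simple,
    write_vcf,
)


def make_alignment(contig_seq, ref_seq, hp=1, contig_id=None, mapq=60):
    aln = align_contig(contig_id or f"1_PS1:{len(ref_seq)}_hp{hp}", contig_seq, ref_seq, "c",
                       mapq=mapq)
    return aln


class TestExtract:
    def test_short_contig_contributes_nothing(self, rng):
        ref = random_sequence(rng, 2_000)
        aln = make_alignment(ref[100:1_000], ref)  # 900 bp contig
        assert extract_variants([aln], ref) == {1: [], 2: []}

    def test_low_mapq_alignment_skipped(self, rng):
        ref = random_sequence(rng, 3_000)
        contig = ref[100:1_500]
        aln = make_alignment(contig, ref, mapq=19)
        assert extract_variants([aln], ref) == {1: [], 2: []}

    def test_single_substitution_recovered(self, rng):
        ref = random_sequence(rng, 3_000)
        off = 700
        sub = "A" if ref[100 + off] != "A" else "C"
        contig = ref[100:100 + off] + sub + ref[100 + off + 1:1_900]
        aln = make_alignment(contig, ref)
        cands = extract_variants([aln], ref)[1]
        assert len(cands) == 1
        c = cands[0]
        assert (c.pos, c.ref, c.alt, c.vtype) == (100 + off + 1, ref[100 + off], sub, "SNP")

    def test_insertion_left_aligned(self, rng):
        # insertion of "TT" immediately left of a TT run must shift to the
        # run's leftmost anchor
        core = random_sequence(rng, 1_000)
        ref = core + "GCTGGTTCGT" + random_sequence(rng, 1_000)
        hap = core + "GCTGGTTTTCGT" + ref[len(core) + 10:]
        aln = make_alignment(hap[:1_800], ref)
        cands = [c for c in extract_variants([aln], ref)[1] if c.vtype == "INS"]
        assert len(cands) == 1
        c = cands[0]
        assert (c.pos, c.ref, c.alt) == (len(core) + 5, "G", "GTT")

    def test_deletion_recovered_with_size(self, rng):
        ref = random_sequence(rng, 3_000)
        contig = ref[100:1_200] + ref[1_500:2_500]  # 300 bp deletion
        aln = make_alignment(contig, ref)
        cands = [c for c in extract_variants([aln], ref)[1] if c.vtype == "DEL"]
        assert len(cands) == 1
        assert cands[0].size == 300
        # left-aligned exact representation reproduces the haplotype
        c = cands[0]
        rebuilt = ref[:c.pos - 1] + c.alt + ref[c.pos - 1 + len(c.ref):]
        assert rebuilt == ref[:100] + contig + ref[2_500:]

    def test_malformed_cigar_reports_offset(self):
        with pytest.raises(ValueError, match="offset"):
            parse_extended_cigar("10=xx3I")

    def test_paf_cs_parsing(self, tmp_path, rng):
        ref = random_sequence(rng, 2_000)
        paf = tmp_path / "aln.paf"
        # 500= *(sub) 499= -3bp 498=
        row = ["5_PS1:2000_hp2", "1500", "0", "1500", "+", "c", "2000", "100", "1603",
               "1497", "1500", "60", "cs:Z::500*ag:499-acg:498"]
        paf.write_text("\t".join(row) + "\n")
        alns = read_paf(paf, {"c": ref})
        assert len(alns) == 1
        assert [op for op, _ in alns[0].ops] == ["=", "X", "=", "D", "="]

    def test_left_align_rotation(self):
        ref = "GGGCACACACTT"
        # delete the "CA" unit at 0-based [5, 7): anchored form (5, "ACA", "A")
        cand = VariantCandidate(1, "c", 5, "ACA", "A")
        norm = left_align(cand, ref)
        assert (norm.pos, norm.ref, norm.alt) == (3, "GCA", "G")
        # the normalised event reproduces the same haplotype
        for c in (cand, norm):
            assert ref[:c.pos - 1] + c.alt + ref[c.pos - 1 + len(c.ref):] == "GGGCACACTT"


class TestSnpZygosity:
    COV = {1: [(0, 10_000)], 2: [(0, 10_000)]}

    def test_same_alt_on_both_haplotypes_is_hom(self):
        c1 = VariantCandidate(1, "c", 500, "A", "G")
        c2 = VariantCandidate(2, "c", 500, "A", "G")
        out = infer_snp_zygosity([c1], [c2], self.COV)
        assert [(v.genotype, v.alt) for v in out] == [("hom", "G")]

    def test_alt_on_one_with_ref_coverage_is_het(self):
        c1 = VariantCandidate(1, "c", 500, "A", "G")
        out = infer_snp_zygosity([c1], [], self.COV)
        assert out[0].genotype == "het"
        assert "low_confidence" not in out[0].flags

    def test_alt_on_one_without_coverage_flagged(self):
        c1 = VariantCandidate(1, "c", 500, "A", "G")
        out = infer_snp_zygosity([c1], [], {1: [(0, 10_000)], 2: []})
        assert "low_confidence" in out[0].flags

    def test_conflicting_alts_two_het_records(self):
        c1 = VariantCandidate(1, "c", 500, "A", "G")
        c2 = VariantCandidate(2, "c", 500, "A", "T")
        out = infer_snp_zygosity([c1], [c2], self.COV)
        assert len(out) == 2
        assert all(v.genotype == "het" and "multiallelic" in v.flags for v in out)


class TestIndelZygosity:
    COV = {1: [(0, 100_000)], 2: [(0, 100_000)]}

    def test_insertions_within_20bp_merge_to_hom(self):
        a = VariantCandidate(1, "c", 1_000, "A", "A" + "G" * 60)
        b = VariantCandidate(2, "c", 1_015, "T", "T" + "G" * 60)
        out = infer_indel_sv_zygosity([a], [b], self.COV)
        assert [v.genotype for v in out] == ["hom"]

    def test_insertions_beyond_20bp_stay_het(self):
        a = VariantCandidate(1, "c", 1_000, "A", "A" + "G" * 60)
        b = VariantCandidate(2, "c", 1_025, "T", "T" + "G" * 60)
        out = infer_indel_sv_zygosity([a], [b], self.COV)
        assert sorted(v.genotype for v in out) == ["het", "het"]

    def test_overlapping_deletions_merge(self):
        a = VariantCandidate(1, "c", 100, "N" + "A" * 200, "N")
        b = VariantCandidate(2, "c", 250, "N" + "A" * 250, "N")
        out = infer_indel_sv_zygosity([a], [b], self.COV)
        assert [v.genotype for v in out] == ["hom"]

    def test_non_overlapping_deletions_stay_separate(self):
        a = VariantCandidate(1, "c", 100, "N" + "A" * 50, "N")
        b = VariantCandidate(2, "c", 500, "N" + "A" * 50, "N")
        out = infer_indel_sv_zygosity([a], [b], self.COV)
        assert len(out) == 2


class TestMergeSnpCalls:
    def test_assembly_only_site_kept(self):
        v = FinalVariant("c", 100, "A", "G", "het")
        out = merge_snp_calls([v], [("c", 200, "T", "C", "het")])
        assert {(x.pos, x.source) for x in out} == {(100, "assembly"), (200, "read_based")}

    def test_site_in_both_marked_both(self):
        v = FinalVariant("c", 100, "A", "G", "het")
        out = merge_snp_calls([v], [("c", 100, "A", "G", "het")])
        assert out[0].source == "both"

    def test_genotype_conflict_prefers_read_based(self):
        v = FinalVariant("c", 100, "A", "G", "hom")
        out = merge_snp_calls([v], [("c", 100, "A", "G", "het")])
        assert out[0].genotype == "het"
        assert any(f.startswith("assembly_call=") for f in out[0].flags)

    def test_reference_mismatch_raises(self):
        v = FinalVariant("c", 100, "A", "G", "het")
        with pytest.raises(ReferenceMismatchError):
            merge_snp_calls([v], [("c", 100, "T", "G", "het")])


class TestPhaseVariants:
    def blocks(self):
        # scaffold: positions 100..900, hap1 carries the alt everywhere
        return [PhaseBlock(100, {i: 1 for i in range(9)}, {}, (100, 900))]

    def var_pos(self):
        return {i: (i + 1) * 100 for i in range(9)}

    def test_unanimous_vote_phases_sv(self):
        finals = [FinalVariant("c", (i + 1) * 100, "A", "G", "het", haplotype=1)
                  for i in range(5)]
        sv = FinalVariant("c", 550, "N" + "A" * 60, "N", "het", haplotype=1)
        out = phase_variants(finals + [sv], self.blocks(), self.var_pos())
        assert sv.phase == (1, 0, 100)

    def test_tied_vote_leaves_unphased(self):
        finals = [FinalVariant("c", (i + 1) * 100, "A", "G", "het", haplotype=1 + i % 2)
                  for i in range(4)]
        sv = FinalVariant("c", 550, "N" + "A" * 60, "N", "het", haplotype=1)
        out = phase_variants(finals + [sv], self.blocks(), self.var_pos())
        assert sv.phase is None

    def test_crossed_labels_oriented_by_vote(self):
        # contig hp2 carries the alts the scaffold puts on hap1
        finals = [FinalVariant("c", (i + 1) * 100, "A", "G", "het", haplotype=2)
                  for i in range(5)]
        out = phase_variants(finals, self.blocks(), self.var_pos())
        assert all(v.phase == (1, 0, 100) for v in out)

    def test_hom_phased_as_1_1(self):
        v = FinalVariant("c", 550, "A", "G", "hom")
        phase_variants([v], self.blocks(), self.var_pos())
        assert v.phase == (1, 1, 0)

    def test_read_based_het_snp_phased_from_scaffold(self):
        v = FinalVariant("c", 300, "A", "G", "het", source="read_based")
        phase_variants([v], self.blocks(), self.var_pos())
        assert v.phase == (1, 0, 100)


class TestVcf:
    def test_round_trip_through_pysam(self, tmp_path):
        import pysam
        variants = [
            FinalVariant("c", 100, "A", "G", "het", phase=(1, 0, 100)),
            FinalVariant("c", 200, "T", "C", "hom"),
            FinalVariant("c", 300, "G", "GA", "het"),
        ]
        path = tmp_path / "out.vcf"
        write_vcf(path, variants, {"c": 10_000})
        with pysam.VariantFile(str(path)) as fh:
            recs = list(fh)
        assert len(recs) == 3
        s0 = recs[0].samples[0]
        assert s0["GT"] == (1, 0) and s0.phased and s0["PS"] == 100
        assert recs[1].samples[0]["GT"] == (1, 1)
        assert not recs[2].samples[0].phased
        rows = read_vcf_simple(path)
        assert [(r[1], r[4]) for r in rows] == [(100, "het"), (200, "hom"), (300, "het")]

    def test_unsorted_variants_rejected(self, tmp_path):
        variants = [FinalVariant("c", 200, "T", "C", "hom"),
                    FinalVariant("c", 100, "A", "G", "het")]
        with pytest.raises(ValueError, match="sorted"):
            write_vcf(tmp_path / "bad.vcf", variants, {"c": 1_000})
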
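"""Coverage profiles, k-mer uniqueness, partitioning points and stitching."""

import numpy as np

from phasembly.contiguity import (
    compute_profiles,
    compute_uniqueness,
    consolidate_contigs,
    cut_phase_block,
    select_partitioning_points,
    stitch_minicontigs,
    StitchedContig,
    uniqueness_from_bed,
)
from phasembly.fragments import Molecule, ReadAlignment
from phasembly.haplotyping import PhaseBlock
from phasembly.sim import random_sequence


def read(rid, start, end, barcode="BX1"):
    return ReadAlignment(read_id=rid, barcode=barcode, chrom="c", start=start, end=end)


class TestProfiles:
    def test_half_open_convention(self):
        p = compute_profiles([read("a", 10, 20)], [], 30)
        assert p.c[9] == 0 and p.c[10] == 1 and p.c[19] == 1 and p.c[20] == 0

    def test_fragment_depth_counts_molecules(self):
        m = Molecule(0, "BX1", "c", 0, 1000)
        p = compute_profiles([read("a", 0, 100), read("b", 800, 900)], [m], 1000)
        assert p.c_f[500] == 1
        assert p.c[500] == 0

    def test_matches_naive_counting_oracle(self, rng):
        L = 300
        reads = []
        mols = []
        for i in range(40):
            s = int(rng.integers(0, L - 10))
            e = s + int(rng.integers(1, 50))
            reads.append(read(f"r{i}", s, min(e, L)))
            mols.append(Molecule(i, "BX", "c", s, min(e + 20, L)))
        p = compute_profiles(reads, mols, L)
        naive_c = np.zeros(L)
        naive_f = np.zeros(L)
        for pos in range(L):
            naive_c[pos] = sum(r.start <= pos < r.end for r in reads)
            naive_f[pos] = sum(m.start <= pos < m.end for m in mols)
        assert np.array_equal(p.c, naive_c)
        assert np.array_equal(p.c_f, naive_f)

    def test_empty_inputs_zero_profile(self):
        p = compute_profiles([], [], 100)
        assert p.c.sum() == 0 and p.c_f.sum() == 0 and p.c_avg == 0.0


class TestUniqueness:
    def test_random_sequence_mostly_unique(self, rng):
        seq = random_sequence(rng, 10_000)
        track = compute_uniqueness(seq, k=100)
        assert track.mask.mean() >= 0.99

    def test_duplicated_segment_not_unique(self, rng):
        core = random_sequence(rng, 2_000)
        seq = random_sequence(rng, 3_000) + core + random_sequence(rng, 500) + core
        track = compute_uniqueness(seq, k=100)
        first = slice(3_000, 3_000 + 2_000 - 100 + 1)
        assert not track.mask[first].any()

    def test_homopolymer_has_no_unique_positions(self):
        track = compute_uniqueness("A" * 500, k=100)
        assert not track.mask.any()

    def test_k_exceeding_length_gives_empty_track(self):
        assert len(compute_uniqueness("ACGT", k=100).mask) == 0

    def test_reverse_complement_collision_breaks_uniqueness(self, rng):
        from phasembly.sim import revcomp
        core = random_sequence(rng, 300)
        seq = random_sequence(rng, 1000) + core + random_sequence(rng, 400) + revcomp(core)
        track = compute_uniqueness(seq, k=100)
        assert not track.mask[1000 : 1000 + 300 - 100 + 1].any()

    def test_bed_reader_roundtrip(self, tmp_path, rng):
        seq = random_sequence(rng, 2_000)
        track = compute_uniqueness(seq, k=100)
        bed = tmp_path / "uniq.bed"
        with open(bed, "w") as fh:
            start = None
            for i, v in enumerate(track.mask):
                if v and start is None:
                    start = i
                elif not v and start is not None:
                    fh.write(f"c\t{start}\t{i}\n")
                    start = None
            if start is not None:
                fh.write(f"c\t{start}\t{len(track.mask)}\n")
        loaded = uniqueness_from_bed(bed, 2_000, k=100)
        assert np.array_equal(loaded.mask, track.mask)


class TestPartitioningPoints:
    def make_profile(self, c, c_f):
        from phasembly.contiguity import CoverageProfile
        return CoverageProfile(c=np.asarray(c), c_f=np.asarray(c_f),
                               c_avg=float(np.mean([x for x in c if x > 0])),
                               c_f_avg=float(np.mean([x for x in c_f if x > 0])))

    def test_all_three_criteria_required(self, rng):
        from phasembly.contiguity import UniquenessTrack
        n = 100
        c = np.full(n, 10.0)
        c_f = np.full(n, 10.0)
        c[5] = 7.0   # 0.7 * avg -> excluded
        c[6] = 9.0   # 0.9 * avg, kept if unique
        mask = np.ones(n, dtype=bool)
        mask[7] = False
        profile = self.make_profile(c, c_f)
        uniq = UniquenessTrack(k=100, length=n + 99, mask=mask)
        pts = select_partitioning_points(profile, uniq)
        assert 6 in pts and 5 not in pts and 7 not in pts

    def test_matches_bruteforce_filter(self, rng):
        from phasembly.contiguity import UniquenessTrack
        n = 500
        c = rng.integers(0, 20, n).astype(float)
        c_f = rng.integers(0, 30, n).astype(float)
        mask = rng.random(n) < 0.7
        profile = self.make_profile(c, c_f)
        uniq = UniquenessTrack(k=100, length=n + 99, mask=mask)
        got = set(select_partitioning_points(profile, uniq).tolist())
        want = {i for i in range(n)
                if c[i] > 0.8 * profile.c_avg and c_f[i] > 0.8 * profile.c_f_avg and mask[i]}
        assert got == want


def block(span):
    return PhaseBlock(block_id=span[0], variants={0: 0, 1: 1}, molecules={}, span=span)


class TestCutPhaseBlock:
    def test_small_block_single_chunk_per_haplotype(self):
        chunks = cut_phase_block(block((0, 150_000)), np.arange(0, 150_000, 50))
        assert len(chunks) == 2
        assert {c.haplotype for c in chunks} == {1, 2}
        assert all(c.interval == (0, 150_000) for c in chunks)

    def test_large_block_cut_into_chunk_len_pieces(self):
        chunks = cut_phase_block(block((0, 500_000)), np.arange(0, 500_000, 50))
        per_hap = [c for c in chunks if c.haplotype == 1]
        assert len(per_hap) == 5
        sizes = [c.end - c.start for c in per_hap]
        assert all(abs(s - 100_000) <= 20_000 for s in sizes)
        # tiling: neighbours share exactly the cut position
        for a, b in zip(per_hap, per_hap[1:]):
            assert a.end == b.start

    def test_no_points_fallback_single_chunk(self):
        chunks = cut_phase_block(block((0, 500_000)), np.array([], dtype=int))
        assert len(chunks) == 2
        assert all(c.interval == (0, 500_000) for c in chunks)

    def test_cut_snaps_to_nearest_qualifying_point(self):
        points = np.array([95_000, 112_000, 201_000])
        chunks = cut_phase_block(block((0, 300_000)), points)
        per_hap = [c for c in chunks if c.haplotype == 1]
        assert [c.start for c in per_hap] == [0, 95_000, 201_000]

    def test_chunks_tile_block_span(self):
        chunks = cut_phase_block(block((10_000, 450_000)), np.arange(0, 450_000, 100))
        per_hap = sorted((c for c in chunks if c.haplotype == 2), key=lambda c: c.start)
        assert per_hap[0].start == 10_000 and per_hap[-1].end == 450_000
        assert per_hap[0].is_block_start and per_hap[-1].is_block_end


class TestStitching:
    def test_two_pieces_spliced_at_anchor(self, rng):
        ref = random_sequence(rng, 3_000)
        left, right = ref[0:1_600], ref[1_500:3_000]
        out = stitch_minicontigs({(0, 1500): [left], (1500, 3000): [right]},
                                 [(0, 1500), (1500, 3000)], ref, block_id=1, haplotype=1)
        assert len(out) == 1
        assert out[0].sequence == ref
        assert out[0].chunks == [(0, 1500), (1500, 3000)]

    def test_missing_anchor_keeps_pieces_separate(self, rng):
        ref = random_sequence(rng, 6_000)
        left, right = ref[0:1_550], ref[3_800:6_000]  # no shared anchor window
        out = stitch_minicontigs({(0, 1500): [left], (1500, 6000): [right]},
                                 [(0, 1500), (1500, 6000)], ref, block_id=1, haplotype=1)
        assert len(out) == 2

    def test_three_chunk_chain_concatenates_iteratively(self, rng):
        ref = random_sequence(rng, 5_000)
        pieces = {(0, 2000): [ref[0:2_100]], (2000, 4000): [ref[1_900:4_100]],
                  (4000, 5000): [ref[3_900:5_000]]}
        out = stitch_minicontigs(pieces, sorted(pieces), ref, 1, 2)
        assert len(out) == 1
        assert out[0].sequence == ref

    def test_variant_at_point_recovered_via_search_margin(self, rng):
        # a substitution right at the cut point breaks the point anchor; the
        # stitcher must find a variant-free anchor window further right
        ref = random_sequence(rng, 4_000)
        hap = ref[:2_050] + ("A" if ref[2_050] != "A" else "C") + ref[2_051:]
        left, right = hap[0:2_300], hap[1_800:4_000]
        out = stitch_minicontigs({(0, 2000): [left], (2000, 4000): [right]},
                                 [(0, 2000), (2000, 4000)], ref, 1, 1)
        assert len(out) == 1
        assert out[0].sequence == hap

    def test_duplicate_leftover_pieces_dropped(self, rng):
        ref = random_sequence(rng, 3_000)
        out = stitch_minicontigs(
            {(0, 1500): [ref[0:1_600], ref[200:900]], (1500, 3000): [ref[1_500:3_000]]},
            [(0, 1500), (1500, 3000)], ref, 1, 1)
        assert len(out) == 1  # the contained fragment is not re-emitted


class TestConsolidate:
    def test_overlapping_pieces_merge(self, rng):
        ref = random_sequence(rng, 5_000)
        a = StitchedContig(ref[0:2_200], 1, 1, [(0, 2000)])
        b = StitchedContig(ref[2_000:5_000], 1, 1, [])
        out = consolidate_contigs([a, b])
        assert len(out) == 1
        assert out[0].sequence == ref
        assert out[0].chunks == [(0, 2000)]

    def test_disjoint_pieces_stay_separate(self, rng):
        ref = random_sequence(rng, 5_000)
        a = StitchedContig(ref[0:2_000], 1, 1, [])
        b = StitchedContig(ref[2_500:5_000], 1, 1, [])
        assert len(consolidate_contigs([a, b])) == 2

    def test_mismatching_overlap_not_merged(self, rng):
        # head anchor matches but the rest of the claimed overlap does not
        ref = random_sequence(rng, 4_000)
        altered = ref[1_800:1_900] + random_sequence(rng, 1_000)
        a = StitchedContig(ref[0:2_100], 1, 1, [])
        b = StitchedContig(altered, 1, 1, [])
        assert len(consolidate_contigs([a, b])) == 2
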
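"""Partitioning-point selection and minicontig stitching.

Large phase blocks are cut into ~100 kb assembly chunks at "high-confidence
partitioning points": positions with near-average read coverage, near-average
physical (fragment) coverage, and a 100-mer unique in the reference on both
strands.  After per-chunk assembly, neighbouring minicontigs bounded by the
same partitioning point are spliced back together at the reference 100-mer
anchored at that point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fragments import Molecule, ReadAlignment
from .haplotyping import PhaseBlock

logger = logging.getLogger(__name__)

DEFAULT_UNIQ_K = 100
DEFAULT_COVERAGE_FACTOR = 0.8
DEFAULT_BLOCK_THRESHOLD = 200_000
DEFAULT_CHUNK_LEN = 100_000
DEFAULT_SEARCH_WINDOW = 20_000
DEFAULT_ANCHOR_K = 100
DEFAULT_SEARCH_MARGIN = 2000


@dataclass(slots=True)
class CoverageProfile:
    """Per-base read depth C and fragment depth C_F with covered-region averages."""

    c: np.ndarray
    c_f: np.ndarray
    c_avg: float
    c_f_avg: float


def compute_profiles(
    alignments: list[ReadAlignment],
    molecules: list[Molecule],
    chrom_length: int,
) -> CoverageProfile:
    """Count reads and molecules overlapping each position (half-open intervals)."""
    c = np.zeros(chrom_length + 1, dtype=np.int32)
    for a in alignments:
        c[min(a.start, chrom_length)] += 1
        c[min(a.end, chrom_length)] -= 1
    c = np.cumsum(c[:-1]).astype(np.int32)
    c_f = np.zeros(chrom_length + 1, dtype=np.int32)
    for m in molecules:
        c_f[min(m.start, chrom_length)] += 1
        c_f[min(m.end, chrom_length)] -= 1
    c_f = np.cumsum(c_f[:-1]).astype(np.int32)
    covered = c > 0
    covered_f = c_f > 0
    c_avg = float(c[covered].mean()) if covered.any() else 0.0
    c_f_avg = float(c_f[covered_f].mean()) if covered_f.any() else 0.0
    return CoverageProfile(c=c, c_f=c_f, c_avg=c_avg, c_f_avg=c_f_avg)


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling polynomial hashes (uint64, wraparound) of all k-mers."""
    r = np.uint64(0x9E3779B97F4A7C15)
    n = len(codes)
    vals = codes.astype(np.uint64) + np.uint64(1)
    rp = np.empty(n + 1, dtype=np.uint64)
    rp[0] = 1
    np.multiply.accumulate(np.full(n, r, dtype=np.uint64), out=rp[1:])
    # window hash = sum v[j] r^(i+k-1-j) over j in [i, i+k), via scaled prefix
    # sums; r is odd so it is invertible mod 2^64 and wraparound is harmless
    r_inv = pow(int(r), -1, 1 << 64)
    rp_inv = np.empty(n + 1, dtype=np.uint64)
    rp_inv[0] = 1
    np.multiply.accumulate(np.full(n, np.uint64(r_inv), dtype=np.uint64), out=rp_inv[1:])
    scaled = vals * rp_inv[1 : n + 1]
    np.cumsum(scaled, dtype=np.uint64, out=scaled)
    pref = np.concatenate(([np.uint64(0)], scaled))
    # hash of window [i, i+k) = (pref[i+k] - pref[i]) * r^(i+k)
    w = (pref[k:] - pref[:-k]) * rp[k:]
    return w


@dataclass(slots=True)
class UniquenessTrack:
    """Positions whose k-mer occurs exactly once in the reference and its
    reverse complement."""

    k: int
    length: int
    mask: np.ndarray  # bool over [0, length - k + 1)

    def __contains__(self, pos: int) -> bool:
        return 0 <= pos < len(self.mask) and bool(self.mask[pos])

    @property
    def positions(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def compute_uniqueness(ref_seq: str, k: int = DEFAULT_UNIQ_K) -> UniquenessTrack:
    """Mark positions whose k-mer is unique across both strands of the reference."""
    n = len(ref_seq)
    if k > n:
        return UniquenessTrack(k=k, length=n, mask=np.zeros(0, dtype=bool))
    codes = _CODE[np.frombuffer(ref_seq.encode(), dtype=np.uint8)]
    valid = codes != 255
    fwd = _kmer_hashes(np.where(valid, codes, 0), k)
    rc_codes = _COMP_CODE[np.where(valid, codes, 0)][::-1]
    rev = _kmer_hashes(rc_codes, k)
    all_h = np.concatenate([fwd, rev])
    uniq, counts = np.unique(all_h, return_counts=True)
    count_of = dict(zip(uniq.tolist(), counts.tolist()))
    mask = np.fromiter((count_of[h] == 1 for h in fwd.tolist()), dtype=bool, count=len(fwd))
    # windows containing non-ACGT bases are never unique
    ok = np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    mask &= ok
    return UniquenessTrack(k=k, length=n, mask=mask)


def uniqueness_from_bed(path, length: int, k: int = DEFAULT_UNIQ_K) -> UniquenessTrack:
    """Load a precomputed uniqueness track from BED intervals of unique starts."""
    mask = np.zeros(max(length - k + 1, 0), dtype=bool)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            s, e = int(fields[1]), int(fields[2])
            mask[s : min(e, len(mask))] = True
    return UniquenessTrack(k=k, length=length, mask=mask)


def select_partitioning_points(
    profile: CoverageProfile,
    uniq: UniquenessTrack,
    factor: float = DEFAULT_COVERAGE_FACTOR,
) -> np.ndarray:
    """Positions passing all three criteria, sorted ascending.

    A position qualifies when C > factor * C_avg, C_F > factor * C_F_avg and
    its k-mer is unique (factor 0.8 by default).
    """
    n = len(uniq.mask)
    ok = (
        (profile.c[:n] > factor * profile.c_avg)
        & (profile.c_f[:n] > factor * profile.c_f_avg)
        & uniq.mask
    )
    return np.flatnonzero(ok)


@dataclass(slots=True)
class AssemblyChunk:
    """One per-haplotype local-assembly work unit inside a phase block."""

    block_id: int
    haplotype: int
    start: int
    end: int
    is_block_start: bool = False
    is_block_end: bool = False
    read_ids: list[str] = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def cut_phase_block(
    block: PhaseBlock,
    points: np.ndarray,
    block_threshold: int = DEFAULT_BLOCK_THRESHOLD,
    chunk_len: int = DEFAULT_CHUNK_LEN,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    span: tuple[int, int] | None = None,
) -> list[AssemblyChunk]:
    """Cut a phase block into per-haplotype assembly chunks.

    Blocks no longer than ``block_threshold`` (200 kb) become a single chunk
    per haplotype.  Longer blocks are cut at the qualifying partitioning
    point nearest each ideal multiple of ``chunk_len`` (100 kb), searching
    within +/- ``search_window``; when no point qualifies the boundary is
    skipped and the chunk simply grows.  Chunks tile the block, neighbouring
    chunks sharing exactly their cut position.
    """
    start, end = span if span is not None else block.span
    cuts: list[int] = []
    if end - start > block_threshold:
        points = np.asarray(points)
        ideal = start + chunk_len
        while ideal < end - chunk_len // 2:
            if len(points):
                i = int(np.searchsorted(points, ideal))
                cands = [j for j in (i - 1, i) if 0 <= j < len(points)]
                best = None
                for j in cands:
                    d = abs(int(points[j]) - ideal)
                    if d <= search_window and (best is None or d < best[0]):
                        best = (d, int(points[j]))
            else:
                best = None
            if best is not None and (not cuts or best[1] > cuts[-1]):
                cuts.append(best[1])
                ideal = best[1] + chunk_len
            else:
                logger.info("no qualifying partitioning point near %d; boundary skipped", ideal)
                ideal += chunk_len
    bounds = [start, *cuts, end]
    chunks = []
    for hp in (1, 2):
        for i in range(len(bounds) - 1):
            chunks.append(AssemblyChunk(
                block_id=block.block_id,
                haplotype=hp,
                start=bounds[i],
                end=bounds[i + 1],
                is_block_start=(i == 0),
                is_block_end=(i == len(bounds) - 2),
            ))
    return chunks


@dataclass(slots=True)
class StitchedContig:
    sequence: str
    block_id: int
    haplotype: int
    chunks: list[tuple[int, int]]  # constituent chunk intervals, left to right

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)


def _find_once(haystack: str, needle: str) -> int | None:
    i = haystack.find(needle)
    if i < 0:
        return None
    if haystack.find(needle, i + 1) >= 0:
        return None
    return i


def stitch_minicontigs(
    minicontigs: dict[tuple[int, int], list[str]],
    chunk_order: list[tuple[int, int]],
    ref_seq: str,
    block_id: int,
    haplotype: int,
    anchor_k: int = DEFAULT_ANCHOR_K,
    search_margin: int = DEFAULT_SEARCH_MARGIN,
) -> list[StitchedContig]:
    """Splice per-chunk minicontigs at shared partitioning points.

    ``minicontigs`` maps chunk interval -> assembled sequences for one
    (block, haplotype); ``chunk_order`` lists the intervals left to right.
    At each shared boundary point the reference ``anchor_k``-mer starting at
    the point must occur exactly once in one minicontig on each side: the
    stitched sequence is the left piece up to the anchor plus the right
    piece from the anchor on, and each concatenation feeds the next.  When a
    variant sits inside the anchor window the haplotype does not contain the
    reference k-mer, so anchor start positions up to ``search_margin`` bp
    right of the point are tried in turn.  Pieces that cannot be spliced are
    emitted as standalone contigs.
    """
    out: list[StitchedContig] = []
    cur_seq: str | None = None
    cur_chunks: list[tuple[int, int]] = []

    def flush():
        nonlocal cur_seq, cur_chunks
        if cur_seq is not None:
            out.append(StitchedContig(cur_seq, block_id, haplotype, cur_chunks))
        cur_seq, cur_chunks = None, []

    leftovers: list[str] = []
    for idx, interval in enumerate(chunk_order):
        pieces = sorted(minicontigs.get(interval, []), key=len, reverse=True)
        if not pieces:
            flush()
            continue
        if cur_seq is None:
            cur_seq = pieces[0]
            cur_chunks = [interval]
            leftovers.extend(pieces[1:])
            continue
        point = interval[0]
        spliced = False
        for delta in range(0, search_margin, 13):
            anchor = ref_seq[point + delta : point + delta + anchor_k]
            if len(anchor) < anchor_k:
                break
            li = _find_once(cur_seq, anchor)
            if li is None:
                continue
            for pi, piece in enumerate(pieces):
                ri = _find_once(piece, anchor)
                if ri is not None:
                    cur_seq = cur_seq[:li] + piece[ri:]
                    cur_chunks.append(interval)
                    leftovers.extend(p for qi, p in enumerate(pieces) if qi != pi)
                    spliced = True
                    break
            if spliced:
                break
        if not spliced:
            flush()
            cur_seq = pieces[0]
            cur_chunks = [interval]
            leftovers.extend(pieces[1:])
    flush()
    # Reads are shared between neighbouring chunks through their molecules, so
    # secondary minicontigs often reproduce sequence another contig already
    # carries; exact duplicates (substrings) are dropped rather than emitted.
    main_seqs = [c.sequence for c in out]
    leftovers.sort(key=len, reverse=True)
    kept_leftovers: list[str] = []
    for piece in leftovers:
        if any(piece in s for s in main_seqs) or any(piece in s for s in kept_leftovers):
            continue
        kept_leftovers.append(piece)
    for piece in kept_leftovers:
        out.append(StitchedContig(piece, block_id, haplotype, []))
    return out


def consolidate_contigs(
    contigs: list[StitchedContig],
    anchor_k: int = DEFAULT_ANCHOR_K,
    max_rounds: int = 50,
) -> list[StitchedContig]:
    """Merge same-haplotype contigs that share an exact sequence overlap.

    Assembly of a chunk can break into pieces where contaminating reads
    create branches; the pieces genuinely overlap (they broke at branch
    points, not at coverage gaps).  Two contigs are merged when the first
    ``anchor_k`` bases of one occur exactly once in the other and the
    overlapping suffix/prefix match verbatim; a contig wholly contained in
    another is absorbed.  Only exact overlaps merge, so error-containing
    tips are left alone.
    """
    items = sorted(contigs, key=lambda c: -len(c.sequence))
    for _ in range(max_rounds):
        merged_any = False
        for i, x in enumerate(items):
            for j, y in enumerate(items):
                if i == j or len(y.sequence) < anchor_k:
                    continue
                head = y.sequence[:anchor_k]
                px = _find_once(x.sequence, head)
                if px is None:
                    continue
                overlap = len(x.sequence) - px
                if overlap <= 0:
                    continue
                if overlap >= len(y.sequence):
                    if x.sequence[px : px + len(y.sequence)] != y.sequence:
                        continue
                    new_seq = x.sequence  # y contained in x
                else:
                    if x.sequence[px:] != y.sequence[:overlap]:
                        continue
                    new_seq = x.sequence + y.sequence[overlap:]
                merged = StitchedContig(
                    sequence=new_seq,
                    block_id=x.block_id,
                    haplotype=x.haplotype,
                    chunks=sorted(set(x.chunks) | set(y.chunks)),
                )
                items = [c for k, c in enumerate(items) if k not in (i, j)]
                items.append(merged)
                items.sort(key=lambda c: -len(c.sequence))
                merged_any = True
                break
            if merged_any:
                break
        if not merged_any:
            break
    return items


def write_bedgraph(path, chrom: str, values: np.ndarray) -> None:
    """Persist a per-base profile as bedGraph (run-length encoded)."""
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[start]:
                fh.write(f"{chrom}\t{start}\t{i}\t{values[start]}\n")
                start = i
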
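"""Reconstruction of long DNA molecules from barcoded short-read alignments.

Linked-read libraries tag every short read with the barcode of the droplet
its source molecule was partitioned into.  Reads sharing a barcode and
falling close together on the reference therefore almost surely derive from
one original long fragment ("molecule").  This module rebuilds those
molecules, attaches heterozygous-SNP allele observations to each one, and
computes the coverage statistics (C, C_F, C_R) that characterise a library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_SPLIT_GAP = 50_000  # bp between successive same-barcode reads that splits molecules
DEFAULT_MIN_MAPQ = 20

# Phred probability that a base call is correct, clamped so that a single
# observation can never be treated as certain (or as uninformative).
P_CORRECT_MIN = 0.51
P_CORRECT_MAX = 0.9999


def phred_to_p_correct(qual: float) -> float:
    """Convert a phred base quality to a clamped probability of correctness."""
    p = 1.0 - 10.0 ** (-qual / 10.0)
    return min(max(p, P_CORRECT_MIN), P_CORRECT_MAX)


@dataclass(slots=True)
class ReadAlignment:
    """One aligned short read.

    ``base_calls`` maps heterozygous-variant id -> (allele, base quality),
    where allele 0 is the reference allele and 1 the alternate.
    Coordinates are 0-based half-open on the reference.
    """

    read_id: str
    barcode: str
    chrom: str
    start: int
    end: int
    mapq: int = 60
    base_calls: dict[int, tuple[int, int]] = field(default_factory=dict)
    seq: str | None = None
    quals: str | None = None
    # simulator provenance (None for real data)
    truth_hap: int | None = None
    truth_molecule: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id}: start {self.start} >= end {self.end}")
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"read {self.read_id}: mapq {self.mapq} outside [0, 60]")


@dataclass(slots=True)
class Molecule:
    """A reconstructed long fragment.

    ``allele_calls`` maps het-variant id -> (allele, p_correct) where
    p_correct is the clamped phred probability of the supporting base calls.
    """

    molecule_id: int
    barcode: str
    chrom: str
    start: int
    end: int
    read_ids: list[str] = field(default_factory=list)
    allele_calls: dict[int, tuple[int, float]] = field(default_factory=dict)
    reads: list[ReadAlignment] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class HetVariant:
    """A candidate heterozygous SNP from the read-based caller."""

    variant_id: int
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    qual: float
    depth: int
    alt_count: int

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


class UnsortedInputError(ValueError):
    """Raised when the alignment stream violates (barcode, chrom, start) order."""


def reconstruct_fragments(
    alignments,
    split_gap: int = DEFAULT_SPLIT_GAP,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[Molecule]:
    """Group a (barcode, chrom, start)-sorted alignment stream into molecules.

    Two successive reads with the same barcode on the same chromosome belong
    to the same molecule unless the gap between the end of the earlier read
    and the start of the later one exceeds ``split_gap`` (50 kb by default),
    in which case a new molecule is started.  Reads below ``min_mapq`` are
    discarded before grouping.  The input must already be sorted; an
    out-of-order stream raises :class:`UnsortedInputError` rather than being
    silently re-sorted.
    """
    molecules: list[Molecule] = []
    cur: Molecule | None = None
    prev_key: tuple[str, str, int] | None = None
    prev_end = 0
    next_id = 0
    for aln in alignments:
        key = (aln.barcode, aln.chrom, aln.start)
        if prev_key is not None and key < prev_key:
            raise UnsortedInputError(
                f"alignment stream not sorted by (barcode, chrom, start) at read {aln.read_id}"
            )
        prev_key = key
        if aln.mapq < min_mapq:
            continue
        same_group = (
            cur is not None
            and aln.barcode == cur.barcode
            and aln.chrom == cur.chrom
            # gap measured end-of-previous to start-of-next
            and aln.start - prev_end <= split_gap
        )
        if same_group:
            cur.read_ids.append(aln.read_id)
            cur.reads.append(aln)
            cur.end = max(cur.end, aln.end)
            prev_end = max(prev_end, aln.end)
        else:
            cur = Molecule(
                molecule_id=next_id,
                barcode=aln.barcode,
                chrom=aln.chrom,
                start=aln.start,
                end=aln.end,
                read_ids=[aln.read_id],
                reads=[aln],
            )
            next_id += 1
            molecules.append(cur)
            prev_end = aln.end
    return molecules


def assign_alleles(molecule: Molecule, variants: list[HetVariant] | None = None) -> Molecule:
    """Attach heterozygous-SNP allele calls to a molecule from its reads.

    Every het site covered by the molecule's reads with a consistent allele
    across all of its reads gets one entry; sites where reads of the *same*
    molecule disagree are dropped from this molecule only (the molecule is
    retained).  p_correct is derived from the best supporting base quality.
    """
    by_site: dict[int, list[tuple[int, int]]] = {}
    for read in molecule.reads:
        for vid, (allele, qual) in read.base_calls.items():
            by_site.setdefault(vid, []).append((allele, qual))
    calls: dict[int, tuple[int, float]] = {}
    for vid, obs in by_site.items():
        alleles = {a for a, _ in obs}
        if len(alleles) != 1:
            continue  # intra-molecule conflict: drop the site here
        allele = obs[0][0]
        best_q = max(q for _, q in obs)
        calls[vid] = (allele, phred_to_p_correct(best_q))
    if variants is not None:
        keep = {v.variant_id for v in variants}
        calls = {vid: c for vid, c in calls.items() if vid in keep}
    molecule.allele_calls = calls
    return molecule


def merge_libraries(per_library_molecules: list[list[Molecule]]) -> list[Molecule]:
    """Pool molecules from several libraries into one set.

    Once molecules are reconstructed per library, barcodes are no longer
    needed, so libraries sharing a barcode whitelist can be combined by
    re-keying molecule ids (and barcodes) with a library prefix.
    """
    merged: list[Molecule] = []
    next_id = 0
    for lib_idx, mols in enumerate(per_library_molecules):
        for m in mols:
            merged.append(
                Molecule(
                    molecule_id=next_id,
                    barcode=f"L{lib_idx}:{m.barcode}",
                    chrom=m.chrom,
                    start=m.start,
                    end=m.end,
                    read_ids=list(m.read_ids),
                    allele_calls=dict(m.allele_calls),
                    reads=m.reads,
                )
            )
            next_id += 1
    return merged


def coverage_stats(
    molecules: list[Molecule],
    alignments: list[ReadAlignment],
    genome_length: int,
) -> tuple[float, float, float]:
    """Return (C, C_F, C_R): raw, physical (fragment) and per-fragment read coverage.

    C_F = total molecule bases / genome length, C_R = total read bases /
    total molecule bases, and C = total read bases / genome length, so
    C = C_F * C_R by construction.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not molecules or not alignments:
        raise ValueError("coverage_stats requires non-empty molecules and alignments")
    mol_bases = float(sum(m.length for m in molecules))
    read_bases = float(sum(a.end - a.start for a in alignments))
    c_f = mol_bases / genome_length
    c_r = read_bases / mol_bases
    c = read_bases / genome_length
    return c, c_f, c_r


def molecule_table(molecules: list[Molecule]) -> pd.DataFrame:
    """Tabulate molecules (one row each) for TSV export."""
    rows = [
        {
            "molecule_id": m.molecule_id,
            "barcode": m.barcode,
            "chrom": m.chrom,
            "start": m.start,
            "end": m.end,
            "n_reads": len(m.read_ids),
            "n_allele_calls": len(m.allele_calls),
        }
        for m in molecules
    ]
    return pd.DataFrame(rows, columns=[
        "molecule_id", "barcode", "chrom", "start", "end", "n_reads", "n_allele_calls",
    ])


def write_molecule_table(molecules: list[Molecule], path) -> None:
    molecule_table(molecules).to_csv(path, sep="\t", index=False)
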
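"""Per-chunk local assembly and contig naming.

Reads are partitioned by (phase block, haplotype, chunk) and each partition
is assembled independently.  The default backend is a small greedy de Bruijn
assembler (k = 31, k-mers below count 2 dropped, maximal unambiguous paths
emitted) sufficient for error-free or low-error simulated reads; an external
assembler can be plugged in via a shell command template.  Contig headers
follow the scheme

    <n>_PS<block_start>:<block_end>_hp<k>[_merge<cs>:<ce>_hp<k>-...]

where the optional ``_merge`` suffix lists the chunk intervals a stitched
contig was concatenated from.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contiguity import AssemblyChunk, StitchedContig
from .fragments import Molecule, ReadAlignment

DEFAULT_K = 31
DEFAULT_MIN_KMER_COUNT = 2

_BASE_OF = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def partition_reads(
    chunks: list[AssemblyChunk],
    molecules: list[Molecule],
    assignments: dict[int, tuple[int, int]],
) -> dict[int, list[ReadAlignment]]:
    """Distribute reads to chunks via their molecules.

    A molecule assigned to (block, haplotype) contributes all its reads to
    every chunk of that block and haplotype whose interval it overlaps by at
    least 1 bp; unassigned molecules contribute their reads to both
    haplotypes of every overlapping chunk (diploid coverage must not vanish
    in het-poor regions).  Returns chunk index -> reads and fills each
    chunk's ``read_ids``.
    """
    by_block: dict[tuple[int, int], list[int]] = defaultdict(list)
    for idx, ch in enumerate(chunks):
        by_block[(ch.block_id, ch.haplotype)].append(idx)
    out: dict[int, list[ReadAlignment]] = defaultdict(list)
    for m in molecules:
        target = assignments.get(m.molecule_id)
        if target is not None:
            bid, hp = target
            cand = by_block.get((bid, hp), [])
        else:
            cand = range(len(chunks))
        for idx in cand:
            ch = chunks[idx]
            if m.start < ch.end and m.end > ch.start:
                out[idx].extend(m.reads)
                ch.read_ids.extend(m.read_ids)
    return dict(out)


# ---------------------------------------------------------------------------
# toy de Bruijn backend

def _kmer_codes(seqs: list[str], k: int) -> np.ndarray:
    """All valid k-mer codes (2 bits/base, exact for k <= 31) across reads."""
    joined = ("N".join(seqs)).encode()
    codes = _CODE[np.frombuffer(joined, dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    safe = np.where(valid, codes, 0).astype(np.uint64)
    w = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        w = (w << np.uint64(2)) | safe[j : n - k + 1 + j]
    ok = np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    return w[ok]


def _decode(code: int, k: int) -> str:
    return "".join(_BASE_OF[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def toy_assemble(
    seqs: list[str],
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_KMER_COUNT,
    dominance: float = 3.0,
) -> list[str]:
    """Greedy de Bruijn assembly of single-stranded reads.

    Builds the k-mer count table (dropping k-mers seen fewer than
    ``min_count`` times) and emits maximal paths.  A branch is followed when
    one extension dominates: its count is at least ``dominance`` times the
    combined count of the alternatives.  This pops the low-coverage bubbles
    introduced by reads of unassigned molecules (which are deliberately
    given to both haplotypes) without joining genuinely ambiguous paths.
    Reads are treated as coming from one strand; no reverse-complement
    folding.
    """
    if not seqs:
        return []
    codes = _kmer_codes(seqs, k)
    if not len(codes):
        return []
    uniq, counts = np.unique(codes, return_counts=True)
    keep = counts >= min_count
    count_of = dict(zip(uniq[keep].tolist(), counts[keep].tolist()))
    if not count_of:
        return []
    mask = (1 << (2 * k)) - 1
    high = 2 * (k - 1)

    def dominant(cands: list[int]) -> int | None:
        if len(cands) == 1:
            return cands[0]
        if not cands:
            return None
        cands.sort(key=lambda y: -count_of[y])
        rest = sum(count_of[y] for y in cands[1:])
        return cands[0] if count_of[cands[0]] >= dominance * rest else None

    def dom_succ(x: int) -> int | None:
        base = (x << 2) & mask
        return dominant([y for b in range(4) if (y := base | b) in count_of])

    def dom_pred(x: int) -> int | None:
        base = x >> 2
        return dominant([y for b in range(4) if (y := base | (b << high)) in count_of])

    starts = [x for x in count_of if (p := dom_pred(x)) is None or dom_succ(p) != x]
    visited: set[int] = set()
    contigs: list[str] = []

    def walk(start: int) -> None:
        path = [start]
        visited.add(start)
        cur = start
        while True:
            nx = dom_succ(cur)
            if nx is None or nx in visited or dom_pred(nx) != cur:
                break
            path.append(nx)
            visited.add(nx)
            cur = nx
        seq = _decode(path[0], k) + "".join(_BASE_OF[p & 3] for p in path[1:])
        contigs.append(seq)

    for s in sorted(starts):
        if s not in visited:
            walk(s)
    for s in sorted(count_of.keys() - visited):  # leftover cycles/bubble interiors
        if s not in visited:
            walk(s)
    return contigs


class AssemblerNotFoundError(RuntimeError):
    pass


def assemble_chunk(
    reads: list[ReadAlignment],
    backend: str = "toy",
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_KMER_COUNT,
    external_cmd: str | None = None,
) -> list[str]:
    """Assemble one chunk's reads into minicontig sequences.

    ``backend="toy"`` runs the built-in de Bruijn assembler; ``"external"``
    shells out to ``external_cmd`` (a template with {reads} and {out}
    placeholders, e.g. a SPAdes invocation) and parses the resulting FASTA.
    """
    if not reads:
        return []
    if backend == "toy":
        return toy_assemble([r.seq for r in reads if r.seq], k=k, min_count=min_count)
    if backend == "external":
        if not external_cmd:
            raise AssemblerNotFoundError(
                "external backend selected but config key 'external_cmd' is unset"
            )
        exe = external_cmd.split()[0]
        if shutil.which(exe) is None:
            raise AssemblerNotFoundError(
                f"external assembler '{exe}' not found on PATH (config key 'external_cmd')"
            )
        with tempfile.TemporaryDirectory() as tmp:
            fq = Path(tmp) / "reads.fastq"
            with open(fq, "w") as fh:
                for r in reads:
                    fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.quals or 'I' * len(r.seq)}\n")
            outdir = Path(tmp) / "out"
            subprocess.run(external_cmd.format(reads=fq, out=outdir), shell=True, check=True)
            fasta = next(outdir.glob("**/contigs.fasta"), None)
            if fasta is None:
                return []
            return [seq for _, seq in read_fasta(fasta)]
    raise ValueError(f"unknown backend {backend!r}")


def read_fasta(path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(parts)))
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        records.append((name, "".join(parts)))
    return records


# ---------------------------------------------------------------------------
# contig naming

HEADER_RE = re.compile(
    r"^(?P<n>\d+)_PS(?P<start>\d+):(?P<end>\d+)_hp(?P<hp>[12])"
    r"(?:_merge(?P<merge>.+))?$"
)
MERGE_PART_RE = re.compile(r"^(?P<cs>\d+):(?P<ce>\d+)_hp(?P<hp>[12])$")


@dataclass(slots=True)
class ContigName:
    number: int
    block_start: int
    block_end: int
    haplotype: int
    merge_chunks: list[tuple[int, int, int]] = field(default_factory=list)

    def format(self) -> str:
        head = f"{self.number}_PS{self.block_start}:{self.block_end}_hp{self.haplotype}"
        if self.merge_chunks:
            head += "_merge" + "-".join(f"{cs}:{ce}_hp{hp}" for cs, ce, hp in self.merge_chunks)
        return head


def parse_contig_header(header: str) -> ContigName:
    m = HEADER_RE.match(header)
    if not m:
        raise ValueError(f"contig header does not match grammar: {header!r}")
    merges: list[tuple[int, int, int]] = []
    if m.group("merge"):
        for part in m.group("merge").split("-"):
            pm = MERGE_PART_RE.match(part)
            if not pm:
                raise ValueError(f"bad merge component {part!r} in header {header!r}")
            merges.append((int(pm.group("cs")), int(pm.group("ce")), int(pm.group("hp"))))
    return ContigName(
        number=int(m.group("n")),
        block_start=int(m.group("start")),
        block_end=int(m.group("end")),
        haplotype=int(m.group("hp")),
        merge_chunks=merges,
    )


def name_contigs(
    contigs: list[StitchedContig],
    block_spans: dict[int, tuple[int, int]],
) -> list[tuple[str, str]]:
    """Produce FASTA records with grammar-conformant headers.

    Contigs stitched from more than one chunk carry a ``_merge`` suffix
    listing their constituent chunk intervals, most recently concatenated
    first.
    """
    records: list[tuple[str, str]] = []
    for i, c in enumerate(contigs, start=1):
        span = block_spans.get(c.block_id, (c.block_id, c.block_id))
        merges = [(cs, ce, c.haplotype) for cs, ce in reversed(c.chunks)] if len(c.chunks) > 1 else []
        name = ContigName(
            number=i,
            block_start=span[0],
            block_end=span[1],
            haplotype=c.haplotype,
            merge_chunks=merges,
        )
        records.append((name.format(), c.sequence))
    return records
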
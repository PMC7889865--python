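"""Assemble both haplotypes of a simulated genome end to end.

Runs the whole pipeline — haplotyping, partitioning-point selection,
per-chunk assembly with the built-in de Bruijn backend, and minicontig
stitching — then reports the diploid fraction: the share of the genome
covered by exactly one contig per parental haplotype (ideal diploid
assembly = close to 100%).
"""

from phasembly import evaluate as ev
from phasembly.pipeline import run_pipeline
from phasembly.sim import SimConfig, simulate

cfg = SimConfig(genome_length=300_000, n_barcodes=1_500, molecules_per_barcode=1,
                molecule_mean_length=30_000, base_error_rate=0.0, seed=7)
sim = simulate(cfg)
run = run_pipeline(sim.alignments, sim.het_variants, sim.truth.ref_seq, cfg.chrom)

print(f"{len(run.step1.blocks)} phase block(s), {len(run.step1.chunks)} assembly chunks, "
      f"{len(run.step1.points):,} partitioning points")
big = sorted(run.step2.records, key=lambda r: -len(r[1]))[:4]
for header, seq in big:
    print(f"  {header[:60]:<60s} {len(seq):>9,} bp")
frac = ev.diploid_fraction(run.varcall.alignments, cfg.genome_length)
print(f"diploid fraction: {100 * frac:.2f}% "
      "(genome covered by exactly two parental contigs)")
for contig in run.step2.stitched:
    if len(contig.chunks) > 1:
        ok = any(contig.sequence in sim.truth.hap_maps[h].seq for h in (1, 2))
        print(f"  stitched hp{contig.haplotype} contig from {len(contig.chunks)} chunks "
              f"matches a truth haplotype exactly: {ok}")
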
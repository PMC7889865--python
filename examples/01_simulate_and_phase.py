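"""Simulate a linked-read library and phase it into diploid blocks.

Builds a 300 kb diploid genome with heterozygous SNPs, reconstructs the
long molecules from barcode-sharing reads, and runs the Bayesian parity
model plus recursive clustering to produce phase blocks.  The final lines
compare the predicted phase with the simulator truth: a mismatch error is
an isolated single-SNP flip, a long switch is a flip persisting over two
or more consecutive SNPs — both should be zero on error-free data.
"""

from phasembly.fragments import assign_alleles, coverage_stats, reconstruct_fragments
from phasembly.haplotyping import evaluate_phasing, phase_molecules
from phasembly.sim import SimConfig, simulate

cfg = SimConfig(genome_length=300_000, n_barcodes=1_500, molecules_per_barcode=1,
                molecule_mean_length=30_000, base_error_rate=0.0, seed=7)
sim = simulate(cfg)
print(f"simulated {len(sim.alignments)} reads, {len(sim.het_variants)} het SNPs")

molecules = reconstruct_fragments(sim.alignments)
for m in molecules:
    assign_alleles(m)
c, c_f, c_r = coverage_stats(molecules, sim.alignments, cfg.genome_length)
print(f"reconstructed {len(molecules)} molecules; C={c:.1f} C_F={c_f:.1f} C_R={c_r:.2f}")

blocks, assignments, kept = phase_molecules(molecules, sim.het_variants)
var_pos = {v.variant_id: v.pos for v in kept}
report = evaluate_phasing(blocks, sim.truth.truth_phase, var_pos)
print(f"{len(blocks)} phase block(s), {report['phased_count']} SNPs phased, "
      f"N50 {report['block_N50']:,} bp")
print(f"mismatch errors: {report['mismatch_errors']}   "
      f"long switch errors: {report['long_switch_errors']}")
print("(zero errors = every phased SNP assigned to the correct parental haplotype)")
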
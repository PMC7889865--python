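# Methods

This note records the models, parameter choices and numerical decisions
behind `phasembly`, and what the bundled simulator does and does not show
about real data.

## The phasing model

Linked reads carry their droplet barcode; reads sharing a barcode within a
50 kb gap are taken to descend from one long molecule. Every molecule
covering two heterozygous SNPs observes a two-site key. Because the two
parental haplotypes are complementary at het sites, the truth is either the
even-parity key pair {00, 11} or the odd pair {01, 10}; sequencing errors
flip individual keys across parities.

Writing p₁ and p₂ for the probabilities that the allele calls at the two
sites are correct, a key retains the true parity when both calls are right
or both are wrong: p_c = p₁p₂ + (1−p₁)(1−p₂). Among N molecules covering
the pair, the even-key count k is Binomial(N, p_c) if even parity is true
and Binomial(N, 1−p_c) if odd is true. With equal priors the posterior for
even parity is

    P(even | k, N) = p_c^k (1−p_c)^(N−k) /
                     [ p_c^k (1−p_c)^(N−k) + (1−p_c)^k p_c^(N−k) ]

(binomial coefficients cancel). A pair is called EVEN or ODD when the
posterior for that hypothesis exceeds α = 0.99, otherwise UNDETERMINED. An
unnormalised variant of this quotient — dividing the even-parity likelihood
by C(N,k)/2^N with a prior of 1 — appears in the linked-read literature; it
can exceed 1 and is retained here only behind `literal=True`. The
normalised posterior reproduces the same accept/reject behaviour at the
0.99 level (exhaustively checked for N ≤ 12) while remaining a probability.
Per-variant p values default to the mean per-call correctness probability
(from base qualities, clamped to [0.51, 0.9999]) floored at 0.95; the floor
keeps a single lucky Q40 call from dominating a decision.

Pairs with a confident parity seed cluster pairs — the molecules carrying
one key versus its complement. Cluster pairs merge, complements in
lockstep, when the molecules shared between them and supporting the same
haplotype number at least `merge_support = 3` (bounding the per-pair
merge error by ((1−p₁)(1−p₂))³); a molecule counts once per cluster pair.
Orientation is chosen by the larger of the straight/crossed shared-molecule
counts; exact ties are skipped as contradictory. Merging repeats to a fixed
point and, because the merge criterion is monotone in the growing clusters,
the result is order-independent on consistent data (tested against a
random-order oracle).

Converged cluster pairs become phase blocks: a variant is phased only when
every assigned molecule covering it agrees with the block haplotype. Blocks
sharing at least `overlap_support = 5` consistently oriented variants merge
via union-find with an orientation bit (merge error ≤ p⁵ for per-variant
error p). Afterwards blocks are made disjoint in variant membership: larger
blocks claim their variants first and remnants left with fewer than two
variants of their own are dropped. This last step matters because read
coverage within a molecule is sparse (C_R < 1): each molecule sees a
different subset of het sites, so thousands of small seed pairs survive
merging as subsets of a large block and would otherwise linger as duplicate
micro-blocks.

Finally every molecule with ≥ 2 het calls is assigned to the (block,
haplotype) maximising p(M|p,H) − p(M|p,H_c), with
p(M|p,H) = Π θ(Hᵢ,Mᵢ)pᵢ + (1−θ(Hᵢ,Mᵢ))(1−pᵢ). Margins below 10⁻¹² are
treated as ties and the molecule stays unassigned; its reads later go to
both haplotypes so diploid coverage survives het-poor regions.

### Variant pruning

Before any of this, het-SNP candidates are pruned: alternate-allele
fraction ≥ 0.25, call quality ≥ 13, and depth within a two-tailed band. The
band is implemented as the 10th–90th percentile of the per-variant depth
distribution; the literal band 0.1×mean ≤ d ≤ 0.9×mean (available via
`PruneConfig(literal_coverage_band=True)`) would reject every variant at
typical depth, since the mean itself lies outside [0.1·mean, 0.9·mean]
bands only for heavily skewed distributions. All cutoffs are
boundary-inclusive.

## Partitioning and stitching

Partitioning points are positions with read depth above 0.8 of the covered
average, molecule depth above 0.8 of its covered average, and a 100-mer
that occurs exactly once in the reference and its reverse complement
(k-mers hashed with an exact-collision-negligible 64-bit rolling
polynomial; a hash collision can only demote a unique position, never
promote a repeated one). Blocks longer than `block_threshold = 200 kb` are
cut at the qualifying point nearest each 100 kb multiple within ± 20 kb;
with no qualifying point the boundary is skipped and the chunk grows.
Boundary chunks extend to midpoints between neighbouring blocks (and to the
chromosome ends) so assembly does not stop at the outermost phased variant.

Stitching splices the minicontigs of neighbouring chunks at the reference
100-mer anchored at their shared point, keeping the left piece up to the
anchor and the right piece from it. A planted variant within 100 bp of the
point removes that exact 100-mer from the haplotype (≈ 10% of points per
haplotype at het rate 10⁻³), so anchor start positions up to
`search_margin = 2 kb` right of the point are tried in turn; each splice
feeds the next. Unspliceable pieces are kept. Two clean-up passes follow,
both restricted to exactly redundant sequence: same-haplotype contigs
sharing a verbatim overlap (first 100-mer of one unique in the other,
overlap identical) are merged — chunk assemblies break at contamination
branch points, not coverage gaps, so the pieces genuinely overlap — and
unplaced pieces whose reference interval a placed same-haplotype contig
already covers are purged as duplicate haplotigs.

## The toy assembler

The built-in backend builds a k = 31 de Bruijn graph over single-stranded
reads (2-bit-exact integer k-mers, vectorised extraction), drops k-mers
seen fewer than `min_count = 2` times, and emits maximal paths. A branch is
taken when one extension's count is at least 3× the combined count of the
alternatives. This dominance rule exists because reads of unassignable
molecules are deliberately duplicated into both haplotypes: at every het
site they open a low-coverage bubble that would end a
maximal-unambiguous-path walk, fragmenting chunks into kb-scale pieces. At
the default operating point the true path runs at ≈ 35× k-mer coverage
against ≤ ~5× contamination, so the 3× rule pops these bubbles while still
refusing genuinely ambiguous joins. An external assembler can be plugged in
with a shell template (`external_cmd`, `{reads}`/`{out}` placeholders);
the toy backend keeps the test suite self-contained.

## Variant extraction and zygosity

Contigs longer than 1 kb are aligned to the reference (edlib, semi-global,
restricted to the contig's provenance interval padded by 150 kb) at an
assumed MAPQ of 60; external PAF + cs-string alignments parse into the same
structure and MAPQ ≥ 20 is enforced there. Edit-distance alignment is
unit-cost, so one indel may surface as co-optimal pieces separated by short
accidental matches; edit operations closer than 10 bp are therefore
re-normalised together — the spanned reference/query windows are trimmed to
their minimal difference and indels are left-aligned by rotating the event
sequence through its anchor base. Left-alignment is what makes
cross-haplotype and truth comparisons exact.

SNP zygosity: the same alternate allele on both haploid callsets is
homozygous; an alternate on one haplotype whose position the other
haplotype's contigs cover (showing reference) is heterozygous; without
coverage the het call carries a low-confidence flag; different alternates
become two flagged het records. Indels/SVs match across haplotypes by
interval overlap (deletions) or breakpoints within 20 bp (insertions);
variants of size ≥ 50 bp are classed as SVs. Merging with the read-based
SNP callset resolves genotype conflicts in favour of the read-based
genotype, keeping the assembly call as an annotation. Phasing orients each
(block, contig-haplotype) by majority vote of its assembly SNPs against the
scaffold's phased SNPs; ties stay unphased, homozygous records are written
1/1 without a phase set.

## SV post-analysis

Cross-callset merging uses the same deletion-overlap / 20 bp-insertion
rules as zygosity inference, closed transitively (order-independent).
Repeat classes: an SV of 250–350 bp whose global affine-gap identity
(matches / alignment columns, both strands) to the bundled Alu consensus is
≥ 0.80 is "Alu"; otherwise an annotation overlap or a naive tandem detector
(period ≤ 6, ≥ 3 copies, ≥ 50% of the sequence) gives "Repeat"; else
"Other". The bundled consensus (`alu_consensus_synthetic.fasta`) is a
seeded random 311 bp stand-in, not a published element consensus; the
classifier is exercised by mutating it to the identity boundary, which is
independent of the consensus content. Ancestral direction per SV comes from
the gap between its 500 bp flanks on an outgroup: a gap within 2 bp makes a
deletion call "Ins_Ref" and an insertion call "Ins_Tar" (actual
insertions); a gap within 0.9–1.1× the SV size (inclusive) makes them
"Del_Tar" / "Del_Ref" (actual deletions); anything else, flanks on
different outgroup chromosomes, or disagreeing outgroups is unresolved.
Segregation patterns over the five observed chromosomes (two individuals ×
two haplotypes + the reference haplome) form 18 raw ancestral/derived
combinations, 16 observable ones (1–4 derived alleles), 12 with differing
individual genotypes arranged in 6 swap-equivalence pairs — 12 classes once
actual insertions and deletions are distinguished.

## The simulator and what passing means

The simulator draws a uniform-random reference, plants non-overlapping
variants (binomial counts at the configured rates; het variants assigned to
one haplotype; ≥ 60 bp separation so every event is distinctly
representable), builds both haplomes with exact coordinate maps, places
molecules with exponential lengths truncated to [1 kb, 5× mean] (barcodes
hold 2 molecules ≥ 200 kb apart), and emits paired 100 bp reads at known
placements with per-base errors (Q30 bases, Q10 at error positions).
Alignments are truth-placed, bypassing a mapper. Defaults are the study
conditions: 1 Mb genome, het SNP rate 10⁻³, C_F ≈ 250 from 50 kb molecules,
C_R = 0.4, hence C ≈ 100 — the operating point of deep linked-read
libraries (C ≈ 100×, C_F 10²–10³, C_R 0.05–0.4). Molecules overhanging the
genome ends are clipped, as real molecules are at chromosome ends; the
resulting pile-up of short (hence unassignable) fragments there is the main
stress the clean-up passes above address. Tests at 300 kb shrink only the
genome, not the coverage densities.

Not emulated: mapping ambiguity and soft-clipping, barcode errors and
whitelists, GC and coverage bias, chimeric molecules, instrument-specific
error profiles, and real repeat structure (a random genome is almost
everywhere 100-mer-unique, so partitioning points are dense). Passing the
bundled end-to-end checks therefore demonstrates the algorithms are
implemented correctly and are robust to sequencing error and to
both-haplotype read contamination — not that real-genome contiguity or F1
would match these numbers.

## Problem sizes and runtime

The acceptance run uses the 1 Mb default simulation (~900 k reads, ~5000
molecules, ~1600 het SNPs): roughly 20 s to simulate and 4–5 min for the
full pipeline on one CPU, dominated by per-chunk k-mer counting. The test
suite runs the same 1 Mb condition once (shared fixture) plus a 300 kb
fixture and unit tests. Determinism: a fixed simulator seed fixes all
downstream results bit-for-bit; the pipeline itself is seed-free
(deterministic given its input).

## Known limitations

- Contigs are aligned with unit edit costs; very large or nested events
  can mis-normalise even after cluster re-normalisation.
- The dominance rule assumes contamination stays several-fold below true
  coverage; at C below ~40× the toy assembler fragments (use an external
  assembler there).
- `merge_snp_calls` keys sites by position only; co-located SNPs and
  indels from the read-based set would collide (the simulator separates
  them by construction).
- Phase-block hp1/hp2 labels are arbitrary per block; consumers must treat
  them as such (all bundled evaluations do).
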
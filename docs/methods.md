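# Methods

## The virtual-HTS profile

The profile treats read mapping itself as the measurement. An
error-free read is generated at every position of the forward strand of
the reference, and each read is exhaustively realigned to that same
reference on both strands, allowing up to *k* mismatches, with no cap
on reported placements and no best-hit selection. A read with more than
one placement is *multialigned*. After discarding the unique
alignments, every position still covered by an alignment of a
multialigned read belongs to an M region; maximal such runs are
reported with 1-based inclusive coordinates, and the complement (within
non-N sequence) is the U genome. Positions inside N runs are
`undefined` and belong to neither class.

Two consequences of this operational definition are worth keeping in
mind. First, reads only partially overlapping a repeat are still
multialigned (their overhang counts against the mismatch budget), so M
regions extend up to *r* − 1 nt beyond the exact repeat boundary and
are never shorter than *r* — the read length is the resolution limit.
Second, an inverted copy makes forward-generated reads align on the
reverse strand; both placements count, so palindromic and inverted
duplications are M by construction.

## Alignment

The aligner is exact, not heuristic. A read (or, in color mode, its
color string) is partitioned into *k* + 1 non-overlapping seeds; by the
pigeonhole principle any placement with ≤ *k* mismatches contains at
least one exact seed, which is looked up in a hashed index of the
reference. Candidates are verified by a vectorized Hamming count.
Chromosomes shorter than ~600 nt, or parameter combinations yielding
seeds shorter than 5 symbols, use a full sliding-window scan instead.
Either path produces the identical result set; the test suite checks
set-identity against an independent naive scan over hundreds of random
genomes up to tens of kb at k ≤ 6 in both encodings.

Mismatch offsets are recorded in read orientation; the reference symbol
is always the forward-genome symbol. For a reverse-strand alignment the
mismatch at read offset *q* sits at genomic position
`start + length − 1 − q` and deposits the complement of the read base.

### Color space

The SOLiD dibase code is the XOR of the 2-bit base codes (A=0, C=1,
G=2, T=3): identical pairs give color 0 and every row of the 4×4 dibase
matrix is a permutation. Encoding a length-*L* sequence yields the
first base as primer plus *L* − 1 colors; decoding inverts it exactly.
A single isolated substitution flips exactly the two adjacent colors of
the flanking pairs — the reason *k* color mismatches are stricter than
*k* base mismatches, and the reason color-space cross-alignment over
one divergent site needs *k* ≥ 2. Color alignments compare color
strings only; the primer base is excluded from mismatch counting.

When mapping color mismatches to base substitutions, only an isolated
*adjacent pair* of color mismatches is decoded: the implied substituted
base is computed independently from the left and right flanking
reference bases and kept only when the two agree and differ from the
reference. Isolated single color mismatches and runs of ≥ 3 are treated
as non-SNV mismatches (sequencing-error-like), mirroring dibase error
correction practice.

## Intragenomic SNVs and g-deNoise

Virtual reads are error-free, so a mismatch inside a multialignment can
only be a single-base difference between repeat copies. Each such
mismatch, mapped to forward-genome coordinates, produces one *directed*
record `(chrom, pos, ref, alt)` — the reference base at the position
and the base carried by the partner copy — with duplicates merged into
a support count. A unique alignment carrying a mismatch in a virtual
run is impossible and raises an internal-consistency error.

g-deNoise discards an alignment iff **any** of its mismatches matches
an annotated record exactly on all four fields. Two deliberate choices:

* An alignment carrying one annotated SNV plus novel mismatches is
  still discarded — its placement is consistent with a cross-copy
  origin, and keeping it would re-admit repeat noise.
* Matching is exact on the alternative base, so a mutation to a third
  base at an annotated position is *not* filtered. This asymmetry is
  the point of annotating directions rather than unordered pairs: known
  inter-copy polymorphism is removed, unknown variation survives.

If all placements of a read are discarded the read is dropped from
downstream calling; no placement is trusted.

Applying the filter to the virtual run itself splits each M region:
positions still covered by a surviving multialignment are M_M, the rest
M_U. M_U ∪ M_M tiles M exactly. The filter can only shrink alignment
sets, and an error-free read's origin placement has no mismatches, so
origins are never discarded.

## Variant calling

Calling uses only unique alignments: natively unique reads, plus reads
that became unique after g-deNoise. Pileups are strand-split per base,
and for alternative bases the set of distinct `(start, strand)` pairs
is tracked as a proxy for independent template molecules.

* **U rule** (default `min_fraction = 0.70`): alt fraction of covering
  unique alignments ≥ 70% and ≥ 1 supporting alignment on each strand.
  No absolute depth floor is imposed beyond both-strand support; the
  fraction is per-position over covering unique alignments.
* **M rule** (defaults 10/10/5): ≥ 10 alt alignments on each strand,
  ≥ 5 distinct start points, applied inside M regions after filtering.
* Both thresholds are closed ("at least"): exactly 0.70 and exactly
  10/10/5 pass.

"Noisy" low-complexity tracts are masked before M calling:
homopolymers ≥ 5 nt, and tandem repeats with unit ≤ 6, ≥ 3 copies and
tract ≥ 8 nt, each widened by a 2-nt flank. These defaults are
conservative and CLI-configurable; there is no canonical definition of
"noisy" tract, so the knobs are exposed rather than hidden.

Across *n* ≥ 2 samples a variant key present in all samples is
*constitutive*, in exactly one *acquired*; intermediate sharing is
reported as *shared* with its support list rather than silently
dropped.

## Synthetic study genomes

The fixture generator plants repeat families into a uniform-composition
random background (GC configurable): each family has a copy number,
unit length, per-copy orientation (direct or inverted-complement) and a
chosen number of divergent sites, optionally at explicit unit offsets.
Divergent alleles are assigned round-robin to non-first copies so every
site separates at least one copy pair. Acquired mutations are planted
per copy and applied only to the *sample* genome, never the reference.
After assembly a self-scan verifies that every multialigned window at
the scan read length overlaps a planted copy — i.e. the background is
repeat-free at profiling resolution — regenerating from a derived seed
on collision. Everything is reproducible from `(spec, seed)`.

The read simulator is single-end, uniform over positions and strands,
with i.i.d. substitution errors; it emulates the error regime of
high-quality short reads (defaults used in tests: 50-nt reads, ~40-fold
coverage per strand, 0.1% error). It does not model quality profiles,
position-dependent error, indels, paired ends or coverage bias (GC,
mappability). Passing tests therefore demonstrate the logic of the
method under its stated assumptions — ungapped alignment, substitution
errors, a correct reference — not robustness to the full error
structure of real instruments.

Naive oracles (sliding-window Hamming scans over both strands, in both
encodings, reporting mismatches in window orientation) live beside the
generator and provide ground truth that is algorithmically independent
of the pigeonhole aligner.

## Problem sizes and numerical choices

The test and acceptance workloads run on genomes of 1–30 kb: large
enough that planted repeats, edge ramps and windowed statistics behave
as on real genomes, small enough that the exhaustive naive oracles
remain computable (they are quadratic in genome length). The
acceptance study genome is 30 kb with three repeat families; a
full-genome run of a ~12-Mb yeast-sized reference uses the same code
path via the streaming read generator and the seeded index.

Windowed coverage correlation tiles non-overlapping windows from
position 1, keeps a trailing partial window when it spans at least half
the window size, adds a pseudocount of 1 before the log10 transform so
zero-coverage windows are retained, and reports squared Pearson
correlation. The pseudocount makes scaling invariance approximate
rather than exact (r² ≈ 1 − 10⁻⁶ for a doubled track). Constant tracks
are returned as r² = 1 when identical and NaN otherwise, since Pearson
correlation is undefined there.

Ties and degenerate inputs: duplicate placements are keyed by
`(chrom, start, strand)`; alignment sets are ordered by chromosome
order, then start, then strand; a palindromic self-match on both
strands counts as two placements, making the read multialigned. Reads
containing N are rejected by the aligner; reference windows containing
N never match an N-free read (N compares unequal to every base).

## Known limitations

* Ungapped alignment only: indels in reads or between repeat copies are
  invisible; a gapped copy appears as a run of mismatches.
* M_M regions remain unresolvable by construction; rescuing them needs
  paired-end or long-range information, which is out of scope.
* The M-rule support thresholds presuppose deep (>20-fold per strand)
  coverage; at low coverage M-region variants are simply not called
  rather than called with lower confidence.
* The intragenomic SNV annotation is only as good as the reference:
  collapsed or mis-assembled repeats produce misleading signatures.
* Color-space decoding recovers only isolated single-base changes;
  adjacent substitutions between copies are treated as non-SNV noise
  and therefore not filtered.
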
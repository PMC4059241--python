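# gdenoise

Repeat-aware genome profiling and variant calling for short-read
sequencing.

Repetitive sequence is the blind spot of resequencing studies: reads
originating from near-identical repeat copies align to several places at
once, and most pipelines simply discard them, leaving the repeated
fraction of the genome — and any mutation inside it — invisible.
`gdenoise` attacks this from the reference side. It builds a *virtual
HTS profile* of a reference genome and then uses that profile to
deconvolute multialigned experimental reads, so that single-nucleotide
variants can be called in both unique and repetitive regions.

The pipeline has four steps:

1. **Virtual reads.** One error-free read of length *r* is generated at
   every position of the forward strand, so interior coverage equals
   *r*.
2. **Exhaustive back-alignment.** Every read is realigned to the genome
   on both strands, reporting *all* ungapped placements with at most *k*
   mismatches — no best-hit selection and no cap on the number of hits.
   Alignment can be done in base space or in SOLiD dinucleotide color
   space (where one base substitution costs two adjacent color
   mismatches).
3. **U/M annotation.** After discarding unique alignments, the genomic
   positions still covered by the remaining "ambiguous" alignments form
   the multialigned (M) regions; the complement is the unique (U)
   genome. Annotation is at single-nucleotide resolution — a U region
   can be one base long.
4. **Intragenomic SNVs and g-deNoise.** Since virtual reads are
   error-free, any mismatch in a multialignment marks a single-base
   difference between repeat copies. These *intragenomic SNVs* are
   recorded as directed `(chrom, pos, ref, alt)` signatures. The
   **g-deNoise** filter then discards any alignment (virtual or
   experimental) whose mismatches match an annotated signature exactly;
   reads whose cross-copy placements are all discarded become uniquely
   aligned. M sub-regions that deconvolute completely are labeled M_U,
   the residually ambiguous remainder M_M. Because matching is exact on
   the alternative base, an acquired mutation to a *third* base at a
   known variable position stays visible.

SNPs are then called from pileups of unique alignments with closed
thresholds: in U regions an alternative base seen in at least 70% of
covering alignments and supported on both strands; in M regions (after
g-deNoise) at least 10 supporting alignments per strand from at least 5
distinct start points, outside masked homopolymer/microsatellite
tracts. Across samples, a variant present in every line is
*constitutive* and one present in exactly one line is *acquired*.

## Worked example

Build a small synthetic genome with a polymorphic two-copy 300-nt gene
pair (two divergent sites), export it, and profile it:

```python
from gdenoise.fixtures import FixtureSpec, RepeatFamily, make_genome
from gdenoise.sequence_model import write_fasta

spec = FixtureSpec(6000, seed=5, read_length=50,
                   repeat_families=(RepeatFamily(2, 300, divergence=2,
                                                 divergence_offsets=(130, 170)),))
genome, truth = make_genome(spec)
write_fasta(genome, "demo.fa")
```

```sh
$ gdenoise profile demo.fa -o demo_profile -r 50 -k 3
M regions: 2 covering 620 nt (10.33% of non-N genome)

$ gdenoise annotate-snvs demo.fa -o demo_snvs -r 50 -k 3
16 intragenomic SNVs; M_U 102 nt + M_M 518 nt = M 620 nt
```

The two planted copies sit at 2476–2775 and 3802–4101; each M region is
310 nt — the 300-nt copy extended by 49-nt read overlap on one side and
trimmed where flanking reads accumulate too many mismatches. The SNV
table contains the planted divergent sites as reciprocal directed
records with full read support:

```
chrom   pos     ref  alt  support
chr1    2606    A    G    50
chr1    2646    T    G    50
...
chr1    3932    G    A    50
chr1    3972    G    T    50
```

(low-support records near the copy boundaries come from reads that
overlap the copy ends by a few bases — their background overhang is
itself a cross-copy mismatch). The 102 nt of M_U around the divergent
sites are the positions where every covering read is rescued by
g-deNoise; `gdenoise call` will accept SNP calls there.

## Layout

- `gdenoise.sequence_model` — genome container, FASTA I/O, color-space codec
- `gdenoise.virtual_reads` — exhaustive virtual-read generation
- `gdenoise.aligner` — all-hits ungapped aligner (base/color), SAM I/O
- `gdenoise.um_annotator` — coverage tracks, U/M regions, sweep, correlation
- `gdenoise.snv_denoise` — intragenomic SNVs, g-deNoise, M_U/M_M
- `gdenoise.variant_caller` — pileup, U/M calling rules, masking, sample status
- `gdenoise.fixtures` — seeded planted-repeat genomes, read simulator, naive oracles
- `gdenoise.cli` — `gdenoise profile | annotate-snvs | call | sweep | correlate`

See `docs/methods.md` for the model, parameter defaults and known
limitations.
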
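"""Intragenomic SNV annotation, g-deNoise filtering and M_U/M_M labeling."""

import numpy as np
import pytest

from gdenoise import (
    InternalConsistencyError,
    align_all,
    classify_mu_mm,
    extract_intragenomic_snvs,
    g_denoise,
    genomic_mismatches,
    profile,
)
from gdenoise.aligner import Alignment, AlignmentSet
from gdenoise.fixtures import (
    FixtureSpec,
    PlantedMutation,
    RepeatFamily,
    apply_mutations,
    make_genome,
    oracle_snvs,
)
from gdenoise.snv_denoise import SnvAnnotation


def diverged_pair(seed=50, divergence_offsets=(25, 95), unit=120, length=4000):
    spec = FixtureSpec(
        length, seed=seed, read_length=50,
        repeat_families=(
            RepeatFamily(2, unit, divergence=len(divergence_offsets),
                         divergence_offsets=divergence_offsets),
        ),
    )
    return make_genome(spec)


class TestExtraction:
    def test_single_divergent_site_yields_directed_pair(self):
        # unit short enough that every copy-flank read also spans the
        # divergent site, so only the two directed site records appear
        genome, truth = diverged_pair(seed=51, divergence_offsets=(45,), unit=90)
        _, regions, multi = profile(genome, 50, 1)
        ann = extract_intragenomic_snvs(multi, genome)
        site = truth.divergent_sites[0]
        keys = {(s.chrom, s.pos, s.ref_base, s.alt_base) for s in ann.snvs}
        p0, p1 = site.positions
        a0, a1 = site.alleles
        assert keys == {("chr1", p0, a0, a1), ("chr1", p1, a1, a0)}

    def test_identical_copies_yield_empty_annotation(self):
        spec = FixtureSpec(3000, seed=52, read_length=25,
                           repeat_families=(RepeatFamily(2, 100),))
        genome, _ = make_genome(spec)
        _, _, multi = profile(genome, 25, 0)
        assert multi, "identical copies must cross-align"
        ann = extract_intragenomic_snvs(multi, genome)
        assert len(ann) == 0

    def test_d_sites_give_2d_records_matching_planted_truth(self):
        offsets = (25, 60, 95)  # each within a read length of both unit ends
        genome, truth = diverged_pair(seed=53, divergence_offsets=offsets)
        _, _, multi = profile(genome, 50, 1)
        ann = extract_intragenomic_snvs(multi, genome)
        assert len(ann) == 2 * len(offsets)
        expected = set()
        for site in truth.divergent_sites:
            p0, p1 = site.positions
            a0, a1 = site.alleles
            expected |= {("chr1", p0, a0, a1), ("chr1", p1, a1, a0)}
        assert {(s.chrom, s.pos, s.ref_base, s.alt_base) for s in ann.snvs} == expected

    def test_base_space_annotation_matches_bruteforce_oracle(self):
        genome, _ = diverged_pair(seed=54, divergence_offsets=(25, 95))
        _, _, multi = profile(genome, 50, 1)
        ann = extract_intragenomic_snvs(multi, genome)
        keys = {(s.chrom, s.pos, s.ref_base, s.alt_base) for s in ann.snvs}
        assert keys == oracle_snvs(genome, 50, 1)

    def test_color_space_run_recovers_planted_sites(self):
        # one base substitution costs two adjacent color mismatches, so a
        # color-space run needs k >= 2 to cross-align over one SNV
        genome, truth = diverged_pair(seed=54, divergence_offsets=(25, 95))
        _, _, multi = profile(genome, 50, 2, "color")
        ann = extract_intragenomic_snvs(multi, genome, "color")
        keys = {(s.chrom, s.pos, s.ref_base, s.alt_base) for s in ann.snvs}
        expected = set()
        for site in truth.divergent_sites:
            p0, p1 = site.positions
            a0, a1 = site.alleles
            expected |= {("chr1", p0, a0, a1), ("chr1", p1, a1, a0)}
        assert expected <= keys
        copy_spans = [(c.start, c.end) for c in truth.copies]
        inside = {
            k for k in keys if any(s <= k[1] <= e for s, e in copy_spans)
        }
        assert inside == expected

    def test_unique_alignment_with_mismatch_is_inconsistent(self):
        genome, _ = diverged_pair(seed=55, divergence_offsets=(60,))
        bad = AlignmentSet(
            "x", [Alignment("x", "chr1", 10, "+", 50, ((3, "A", "C"),))]
        )
        with pytest.raises(InternalConsistencyError):
            extract_intragenomic_snvs([bad], genome)


class TestGenomicMismatchMapping:
    def test_reverse_strand_base_mapping(self):
        from conftest import random_genome
        from gdenoise import reverse_complement

        genome = random_genome(56, 500)
        seq = genome.sequence("c1")
        window = seq[100:130]
        read = list(reverse_complement(window))
        read[7] = "A" if read[7] != "A" else "C"  # substitution in read orientation
        aset = align_all(("r", "".join(read)), genome, 2)
        aln = [a for a in aset.alignments if a.strand == "-"][0]
        (pos, ref, alt) = genomic_mismatches(aln, genome)[0]
        assert seq[pos - 1] == ref
        assert alt == reverse_complement(read[7])
        assert pos == aln.start + (30 - 1 - 7)


class TestGDenoise:
    def test_cross_copy_reads_become_unique(self):
        # Fig-5-style scenario: two near-exact copies, one divergent site
        genome, truth = diverged_pair(seed=57, divergence_offsets=(60,))
        _, _, multi = profile(genome, 50, 1)
        ann = extract_intragenomic_snvs(multi, genome)
        site = truth.divergent_sites[0]
        rescued = 0
        for aset in multi:
            res = g_denoise(aset, ann)
            if res.became_unique:
                kept = res.kept[0]
                # the kept alignment is the perfect (origin) placement
                assert kept.n_mismatch == 0
                rescued += 1
            assert len(res.kept) + len(res.discarded) == aset.n
        assert rescued > 0

    def test_unique_set_passes_through_unchanged(self):
        genome, _ = diverged_pair(seed=58, divergence_offsets=(60,))
        ann = SnvAnnotation(genome)
        aset = AlignmentSet("u", [Alignment("u", "chr1", 5, "+", 50, ())])
        res = g_denoise(aset, ann)
        assert res.kept == aset.alignments and not res.became_unique

    def test_filter_never_grows_a_set(self):
        genome, _ = diverged_pair(seed=59, divergence_offsets=(25, 95))
        _, _, multi = profile(genome, 50, 1)
        ann = extract_intragenomic_snvs(multi, genome)
        for aset in multi:
            res = g_denoise(aset, ann)
            assert len(res.kept) <= aset.n

    def test_novel_alt_at_annotated_position_is_not_filtered(self):
        # an acquired change to a third base at a known variable position
        # must remain visible: matching is exact on (pos, ref, alt)
        genome, truth = diverged_pair(seed=60, divergence_offsets=(60,))
        ann = SnvAnnotation(genome)
        site = truth.divergent_sites[0]
        pos, ref = site.positions[0], site.alleles[0]
        ann.add("chr1", pos, ref, site.alleles[1])
        third = next(b for b in "ACGT" if b not in site.alleles)
        aln = Alignment("x", "chr1", pos - 10, "+", 50, ((10, ref, third),))
        other = Alignment("x", "chr1", 1, "+", 50, ())
        res = g_denoise(AlignmentSet("x", [aln, other]), ann)
        assert aln in res.kept

    def test_mutated_read_keeps_origin_discards_cross_copy(self):
        spec = FixtureSpec(
            4000, seed=61, read_length=50,
            repeat_families=(RepeatFamily(2, 120, divergence=2,
                                          divergence_offsets=(45, 75)),),
            planted_mutations=(PlantedMutation(0, 0, 60, None),),
        )
        genome, truth = make_genome(spec)
        _, _, multi = profile(genome, 50, 3)
        ann = extract_intragenomic_snvs(multi, genome)
        chrom, pos, ref, alt = truth.mutations[0]
        sample = apply_mutations(genome, truth.mutations)
        # read from the mutated copy spanning the mutation and a flanking SNV
        read = sample.sequence(chrom)[pos - 30 : pos + 20]
        aset = align_all(("m", read), genome, 3)
        assert aset.n > 1
        res = g_denoise(aset, ann)
        assert res.became_unique
        assert res.kept[0].start == pos - 29


class TestClassifyMuMm:
    def test_identical_copies_are_entirely_mm(self):
        spec = FixtureSpec(3000, seed=62, read_length=25,
                           repeat_families=(RepeatFamily(2, 100),))
        genome, _ = make_genome(spec)
        _, regions, multi = profile(genome, 25, 0)
        ann = extract_intragenomic_snvs(multi, genome)
        labeled = classify_mu_mm(multi, ann, regions)
        assert labeled and all(r.label == "M_M" for r in labeled)

    def test_divergent_site_creates_mu_subregions(self):
        genome, truth = diverged_pair(seed=63, divergence_offsets=(60,))
        _, regions, multi = profile(genome, 50, 1)
        ann = extract_intragenomic_snvs(multi, genome)
        labeled = classify_mu_mm(multi, ann, regions)
        mu = [r for r in labeled if r.label == "M_U"]
        assert mu, "expected M_U sub-regions around the divergent site"
        positions = {p for site in truth.divergent_sites for p in site.positions}
        assert any(r.start <= p <= r.end for r in mu for p in positions)

    def test_mu_plus_mm_tiles_m_exactly(self):
        genome, _ = diverged_pair(seed=64, divergence_offsets=(25, 95))
        _, regions, multi = profile(genome, 50, 1)
        ann = extract_intragenomic_snvs(multi, genome)
        labeled = classify_mu_mm(multi, ann, regions)
        m_total = sum(r.length for r in regions if r.label == "M")
        assert sum(r.length for r in labeled) == m_total
        covered = set()
        for r in labeled:
            span = set(range(r.start, r.end + 1))
            assert not span & covered
            covered |= span
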
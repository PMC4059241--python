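"""Coverage tracks, U/M region calling, sweep and coverage correlation."""

import numpy as np
import pytest

from gdenoise import (
    ReferenceGenome,
    align_batch,
    build_coverage,
    call_m_regions,
    coverage_of_generation,
    generate_virtual_reads,
    profile,
    region_length_stats,
    sweep,
    windowed_coverage_correlation,
)
from gdenoise.fixtures import (
    FixtureSpec,
    RepeatFamily,
    make_genome,
    oracle_m_intervals,
    simulate_reads,
)
from gdenoise.um_annotator import CoverageTrack, Region

from conftest import random_genome


def m_intervals(regions):
    return {
        chrom: [(r.start, r.end) for r in regions if r.chrom == chrom and r.label == "M"]
        for chrom in {r.chrom for r in regions}
    }


def make_track(ambiguous, chrom="c1"):
    amb = np.asarray(ambiguous)
    total = np.maximum(amb, 1)
    return CoverageTrack(
        chrom=chrom,
        total=total,
        forward=total,
        reverse=np.zeros_like(total),
        ambiguous=amb,
        undefined_mask=np.zeros(len(amb), dtype=bool),
    )


class TestBuildCoverage:
    def test_repeat_free_genome_has_zero_ambiguous_coverage(self):
        genome = random_genome(40, 1200)
        sets = align_batch(generate_virtual_reads(genome, 25), genome, 0)
        track = build_coverage(sets, genome)["c1"]
        assert track.ambiguous.sum() == 0

    def test_total_equals_generation_ramp_on_repeat_free_genome(self):
        genome = random_genome(41, 900)
        sets = align_batch(generate_virtual_reads(genome, 30), genome, 0)
        track = build_coverage(sets, genome)["c1"]
        expected = coverage_of_generation(genome, 30)["c1"]
        assert np.array_equal(track.total, expected)

    def test_forward_plus_reverse_equals_total(self):
        spec = FixtureSpec(3000, seed=42, read_length=25,
                           repeat_families=(RepeatFamily(2, 100),))
        genome, _ = make_genome(spec)
        sets = align_batch(generate_virtual_reads(genome, 25), genome, 0)
        track = build_coverage(sets, genome)["chr1"]
        assert np.array_equal(track.total, track.forward + track.reverse)
        assert (track.ambiguous <= track.total).all()

    def test_out_of_bounds_alignment_rejected(self):
        from gdenoise.aligner import Alignment, AlignmentSet

        genome = random_genome(43, 100)
        bad = AlignmentSet("x", [Alignment("x", "c1", 90, "+", 20, ())])
        with pytest.raises(ValueError, match="beyond chromosome end"):
            build_coverage([bad], genome)


class TestCallMRegions:
    def test_no_ambiguity_gives_single_u_region(self):
        regions = call_m_regions(make_track(np.zeros(1000, dtype=int)))
        assert regions == [Region("c1", 1, 1000, "U")]

    def test_one_nucleotide_u_region_between_m_regions(self):
        amb = np.ones(201, dtype=int)
        amb[100] = 0  # single non-ambiguous base splits two M regions
        regions = call_m_regions(make_track(amb))
        assert Region("c1", 101, 101, "U") in regions
        assert [r.label for r in regions] == ["M", "U", "M"]

    def test_n_runs_labeled_undefined(self):
        genome = ReferenceGenome([("a", "ACGTACGT" + "N" * 5 + "ACGTACGT")])
        sets = align_batch(generate_virtual_reads(genome, 4), genome, 0)
        regions = call_m_regions(build_coverage(sets, genome))
        assert Region("a", 9, 13, "undefined") in regions

    def test_planted_duplication_matches_oracle(self):
        spec = FixtureSpec(4000, seed=7, read_length=25,
                           repeat_families=(RepeatFamily(2, 200),))
        genome, truth = make_genome(spec)
        _, regions, _ = profile(genome, 25, 0)
        assert m_intervals(regions) == oracle_m_intervals(genome, 25, 0)

    def test_partition_tiles_chromosome(self):
        spec = FixtureSpec(3000, seed=8, read_length=25,
                           repeat_families=(RepeatFamily(2, 150),))
        genome, _ = make_genome(spec)
        _, regions, _ = profile(genome, 25, 1)
        covered = np.zeros(3000, dtype=int)
        for reg in regions:
            covered[reg.start - 1 : reg.end] += 1
        assert (covered == 1).all()


class TestSweep:
    def test_repeat_free_genome_has_zero_m_fraction(self):
        genome = random_genome(44, 1500)
        table = sweep(genome, [20, 25], [0])
        assert (table["m_fraction"] == 0).all()

    def test_m_length_non_increasing_in_read_length(self):
        spec = FixtureSpec(4000, seed=9, read_length=25,
                           repeat_families=(RepeatFamily(2, 200),))
        genome, _ = make_genome(spec)
        table = sweep(genome, [25, 35, 50], [0])
        lengths = table.sort_values("read_length")["m_total_length"].tolist()
        assert lengths == sorted(lengths, reverse=True)

    def test_m_length_non_decreasing_in_mismatches(self):
        spec = FixtureSpec(4000, seed=10, read_length=25,
                           repeat_families=(RepeatFamily(2, 200, divergence=1),))
        genome, _ = make_genome(spec)
        table = sweep(genome, [25], [0, 1, 2])
        lengths = table.sort_values("max_mismatches")["m_total_length"].tolist()
        assert lengths == sorted(lengths)

    def test_m_lengths_at_least_read_length(self):
        spec = FixtureSpec(4000, seed=11, read_length=25,
                           repeat_families=(RepeatFamily(3, 120),))
        genome, _ = make_genome(spec)
        _, regions, _ = profile(genome, 25, 0)
        assert all(r.length >= 25 for r in regions if r.label == "M")


class TestRegionLengthStats:
    def test_empty_region_list(self):
        stats = region_length_stats([])
        assert stats.n == 0 and stats.total == 0 and stats.min is None

    def test_totals_match_sweep_cumulative_length(self):
        spec = FixtureSpec(4000, seed=12, read_length=25,
                           repeat_families=(RepeatFamily(2, 180),))
        genome, _ = make_genome(spec)
        _, regions, _ = profile(genome, 25, 0)
        m = [r for r in regions if r.label == "M"]
        stats = region_length_stats(m)
        table = sweep(genome, [25], [0])
        assert stats.total == table["m_total_length"].iloc[0]
        assert stats.counts.sum() == stats.n == len(m)


class TestWindowedCorrelation:
    def _tracks(self, seed, length=8000):
        spec = FixtureSpec(length, seed=seed, read_length=25,
                           repeat_families=(RepeatFamily(6, 400),))
        genome, _ = make_genome(spec)
        tracks, _, _ = profile(genome, 25, 0)
        return genome, tracks

    def test_self_correlation_is_one(self):
        _, tracks = self._tracks(13)
        assert windowed_coverage_correlation(tracks, tracks, 500) == pytest.approx(1.0)

    def test_scaling_invariance(self):
        _, tracks = self._tracks(14)
        doubled = {
            c: CoverageTrack(c, t.total * 2, t.forward * 2, t.reverse * 2,
                             t.ambiguous * 2, t.undefined_mask)
            for c, t in tracks.items()
        }
        r2 = windowed_coverage_correlation(tracks, doubled, 500)
        # the +1 pseudocount makes log-scaling only approximately affine
        assert r2 == pytest.approx(1.0, abs=1e-4)

    def test_simulated_uniform_experimental_profile_correlates(self):
        genome, tracks = self._tracks(15)
        reads = simulate_reads(genome, 25, 60.0, error_rate=0.0, seed=3)
        exp = build_coverage(align_batch(reads, genome, 0), genome)
        r2 = windowed_coverage_correlation(tracks, exp, 200)
        assert r2 >= 0.99

    def test_too_few_windows_rejected(self):
        _, tracks = self._tracks(16)
        with pytest.raises(ValueError, match="windows"):
            windowed_coverage_correlation(tracks, tracks, 10**6)

    def test_window_below_one_rejected(self):
        _, tracks = self._tracks(16)
        with pytest.raises(ValueError):
            windowed_coverage_correlation(tracks, tracks, 0)
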
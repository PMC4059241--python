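"""Coverage tracks and single-nucleotide-resolution U/M annotation.

A virtual read with more than one reported alignment is multialigned;
after discarding the unique alignments, the genomic positions still
covered by the remaining "ambiguous" alignments form the M regions, and
the complementary stretches between consecutive M regions are the U
regions.  Positions inside N runs are labeled ``undefined`` and belong to
neither class.  Because every read overlapping a repeat is multialigned,
M regions extend up to ``r - 1`` nt beyond the exact repeat boundary and
are never shorter than the read length; a U region, by contrast, can be
as short as a single nucleotide between two flanking M regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aligner import AlignmentSet, align_batch
from .sequence_model import ReferenceGenome
from .virtual_reads import generate_virtual_reads

__all__ = [
    "CoverageTrack",
    "Region",
    "build_coverage",
    "call_m_regions",
    "sweep",
    "region_length_stats",
    "windowed_coverage_correlation",
    "write_regions_bed",
    "write_regions_tsv",
    "write_bedgraph",
]


@dataclass
class CoverageTrack:
    """Per-position alignment coverage for one chromosome.

    ``ambiguous`` counts only alignments of multialigned reads; the M
    regions are exactly the positions where it is >= 1.
    """

    chrom: str
    total: np.ndarray
    forward: np.ndarray
    reverse: np.ndarray
    ambiguous: np.ndarray
    undefined_mask: np.ndarray  # True inside N runs

    def __post_init__(self) -> None:
        if not np.array_equal(self.total, self.forward + self.reverse):
            raise ValueError("total coverage must equal forward + reverse")
        if (self.ambiguous > self.total).any():
            raise ValueError("ambiguous coverage cannot exceed total")


@dataclass(frozen=True)
class Region:
    """A labeled maximal interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    label: str  # U, M, M_U, M_M, undefined

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def build_coverage(
    alignment_sets: Iterable[AlignmentSet],
    genome: ReferenceGenome,
) -> dict[str, CoverageTrack]:
    """Accumulate total/strand/ambiguous coverage from alignment sets.

    Each alignment increments positions ``start .. start + r - 1``;
    alignments of multialigned sets additionally increment the
    ambiguous-only track.
    """
    L = genome.lengths
    fwd = {c: np.zeros(n + 1, dtype=np.int64) for c, n in L.items()}
    rev = {c: np.zeros(n + 1, dtype=np.int64) for c, n in L.items()}
    amb = {c: np.zeros(n + 1, dtype=np.int64) for c, n in L.items()}
    for aset in alignment_sets:
        multi = aset.is_multialigned
        for aln in aset.alignments:
            if aln.chrom not in L:
                raise ValueError(f"alignment on unknown chromosome {aln.chrom!r}")
            if aln.end > L[aln.chrom] or aln.start < 1:
                raise ValueError(
                    f"alignment {aln.read_id} at {aln.chrom}:{aln.start} "
                    "extends beyond chromosome end (corrupt input)"
                )
            s0, e0 = aln.start - 1, aln.end
            target = fwd if aln.strand == "+" else rev
            target[aln.chrom][s0] += 1
            target[aln.chrom][e0] -= 1
            if multi:
                amb[aln.chrom][s0] += 1
                amb[aln.chrom][e0] -= 1
    tracks = {}
    for chrom in genome.names:
        f = np.cumsum(fwd[chrom][:-1])
        r = np.cumsum(rev[chrom][:-1])
        a = np.cumsum(amb[chrom][:-1])
        tracks[chrom] = CoverageTrack(
            chrom=chrom,
            total=f + r,
            forward=f,
            reverse=r,
            ambiguous=a,
            undefined_mask=genome.n_mask(chrom),
        )
    return tracks


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values as (value, start0, end0-inclusive)."""
    if len(labels) == 0:
        return []
    change = np.nonzero(np.diff(labels))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(labels) - 1]))
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


_LABELS = {0: "U", 1: "M", 2: "undefined"}


def call_m_regions(
    tracks: Mapping[str, CoverageTrack] | CoverageTrack,
) -> list[Region]:
    """Maximal M runs (ambiguous coverage >= 1) and complementary U runs.

    N runs yield ``undefined`` regions.  Adjacent same-label runs are
    merged by construction; per chromosome the output tiles the sequence.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.chrom: tracks}
    regions: list[Region] = []
    for chrom, track in tracks.items():
        lab = np.zeros(len(track.total), dtype=np.int8)
        lab[track.ambiguous >= 1] = 1
        lab[track.undefined_mask] = 2
        for value, s0, e0 in _runs(lab):
            regions.append(Region(chrom, s0 + 1, e0 + 1, _LABELS[value]))
    return regions


def profile(
    genome: ReferenceGenome,
    read_length: int,
    k: int,
    space: str = "base",
):
    """Run the virtual-HTS profiling chain on a genome.

    Generates the exhaustive virtual reads, aligns them with ``k``
    tolerated mismatches, builds coverage and calls U/M regions.  Returns
    ``(tracks, regions, multi_sets)`` where ``multi_sets`` holds only the
    multialigned alignment sets (the input to SNV annotation and M_U/M_M
    classification); unique sets are folded into coverage and dropped.
    """
    multi_sets: list[AlignmentSet] = []

    def tee(sets):
        for aset in sets:
            if aset.is_multialigned:
                multi_sets.append(aset)
            yield aset

    reads = generate_virtual_reads(genome, read_length, space)
    sets = align_batch(reads, genome, k, space)
    tracks = build_coverage(tee(sets), genome)
    regions = call_m_regions(tracks)
    return tracks, regions, multi_sets


def sweep(
    genome: ReferenceGenome,
    read_lengths: Sequence[int],
    k_values: Sequence[int],
    space: str = "base",
) -> pd.DataFrame:
    """Profile the genome over a read-length x mismatch grid.

    One row per (r, k) with the cumulative M length, M region count and
    the M fraction of the non-N genome.
    """
    non_n = genome.non_n_length()
    rows = []
    for r in read_lengths:
        for k in k_values:
            _, regions, _ = profile(genome, r, k, space)
            m = [reg for reg in regions if reg.label == "M"]
            m_len = sum(reg.length for reg in m)
            rows.append(
                {
                    "read_length": r,
                    "max_mismatches": k,
                    "m_total_length": m_len,
                    "m_count": len(m),
                    "m_fraction": m_len / non_n if non_n else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RegionLengthStats:
    counts: pd.Series  # length -> number of regions
    min: int | None
    max: int | None
    total: int
    n: int


def region_length_stats(regions: Sequence[Region]) -> RegionLengthStats:
    """Length histogram and extremes for one run's regions."""
    lengths = pd.Series([r.length for r in regions], dtype=int)
    if lengths.empty:
        return RegionLengthStats(pd.Series(dtype=int), None, None, 0, 0)
    return RegionLengthStats(
        counts=lengths.value_counts().sort_index(),
        min=int(lengths.min()),
        max=int(lengths.max()),
        total=int(lengths.sum()),
        n=len(lengths),
    )


def _window_means(track: CoverageTrack, window: int) -> list[float]:
    cov = track.total
    means = []
    pos = 0
    L = len(cov)
    while pos < L:
        chunk = cov[pos : pos + window]
        if len(chunk) == window or len(chunk) * 2 >= window:
            means.append(float(chunk.mean()))
        pos += window
    return means


def windowed_coverage_correlation(
    tracks_a: Mapping[str, CoverageTrack],
    tracks_b: Mapping[str, CoverageTrack],
    window: int = 2000,
) -> float:
    """Squared Pearson correlation of log10 windowed mean coverage.

    Windows are non-overlapping, tiled from position 1 per chromosome; a
    trailing partial window is kept when it spans at least half the
    window size.  A pseudocount of 1 is added before the log10 transform
    so zero-coverage windows are retained.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if set(tracks_a) != set(tracks_b):
        raise ValueError("coverage tracks cover different chromosome sets")
    xs: list[float] = []
    ys: list[float] = []
    for chrom in tracks_a:
        xs.extend(_window_means(tracks_a[chrom], window))
        ys.extend(_window_means(tracks_b[chrom], window))
    if len(xs) < 2:
        raise ValueError("need at least 2 windows to correlate")
    lx = np.log10(np.asarray(xs) + 1.0)
    ly = np.log10(np.asarray(ys) + 1.0)
    if np.allclose(lx, lx[0]) or np.allclose(ly, ly[0]):
        # constant tracks: identical -> perfect agreement, else undefined
        return 1.0 if np.allclose(lx, ly) else float("nan")
    r, _ = stats.pearsonr(lx, ly)
    return float(r**2)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Sequence[Region], path: str | Path) -> None:
    """BED (0-based half-open) with the label in the name field."""
    with open(path, "w") as fh:
        for reg in regions:
            fh.write(f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\t{reg.label}\n")


def write_regions_tsv(regions: Sequence[Region], path: str | Path) -> None:
    """1-based inclusive TSV: chrom, start, end, label."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\n")
        for reg in regions:
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.label}\n")


def write_bedgraph(
    tracks: Mapping[str, CoverageTrack],
    path: str | Path,
    which: str = "total",
) -> None:
    with open(path, "w") as fh:
        for chrom, track in tracks.items():
            cov = getattr(track, which)
            for value, s0, e0 in _runs(cov):
                fh.write(f"{chrom}\t{s0}\t{e0 + 1}\t{value}\n")
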
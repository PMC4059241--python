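"""Intragenomic SNV annotation and the g-deNoise multialignment filter.

Because virtual reads are error-free copies of the reference, any
mismatch appearing in an alignment of a multialigned virtual read can
only reflect a single-base difference between near-identical repeat
copies — an *intragenomic SNV*.  Recording every such mismatch (mapped to
forward-genome coordinates and bases) yields a directed per-locus
annotation: at each variable position of a repeat copy, the reference
base there and the base carried by the partner copy.

g-deNoise uses the annotation as a signature of cross-copy placement: an
alignment is discarded iff one of its mismatches matches an annotated
SNV exactly on (chrom, pos, ref, alt).  A different alternative base at
an annotated position is *not* filtered — an acquired mutation to a
third base at a known variable position remains detectable.  Reads whose
cross-copy placements are all discarded become uniquely aligned; M
sub-regions where this deconvolution succeeds everywhere are labeled
M_U, the rest M_M.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aligner import Alignment, AlignmentSet
from .sequence_model import BASE_CODE, _CODE_BASE, ReferenceGenome, reverse_complement
from .um_annotator import Region, _runs

__all__ = [
    "IntragenomicSNV",
    "SnvAnnotation",
    "DenoiseResult",
    "InternalConsistencyError",
    "extract_intragenomic_snvs",
    "g_denoise",
    "classify_mu_mm",
    "genomic_mismatches",
]


class InternalConsistencyError(RuntimeError):
    """A unique alignment of an error-free virtual read carried mismatches."""


@dataclass(frozen=True)
class IntragenomicSNV:
    """A genomic position where a repeat copy elsewhere carries a
    different base; ``support`` counts distinct attesting multialignments."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    support: int = 1


def genomic_mismatches(
    aln: Alignment, genome: ReferenceGenome
) -> list[tuple[int, str, str]]:
    """Map an alignment's mismatches to ``(pos, ref_base, alt_base)`` in
    forward-genome coordinates and bases.

    Base space: direct strand mapping of each recorded mismatch.  Color
    space: only *isolated adjacent pairs* of color mismatches encode a
    base substitution; the pair is decoded against the reference and kept
    only when the two colors imply a consistent substituted base.
    Isolated single color mismatches (and longer runs) are treated as
    non-SNV mismatches and yield nothing.
    """
    out: list[tuple[int, str, str]] = []
    r = aln.length
    if aln.space == "base":
        for q, ref_base, read_base in aln.mismatches:
            if aln.strand == "+":
                pos = aln.start + q
                alt = read_base
            else:
                pos = aln.start + (r - 1 - q)
                alt = reverse_complement(read_base)
            out.append((pos, ref_base, alt))
        return out

    # color space: window-orientation color offsets
    m = r - 1
    window_offsets: dict[int, int] = {}
    for q, _ref_color, read_color in aln.mismatches:
        j = q if aln.strand == "+" else m - 1 - q
        window_offsets[j] = int(read_color)
    gcodes = genome.codes(aln.chrom)
    p0 = aln.start - 1
    offsets = sorted(window_offsets)
    i = 0
    while i < len(offsets):
        run = [offsets[i]]
        while i + 1 < len(offsets) and offsets[i + 1] == offsets[i] + 1:
            i += 1
            run.append(offsets[i])
        i += 1
        if len(run) != 2:
            continue  # isolated color change or longer run: not a clean SNV
        j = run[0]
        left = int(gcodes[p0 + j])
        mid = int(gcodes[p0 + j + 1])
        right = int(gcodes[p0 + j + 2])
        if left > 3 or mid > 3 or right > 3:
            continue
        x1 = left ^ window_offsets[j]
        x2 = right ^ window_offsets[j + 1]
        if x1 != x2 or x1 > 3 or x1 == mid:
            continue
        out.append((aln.start + j + 1, _CODE_BASE[mid], _CODE_BASE[x1]))
    return out


class SnvAnnotation:
    """Directed intragenomic SNV records indexed for exact matching."""

    def __init__(self, genome: ReferenceGenome, space: str = "base") -> None:
        self.genome = genome
        self.space = space
        self._index: dict[tuple[str, int, str, str], int] = {}

    def add(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        key = (chrom, pos, ref, alt)
        self._index[key] = self._index.get(key, 0) + 1

    def contains(self, chrom: str, pos: int, ref: str, alt: str) -> bool:
        return (chrom, pos, ref, alt) in self._index

    @property
    def snvs(self) -> list[IntragenomicSNV]:
        return [
            IntragenomicSNV(c, p, r, a, n)
            for (c, p, r, a), n in sorted(self._index.items())
        ]

    def __len__(self) -> int:
        return len(self._index)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tsupport\n")
            for s in self.snvs:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_base}\t{s.alt_base}\t{s.support}\n")


def extract_intragenomic_snvs(
    alignment_sets: Iterable[AlignmentSet],
    genome: ReferenceGenome,
    space: str = "base",
) -> SnvAnnotation:
    """Harvest intragenomic SNVs from a virtual (error-free) run.

    Only multialigned sets contribute; every mismatch of every alignment
    maps to one directed SNV record, with duplicates merged into support
    counts.  A unique alignment carrying mismatches is impossible for an
    error-free read aligned to its own genome and raises
    :class:`InternalConsistencyError`.
    """
    annotation = SnvAnnotation(genome, space)
    for aset in alignment_sets:
        if aset.n == 1 and aset.alignments[0].n_mismatch > 0:
            raise InternalConsistencyError(
                f"virtual read {aset.read_id} is uniquely aligned with "
                "mismatches; virtual runs must be error-free"
            )
        if not aset.is_multialigned:
            continue
        for aln in aset.alignments:
            for pos, ref, alt in genomic_mismatches(aln, genome):
                if ref == alt:
                    continue
                annotation.add(aln.chrom, pos, ref, alt)
    return annotation


@dataclass
class DenoiseResult:
    """Outcome of g-deNoise on one alignment set."""

    read_id: str
    kept: list[Alignment]
    discarded: list[Alignment]
    became_unique: bool

    @property
    def kept_set(self) -> AlignmentSet:
        return AlignmentSet(self.read_id, list(self.kept))


def g_denoise(aset: AlignmentSet, annotation: SnvAnnotation) -> DenoiseResult:
    """Discard alignments consistent with annotated intragenomic SNVs.

    An alignment is discarded iff any of its mismatches matches an
    annotated SNV on (chrom, pos, ref, alt) exactly — even if it also
    carries non-annotated mismatches.  Unique input sets pass through
    unchanged.  Applies identically to virtual and experimental sets.
    """
    if aset.n <= 1:
        return DenoiseResult(aset.read_id, list(aset.alignments), [], False)
    kept: list[Alignment] = []
    discarded: list[Alignment] = []
    for aln in aset.alignments:
        hit = any(
            annotation.contains(aln.chrom, pos, ref, alt)
            for pos, ref, alt in genomic_mismatches(aln, annotation.genome)
        )
        (discarded if hit else kept).append(aln)
    return DenoiseResult(aset.read_id, kept, discarded, len(kept) == 1)


def classify_mu_mm(
    alignment_sets: Iterable[AlignmentSet],
    annotation: SnvAnnotation,
    m_regions: Sequence[Region],
) -> list[Region]:
    """Split M regions into deconvoluted (M_U) and residual (M_M) parts.

    After g-deNoise on the virtual run, any position still covered by a
    remaining multialignment is M_M; the rest of each M region is M_U.
    The output tiles the input M regions exactly.
    """
    genome = annotation.genome
    residual = {c: np.zeros(n + 1, dtype=np.int64) for c, n in genome.lengths.items()}
    for aset in alignment_sets:
        if not aset.is_multialigned:
            continue
        result = g_denoise(aset, annotation)
        if len(result.kept) > 1:
            for aln in result.kept:
                residual[aln.chrom][aln.start - 1] += 1
                residual[aln.chrom][aln.end] -= 1
    marked = {c: np.cumsum(d[:-1]) >= 1 for c, d in residual.items()}
    out: list[Region] = []
    for reg in m_regions:
        if reg.label != "M":
            continue
        sub = marked[reg.chrom][reg.start - 1 : reg.end].astype(np.int8)
        for value, s0, e0 in _runs(sub):
            label = "M_M" if value else "M_U"
            out.append(Region(reg.chrom, reg.start + s0, reg.start + e0, label))
    return out
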
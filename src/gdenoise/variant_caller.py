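"""Strand-aware SNP calling in unique and deconvoluted repeat regions.

Two closed-threshold rules, applied to pileups of *unique* alignments
only:

* U regions — the base change must be seen in at least 70% of the unique
  alignments covering the position and be supported on both strands.
* M regions (after g-deNoise) — the change must be supported by at least
  10 unique alignments on each strand arising from at least 5 distinct
  alignment starting points, and must not fall in a masked homopolymer
  or microsatellite tract.

Across samples, a variant present in every sample is *constitutive*, one
present in exactly one sample is *acquired*; anything in between is
reported as *shared*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import Alignment
from .sequence_model import BASE_CODE, _CODE_BASE, ReferenceGenome, reverse_complement
from .um_annotator import Region

__all__ = [
    "PileupColumn",
    "VariantCall",
    "SampleComparison",
    "pileup",
    "call_u_snps",
    "call_m_snps",
    "mask_low_complexity",
    "compare_samples",
    "write_vcf",
]


@dataclass
class PileupColumn:
    """Strand-split base counts at one position, from unique alignments.

    ``alt_starts`` maps each non-reference base to the set of distinct
    ``(start, strand)`` pairs of the alignments supporting it.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, tuple[int, int]]  # base -> (fwd, rev)
    alt_starts: dict[str, set[tuple[int, str]]]

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())


def _aligned_codes(aln: Alignment, genome: ReferenceGenome) -> np.ndarray:
    """Base codes deposited on the forward genome strand by ``aln``."""
    codes = genome.codes(aln.chrom)[aln.start - 1 : aln.end].copy()
    for q, _ref, read_base in aln.mismatches:
        if aln.strand == "+":
            codes[q] = BASE_CODE[read_base]
        else:
            codes[aln.length - 1 - q] = BASE_CODE[reverse_complement(read_base)]
    return codes


def pileup(
    unique_alignments: Iterable[Alignment],
    genome: ReferenceGenome,
    regions: Sequence[Region] | None = None,
) -> list[PileupColumn]:
    """Pile up unique alignments into strand-split per-base columns.

    ``regions`` optionally restricts the emitted columns to the given
    intervals.  Columns are emitted for every covered position.
    """
    L = genome.lengths
    fwd = {c: np.zeros((4, n), dtype=np.int32) for c, n in L.items()}
    rev = {c: np.zeros((4, n), dtype=np.int32) for c, n in L.items()}
    starts: dict[tuple[str, int, int], set[tuple[int, str]]] = {}
    for aln in unique_alignments:
        if aln.chrom not in L:
            raise ValueError(f"alignment on unknown chromosome {aln.chrom!r}")
        if aln.start < 1 or aln.end > L[aln.chrom]:
            raise ValueError(
                f"alignment {aln.read_id} out of bounds at {aln.chrom}:{aln.start}"
            )
        codes = _aligned_codes(aln, genome)
        positions = np.arange(aln.start - 1, aln.end)
        valid = codes <= 3
        target = fwd if aln.strand == "+" else rev
        np.add.at(target[aln.chrom], (codes[valid], positions[valid]), 1)
        refcodes = genome.codes(aln.chrom)[aln.start - 1 : aln.end]
        for j in np.nonzero(valid & (codes != refcodes))[0]:
            key = (aln.chrom, int(positions[j]), int(codes[j]))
            starts.setdefault(key, set()).add((aln.start, aln.strand))

    keep: dict[str, np.ndarray] | None = None
    if regions is not None:
        keep = {c: np.zeros(n, dtype=bool) for c, n in L.items()}
        for reg in regions:
            keep[reg.chrom][reg.start - 1 : reg.end] = True

    columns: list[PileupColumn] = []
    for chrom in genome.names:
        total = fwd[chrom].sum(axis=0) + rev[chrom].sum(axis=0)
        covered = np.nonzero(total > 0)[0]
        refc = genome.codes(chrom)
        for p0 in covered:
            if keep is not None and not keep[chrom][p0]:
                continue
            counts = {}
            alt_starts = {}
            for b in range(4):
                f = int(fwd[chrom][b, p0])
                r = int(rev[chrom][b, p0])
                if f or r:
                    counts[_CODE_BASE[b]] = (f, r)
                    if b != refc[p0]:
                        alt_starts[_CODE_BASE[b]] = starts.get(
                            (chrom, int(p0), b), set()
                        )
            columns.append(
                PileupColumn(
                    chrom=chrom,
                    pos=int(p0) + 1,
                    ref_base=_CODE_BASE[refc[p0]] if refc[p0] <= 3 else "N",
                    counts=counts,
                    alt_starts=alt_starts,
                )
            )
    return columns


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    fwd_support: int
    rev_support: int
    distinct_starts: int
    allele_fraction: float
    region_label: str  # U or M_U
    masked: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


def call_u_snps(
    columns: Iterable[PileupColumn],
    min_fraction: float = 0.70,
) -> list[VariantCall]:
    """U-region rule: alt fraction >= ``min_fraction`` of unique
    alignments at the position, supported on both strands.  Thresholds
    are closed (exactly 70% passes)."""
    calls = []
    for col in columns:
        total = col.depth
        if total == 0:
            continue
        for alt, (f, r) in col.counts.items():
            if alt == col.ref_base or col.ref_base == "N":
                continue
            fraction = (f + r) / total
            if fraction >= min_fraction and f >= 1 and r >= 1:
                calls.append(
                    VariantCall(
                        chrom=col.chrom,
                        pos=col.pos,
                        ref_base=col.ref_base,
                        alt_base=alt,
                        fwd_support=f,
                        rev_support=r,
                        distinct_starts=len(col.alt_starts.get(alt, ())),
                        allele_fraction=fraction,
                        region_label="U",
                    )
                )
    return calls


def call_m_snps(
    columns: Iterable[PileupColumn],
    min_per_strand: int = 10,
    min_starts: int = 5,
    mask: Mapping[str, np.ndarray] | None = None,
) -> list[VariantCall]:
    """M-region rule on post-g-deNoise unique alignments: >= 10 alt
    alignments per strand from >= 5 distinct starting points, outside
    masked low-complexity tracts.  Thresholds are closed."""
    calls = []
    for col in columns:
        if mask is not None and mask[col.chrom][col.pos - 1]:
            continue
        total = col.depth
        for alt, (f, r) in col.counts.items():
            if alt == col.ref_base or col.ref_base == "N":
                continue
            n_starts = len(col.alt_starts.get(alt, ()))
            if f >= min_per_strand and r >= min_per_strand and n_starts >= min_starts:
                calls.append(
                    VariantCall(
                        chrom=col.chrom,
                        pos=col.pos,
                        ref_base=col.ref_base,
                        alt_base=alt,
                        fwd_support=f,
                        rev_support=r,
                        distinct_starts=n_starts,
                        allele_fraction=(f + r) / total,
                        region_label="M_U",
                    )
                )
    return calls


def mask_low_complexity(
    genome: ReferenceGenome,
    homopolymer_min: int = 5,
    max_unit: int = 6,
    min_copies: int = 3,
    min_tract: int = 8,
    flank: int = 2,
) -> dict[str, np.ndarray]:
    """Boolean mask of noisy homopolymer and microsatellite tracts.

    Masks homopolymer runs of >= ``homopolymer_min`` nt and tandem
    repeats with unit length <= ``max_unit``, >= ``min_copies`` copies
    and total tract length >= ``min_tract``, each extended by ``flank``
    nt on both sides.
    """
    masks = {}
    for chrom in genome.names:
        codes = genome.codes(chrom)
        L = len(codes)
        mask = np.zeros(L, dtype=bool)

        def mark(s0: int, e0: int) -> None:  # inclusive tract, add flanks
            mask[max(0, s0 - flank) : min(L, e0 + 1 + flank)] = True

        for unit in range(1, max_unit + 1):
            if L <= unit:
                break
            eq = codes[unit:] == codes[:-unit]
            eq &= (codes[unit:] <= 3)
            i = 0
            n = len(eq)
            while i < n:
                if not eq[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and eq[j + 1]:
                    j += 1
                tract = (j - i + 1) + unit  # bases spanned by the repeat
                if unit == 1:
                    if tract >= homopolymer_min:
                        mark(i, j + 1)
                if tract >= max(min_tract, unit * min_copies):
                    mark(i, j + unit)
                i = j + 1
        masks[chrom] = mask
    return masks


@dataclass
class SampleComparison:
    """Cross-sample status of every variant key."""

    samples: list[str]
    status: dict[tuple[str, int, str, str], str]  # constitutive/acquired/shared
    sample_support: dict[tuple[str, int, str, str], list[str]]

    def of(self, status: str) -> list[tuple[str, int, str, str]]:
        return sorted(k for k, s in self.status.items() if s == status)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c, "pos": p, "ref": r, "alt": a,
                "status": self.status[(c, p, r, a)],
                "samples": ",".join(self.sample_support[(c, p, r, a)]),
            }
            for (c, p, r, a) in sorted(self.status)
        ]
        return pd.DataFrame(rows)


def compare_samples(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
) -> SampleComparison:
    """Classify variants as constitutive (all samples), acquired
    (exactly one sample) or shared (some but not all)."""
    samples = list(calls_by_sample)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to compare")
    support: dict[tuple[str, int, str, str], list[str]] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            support.setdefault(call.key, [])
            if sample not in support[call.key]:
                support[call.key].append(sample)
    status = {}
    for key, present in support.items():
        if len(present) == len(samples):
            status[key] = "constitutive"
        elif len(present) == 1:
            status[key] = "acquired"
        else:
            status[key] = "shared"
    return SampleComparison(samples, status, support)


def call_sample(
    alignment_sets,
    genome: ReferenceGenome,
    annotation,
    regions: Sequence[Region],
    min_fraction: float = 0.70,
    min_per_strand: int = 10,
    min_starts: int = 5,
    mask: Mapping[str, np.ndarray] | None = None,
    denoise: bool = True,
) -> list[VariantCall]:
    """Full calling chain for one sample's alignment sets.

    Multialignments are passed through g-deNoise (unless ``denoise`` is
    False, in which case only natively unique reads contribute); the
    resulting unique alignments are piled up and the U-region 70%/both-
    strand rule and the M-region 10/10/5 rule are applied in their
    respective regions.
    """
    from .snv_denoise import g_denoise

    unique: list[Alignment] = []
    for aset in alignment_sets:
        if aset.is_unique:
            unique.append(aset.alignments[0])
        elif denoise and aset.is_multialigned:
            result = g_denoise(aset, annotation)
            if len(result.kept) == 1:
                unique.append(result.kept[0])
    u_regions = [r for r in regions if r.label == "U"]
    m_regions = [r for r in regions if r.label == "M"]
    calls: list[VariantCall] = []
    if u_regions:
        calls.extend(
            call_u_snps(pileup(unique, genome, u_regions), min_fraction)
        )
    if m_regions:
        calls.extend(
            call_m_snps(
                pileup(unique, genome, m_regions),
                min_per_strand,
                min_starts,
                mask,
            )
        )
    return calls


def write_vcf(
    calls: Sequence[VariantCall],
    genome: ReferenceGenome,
    path: str | Path,
    sample: str = "sample",
) -> None:
    """Minimal VCF with per-strand support, start diversity and fraction
    in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=gdenoise\n")
        for chrom in genome.names:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Region label (U or M_U)">\n')
        fh.write('##INFO=<ID=SF,Number=1,Type=Integer,Description="Forward-strand alt support">\n')
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="Reverse-strand alt support">\n')
        fh.write('##INFO=<ID=STARTS,Number=1,Type=Integer,Description="Distinct alt alignment start points">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction of unique alignments">\n')
        fh.write(f"##sample={sample}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: (genome.names.index(c.chrom), c.pos)):
            info = (
                f"REGION={call.region_label};SF={call.fwd_support};"
                f"SR={call.rev_support};STARTS={call.distinct_starts};"
                f"AF={call.allele_fraction:.4f}"
            )
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref_base}\t{call.alt_base}"
                f"\t.\tPASS\t{info}\n"
            )
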
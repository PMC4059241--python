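"""Exhaustive ungapped all-hits alignment.

Every placement of a read on either strand of any chromosome with at most
``k`` mismatches is reported — no best-hit selection and no cap on the
number of alignments per read.  Exhaustiveness is guaranteed by pigeonhole
seeding: the read (its color string, in color mode) is partitioned into
``k + 1`` non-overlapping seeds; any placement with <= k mismatches must
contain at least one exact seed, which is found through a hashed genome
index.  Candidates are then verified by a vectorized Hamming count.  Tiny
genomes, or parameter combinations yielding seeds too short to be
selective, fall back to a full sliding-window scan.

Coordinate conventions
----------------------
``start`` is the 1-based leftmost reference position of the aligned
window on the forward genome strand.  Mismatch offsets are 0-based *in
read orientation* (for color mode: into the read's color string); the
``ref`` element of a mismatch is always the forward-genome base (or
color) and the ``read`` element is the read's own base (or color) in read
orientation.  For a reverse-strand alignment the genomic position of the
mismatch at read offset ``q`` is ``start + (length - 1 - q)`` in base
space and ``start + (length - 2 - q) + 1`` in color space, and the base
deposited on the genome forward strand is the complement of the read
base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

import pysam

from .sequence_model import (
    ColorSequence,
    ReferenceGenome,
    _CODE_BASE,
    encode_colorspace,
    reverse_complement,
    seq_to_codes,
)

__all__ = [
    "Alignment",
    "AlignmentSet",
    "align_all",
    "align_batch",
    "read_sam",
    "write_sam",
]

logger = logging.getLogger(__name__)

_MIN_SEED = 5
_SCAN_GENOME = 600  # chromosomes below this length are scanned directly


@dataclass(frozen=True)
class Alignment:
    """One ungapped placement of a read (the atomic evidence unit)."""

    read_id: str
    chrom: str
    start: int  # 1-based leftmost reference position
    strand: str  # '+' or '-'
    length: int  # read length in bases
    mismatches: tuple[tuple[int, str, str], ...]  # (offset, ref, read)
    space: str = "base"

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


@dataclass
class AlignmentSet:
    """All reported placements of one read."""

    read_id: str
    alignments: list[Alignment] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.alignments)

    @property
    def is_unique(self) -> bool:
        return self.n == 1

    @property
    def is_multialigned(self) -> bool:
        return self.n > 1


def _read_payload(read) -> tuple[str, str]:
    if isinstance(read, tuple):
        return read[0], read[1]
    return read.read_id, read.sequence


def _read_color_codes(read, seq: str) -> np.ndarray:
    colors = getattr(read, "colors", None)
    if isinstance(colors, ColorSequence):
        return colors.color_codes
    return encode_colorspace(seq).color_codes


def _seed_index(genome: ReferenceGenome, chrom: str, s: int, space: str) -> dict:
    key = ("seedidx", chrom, s, space)
    if key not in genome._cache:
        arr = genome.codes(chrom) if space == "base" else genome.colors(chrom)
        index: dict[bytes, list[int]] = {}
        data = arr.tobytes()
        for i in range(len(arr) - s + 1):
            index.setdefault(data[i : i + s], []).append(i)
        genome._cache[key] = index
    return genome._cache[key]


def _mismatch_tuples(
    window: np.ndarray,
    pattern: np.ndarray,
    strand: str,
    seq: str,
    read_colors: str | None,
    space: str,
) -> tuple[tuple[int, str, str], ...]:
    diffs = np.nonzero(window != pattern)[0]
    out = []
    m = len(pattern)
    for j in diffs:
        j = int(j)
        q = j if strand == "+" else m - 1 - j
        if space == "base":
            out.append((q, _CODE_BASE[window[j]], seq[q]))
        else:
            assert read_colors is not None
            out.append((q, str(int(window[j])), read_colors[q]))
    out.sort(key=lambda t: t[0])
    return tuple(out)


def align_all(
    read,
    genome: ReferenceGenome,
    k: int,
    space: str = "base",
) -> AlignmentSet:
    """Report every <=k-mismatch ungapped placement of ``read`` on either
    strand of every chromosome.

    Equivalent by construction to a naive both-strand Hamming scan with
    threshold ``k``; in color mode mismatches are counted on the color
    strings with the primer base excluded.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if space not in ("base", "color"):
        raise ValueError(f"unknown space {space!r}")
    read_id, seq = _read_payload(read)
    if "N" in seq:
        raise ValueError(f"read {read_id}: cannot align a read containing N")
    r = len(seq)

    if space == "base":
        fwd = seq_to_codes(seq)
        patterns = {"+": fwd, "-": (3 - fwd)[::-1]}
        read_colors = None
    else:
        cc = _read_color_codes(read, seq)
        patterns = {"+": cc, "-": cc[::-1]}
        read_colors = "".join(str(int(c)) for c in cc)
    m = len(patterns["+"])  # compared length (r in base mode, r-1 in color)

    s = m // (k + 1)
    hits: dict[tuple[str, int, str], Alignment] = {}
    for chrom in genome.names:
        garr = genome.codes(chrom) if space == "base" else genome.colors(chrom)
        L_bases = genome.length(chrom)
        if L_bases < r:
            continue
        n_starts = L_bases - r + 1  # valid 0-based base starts

        def record(p0: int, strand: str, window: np.ndarray) -> None:
            aln = Alignment(
                read_id=read_id,
                chrom=chrom,
                start=p0 + 1,
                strand=strand,
                length=r,
                mismatches=_mismatch_tuples(
                    window, patterns[strand], strand, seq, read_colors, space
                ),
                space=space,
            )
            hits[aln.key] = aln

        if s < _MIN_SEED or L_bases < _SCAN_GENOME:
            sw = sliding_window_view(garr, m)[:n_starts]
            for strand, pattern in patterns.items():
                mm = (sw != pattern).sum(axis=1)
                for p0 in np.nonzero(mm <= k)[0]:
                    record(int(p0), strand, sw[p0])
        else:
            index = _seed_index(genome, chrom, s, space)
            gdata = garr  # verified via numpy slices
            for strand, pattern in patterns.items():
                pbytes = pattern.tobytes()
                cands: set[int] = set()
                for i in range(k + 1):
                    o = i * s
                    for p in index.get(pbytes[o : o + s], ()):
                        cand = p - o
                        if 0 <= cand < n_starts:
                            cands.add(cand)
                for p0 in cands:
                    window = gdata[p0 : p0 + m]
                    if int(np.count_nonzero(window != pattern)) <= k:
                        record(p0, strand, window)

    alignments = sorted(
        hits.values(),
        key=lambda a: (genome.names.index(a.chrom), a.start, a.strand),
    )
    return AlignmentSet(read_id=read_id, alignments=alignments)


def align_batch(
    reads: Iterable,
    genome: ReferenceGenome,
    k: int,
    space: str = "base",
) -> Iterator[AlignmentSet]:
    """Element-wise :func:`align_all` over a read stream, preserving order."""
    for read in reads:
        try:
            yield align_all(read, genome, k, space)
        except Exception as exc:
            read_id = _read_payload(read)[0] if not isinstance(read, tuple) else read[0]
            raise RuntimeError(f"alignment failed for read {read_id!r}") from exc


# ---------------------------------------------------------------------------
# SAM I/O (base-space alignments only; ungapped records)
# ---------------------------------------------------------------------------

def _aligned_window_seq(aln: Alignment, genome: ReferenceGenome) -> str:
    """Forward-genome-orientation sequence deposited by the alignment."""
    window = list(genome.fetch(aln.chrom, aln.start, aln.length))
    for q, _ref, read_base in aln.mismatches:
        if aln.strand == "+":
            window[q] = read_base
        else:
            window[aln.length - 1 - q] = reverse_complement(read_base)
    return "".join(window)


def _md_tag(window_seq: str, ref_seq: str) -> str:
    out: list[str] = []
    run = 0
    for w, ref in zip(window_seq, ref_seq):
        if w == ref:
            run += 1
        else:
            out.append(str(run))
            out.append(ref)
            run = 0
    out.append(str(run))
    return "".join(out)


def write_sam(
    alignment_sets: Iterable[AlignmentSet],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """Write base-space alignment sets as ungapped SAM records.

    All placements of a multialigned read are written; every record after
    the first carries the secondary flag.  NM and MD tags are emitted.
    """
    header = pysam.AlignmentHeader.from_references(
        genome.names, [genome.length(c) for c in genome.names]
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aset in alignment_sets:
            for i, aln in enumerate(aset.alignments):
                if aln.space != "base":
                    raise ValueError("SAM export supports base-space alignments only")
                seg = pysam.AlignedSegment(header)
                seg.query_name = aset.read_id
                seg.flag = (16 if aln.strand == "-" else 0) | (256 if i else 0)
                seg.reference_name = aln.chrom
                seg.reference_start = aln.start - 1
                seg.mapping_quality = 255
                seg.cigarstring = f"{aln.length}M"
                window_seq = _aligned_window_seq(aln, genome)
                seg.query_sequence = window_seq
                ref_seq = genome.fetch(aln.chrom, aln.start, aln.length)
                seg.set_tag("NM", aln.n_mismatch)
                seg.set_tag("MD", _md_tag(window_seq, ref_seq))
                out.write(seg)


def read_sam(path: str | Path, genome: ReferenceGenome) -> list[AlignmentSet]:
    """Read ungapped SAM records back into alignment sets.

    Records are grouped by read name (order of first appearance kept).
    Mismatches are recovered by direct comparison with the reference, so
    MD/NM tags are not required.  Gapped records are skipped; the skipped
    count is logged.
    """
    groups: dict[str, AlignmentSet] = {}
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if seg.reference_name not in genome.names:
                raise ValueError(
                    f"SAM record {seg.query_name}: unknown reference "
                    f"{seg.reference_name!r}"
                )
            cigar = seg.cigartuples
            if cigar is None or len(cigar) != 1 or cigar[0][0] != 0:
                skipped += 1
                continue
            length = cigar[0][1]
            start = seg.reference_start + 1
            strand = "-" if seg.is_reverse else "+"
            window_seq = seg.query_sequence
            if window_seq is None or len(window_seq) != length:
                skipped += 1
                continue
            ref_seq = genome.fetch(seg.reference_name, start, length)
            mismatches = []
            for j, (w, ref) in enumerate(zip(window_seq, ref_seq)):
                if w != ref:
                    q = j if strand == "+" else length - 1 - j
                    read_base = w if strand == "+" else reverse_complement(w)
                    mismatches.append((q, ref, read_base))
            mismatches.sort(key=lambda t: t[0])
            aln = Alignment(
                read_id=seg.query_name,
                chrom=seg.reference_name,
                start=start,
                strand=strand,
                length=length,
                mismatches=tuple(mismatches),
                space="base",
            )
            aset = groups.setdefault(seg.query_name, AlignmentSet(seg.query_name))
            if aln.key not in {a.key for a in aset.alignments}:
                aset.alignments.append(aln)
    if skipped:
        logger.info("read_sam: skipped %d gapped/invalid record(s)", skipped)
    for aset in groups.values():
        aset.alignments.sort(
            key=lambda a: (genome.names.index(a.chrom), a.start, a.strand)
        )
    return list(groups.values())


def skipped_record_count(path: str | Path, genome: ReferenceGenome) -> int:
    """Count gapped/invalid records that :func:`read_sam` would skip."""
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            cigar = seg.cigartuples
            if cigar is None or len(cigar) != 1 or cigar[0][0] != 0:
                skipped += 1
    return skipped
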
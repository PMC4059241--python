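"""Exhaustive virtual-read generation.

One error-free read is emitted per genomic position on the forward strand,
so that in the interior of an N-free chromosome every position is covered
by exactly ``read_length`` reads (the full-coverage plateau of the virtual
profile).  Windows overlapping an N run produce no read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .sequence_model import ColorSequence, ReferenceGenome, encode_colorspace

__all__ = [
    "VirtualRead",
    "generate_virtual_reads",
    "coverage_of_generation",
    "count_virtual_reads",
    "origin_of",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VirtualRead:
    """An error-free forward-strand read taken verbatim from the reference.

    ``read_id`` encodes the origin as ``chrom:start:length`` so planted
    truth is recoverable without side tables.
    """

    read_id: str
    chrom: str
    start: int  # 1-based
    length: int
    sequence: str
    colors: Optional[ColorSequence] = None


def origin_of(read_id: str) -> tuple[str, int, int]:
    """Recover ``(chrom, start, length)`` from a virtual read id."""
    chrom, start, length = read_id.rsplit(":", 2)
    return chrom, int(start), int(length)


def _valid_starts(genome: ReferenceGenome, chrom: str, r: int) -> np.ndarray:
    """0-based starts of N-free windows of length r."""
    n = genome.n_mask(chrom).astype(np.int32)
    L = len(n)
    if L < r:
        return np.empty(0, dtype=np.int64)
    csum = np.concatenate(([0], np.cumsum(n)))
    window_n = csum[r:] - csum[:-r]  # N count per window start
    return np.nonzero(window_n == 0)[0]


def generate_virtual_reads(
    genome: ReferenceGenome,
    read_length: int,
    space: str = "base",
) -> Iterator[VirtualRead]:
    """Yield one read per N-free forward-strand window of every chromosome.

    Chromosomes shorter than ``read_length`` are skipped with a warning.
    In ``color`` space each read additionally carries its dibase encoding.
    """
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    if space not in ("base", "color"):
        raise ValueError(f"unknown space {space!r}")
    for chrom, seq in genome:
        if len(seq) < read_length:
            logger.warning(
                "chromosome %s (%d nt) shorter than read length %d; skipped",
                chrom, len(seq), read_length,
            )
            continue
        for start0 in _valid_starts(genome, chrom, read_length):
            start = int(start0) + 1
            payload = seq[start0 : start0 + read_length]
            colors = encode_colorspace(payload) if space == "color" else None
            yield VirtualRead(
                read_id=f"{chrom}:{start}:{read_length}",
                chrom=chrom,
                start=start,
                length=read_length,
                sequence=payload,
                colors=colors,
            )


def count_virtual_reads(genome: ReferenceGenome, read_length: int) -> int:
    return sum(
        len(_valid_starts(genome, chrom, read_length)) for chrom in genome.names
    )


def coverage_of_generation(
    genome: ReferenceGenome, read_length: int
) -> dict[str, np.ndarray]:
    """Per-position count of generated reads covering each position.

    For an N-free chromosome this is the 1..r ramp at the edges and a flat
    plateau of r in the interior; it is the denominator for full-coverage
    checks against alignment coverage.
    """
    tracks: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        L = genome.length(chrom)
        diff = np.zeros(L + 1, dtype=np.int64)
        starts = _valid_starts(genome, chrom, read_length)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + read_length, -1)
        tracks[chrom] = np.cumsum(diff[:-1])
    return tracks


def write_reads_fasta(reads, path: str | Path) -> None:
    """Export reads (virtual or simulated) as FASTA."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.sequence}\n")


def write_reads_csfasta(reads, path: str | Path) -> None:
    """Export reads in csfasta style (primer base + color digits)."""
    with open(path, "w") as fh:
        for read in reads:
            cs = read.colors or encode_colorspace(read.sequence)
            fh.write(f">{read.read_id}\n{cs}\n")
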
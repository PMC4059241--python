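"""Genome representation, FASTA I/O and SOLiD dinucleotide color-space codec.

Sequences are plain upper-case strings over ``{A, C, G, T, N}``.  All
coordinates handed to users are 1-based inclusive; BED/bedGraph exports
convert to 0-based half-open at the boundary.

The color-space codec implements the standard SOLiD dibase encoding:
with bases coded A=0, C=1, G=2, T=3 the color of an adjacent base pair is
the bitwise XOR of the two base codes, so identical pairs map to color 0
and each row/column of the 4x4 dibase matrix is a permutation.  A single
isolated base substitution therefore changes exactly two adjacent colors,
which is why k mismatches in color space are not equivalent to k
mismatches in base space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "FastaParseError",
    "ReferenceGenome",
    "ColorSequence",
    "load_fasta",
    "reverse_complement",
    "encode_colorspace",
    "decode_colorspace",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base -> 2-bit code; N gets the sentinel 4 (never equal to a real base)
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_BASE = "ACGTN"
N_CODE = 4

_BYTE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODE.items():
    _BYTE_LUT[ord(_b)] = _c
    _BYTE_LUT[ord(_b.lower())] = _c


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``{A,C,G,T,N}``; N maps to N. Involution."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BYTE_LUT[raw]
    if codes.max(initial=0) == 255:
        bad = int(np.argmax(codes == 255))
        raise ValueError(f"invalid base {seq[bad]!r} at position {bad + 1}")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(_CODE_BASE[c] for c in codes)


def codes_to_colors(codes: np.ndarray) -> np.ndarray:
    """Color codes of adjacent pairs; pairs touching an N get sentinel 4."""
    colors = codes[:-1] ^ codes[1:]
    n_touch = (codes[:-1] > 3) | (codes[1:] > 3)
    if n_touch.any():
        colors = colors.copy()
        colors[n_touch] = N_CODE
    return colors


@dataclass(frozen=True)
class ColorSequence:
    """SOLiD-style read: a primer base followed by L-1 color calls."""

    primer_base: str
    colors: str

    def __post_init__(self) -> None:
        if self.primer_base not in "ACGT":
            raise ValueError(f"invalid primer base {self.primer_base!r}")
        if not set(self.colors) <= set("0123"):
            raise ValueError("colors must be digits over {0,1,2,3}")

    def __str__(self) -> str:  # "A313" serialization
        return self.primer_base + self.colors

    @classmethod
    def from_string(cls, text: str) -> "ColorSequence":
        return cls(text[0], text[1:])

    @property
    def color_codes(self) -> np.ndarray:
        return np.frombuffer(self.colors.encode(), dtype=np.uint8) - ord("0")


def encode_colorspace(seq: str) -> ColorSequence:
    """Encode an N-free base sequence (length >= 2) into color space."""
    if len(seq) < 2:
        raise ValueError("color-space encoding needs at least 2 bases")
    if "N" in seq:
        raise ValueError("cannot color-encode a sequence containing N")
    codes = seq_to_codes(seq)
    colors = codes_to_colors(codes)
    return ColorSequence(seq[0], "".join(str(int(c)) for c in colors))


def decode_colorspace(cs: ColorSequence) -> str:
    """Invert :func:`encode_colorspace`: primer base + colors -> bases."""
    code = BASE_CODE[cs.primer_base]
    out = [cs.primer_base]
    for ch in cs.colors:
        code ^= ord(ch) - ord("0")
        out.append(_CODE_BASE[code])
    return "".join(out)


@dataclass
class ReferenceGenome:
    """Ordered named chromosomes of upper-case DNA.

    Derived per-chromosome arrays (base codes, color codes, N masks) and
    aligner seed indexes are cached lazily on the instance.
    """

    chromosomes: list[tuple[str, str]]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        clean: list[tuple[str, str]] = []
        for name, seq in self.chromosomes:
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if name in seen:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seen.add(name)
            seq = seq.upper()
            extra = set(seq) - set("ACGTN")
            if extra:
                raise ValueError(
                    f"chromosome {name!r} contains invalid character(s) "
                    f"{sorted(extra)}"
                )
            clean.append((name, seq))
        self.chromosomes = clean

    # -- basic accessors ---------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    def fetch(self, chrom: str, start: int, length: int) -> str:
        """Substring at 1-based inclusive ``start`` of the given length."""
        seq = self.sequence(chrom)
        if start < 1 or start + length - 1 > len(seq):
            raise ValueError(
                f"window {chrom}:{start}+{length} outside chromosome bounds"
            )
        return seq[start - 1 : start - 1 + length]

    # -- cached derived arrays --------------------------------------------
    def codes(self, chrom: str) -> np.ndarray:
        key = ("codes", chrom)
        if key not in self._cache:
            self._cache[key] = seq_to_codes(self.sequence(chrom))
        return self._cache[key]

    def colors(self, chrom: str) -> np.ndarray:
        key = ("colors", chrom)
        if key not in self._cache:
            self._cache[key] = codes_to_colors(self.codes(chrom))
        return self._cache[key]

    def n_mask(self, chrom: str) -> np.ndarray:
        key = ("nmask", chrom)
        if key not in self._cache:
            self._cache[key] = self.codes(chrom) == N_CODE
        return self._cache[key]

    def non_n_length(self) -> int:
        return sum(
            int((~self.n_mask(name)).sum()) for name in self.names
        )

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.chromosomes)


def load_fasta(path: str | Path) -> ReferenceGenome:
    """Load a (possibly line-wrapped, multi-record) FASTA reference.

    Structure and alphabet are pre-validated line by line so parse errors
    can name the offending line; record assembly is delegated to SeqIO.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                saw_header = True
                if len(stripped) == 1:
                    raise FastaParseError(
                        f"line {lineno}: empty FASTA header"
                    )
                continue
            if not saw_header:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any '>' header"
                )
            bad = set(stripped.upper()) - set("ACGTN")
            if bad:
                raise FastaParseError(
                    f"line {lineno}: invalid character(s) {sorted(bad)}"
                )
    if not saw_header:
        raise FastaParseError("line 1: no FASTA records found (empty file?)")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
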
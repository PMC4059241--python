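"""Seeded synthetic genomes with planted repeat structure, a read
simulator, and naive brute-force oracles.

The generator emulates the repeat classes that dominate a small
eukaryotic genome: dispersed near-identical families (Ty-like), tandem
or scattered polymorphic gene copies (FLO-like) and inverted
duplications (HHF1/HHF2-like).  Planted copies may diverge at a chosen
number of sites (intragenomic SNVs) and may carry planted *acquired*
mutations that exist in the sequenced sample but not in the reference.

The background sequence is verified repeat-free at the profiling read
length by a post-generation self-scan over both strands; on collision
the genome is regenerated from a derived seed.  Everything is
deterministic given ``(spec, seed)``.

The brute-force helpers (:func:`brute_force_alignments`,
:func:`oracle_m_intervals`, :func:`oracle_snvs`) are naive
sliding-window Hamming scans reporting mismatches in window/genome
orientation.  They are deliberately independent of the pigeonhole
aligner and serve as ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sequence_model import (
    _CODE_BASE,
    BASE_CODE,
    ReferenceGenome,
    codes_to_colors,
    codes_to_seq,
    reverse_complement,
)

__all__ = [
    "RepeatFamily",
    "PlantedMutation",
    "FixtureSpec",
    "FixtureTruth",
    "make_genome",
    "apply_mutations",
    "simulate_reads",
    "SimRead",
    "brute_force_alignments",
    "oracle_m_intervals",
    "oracle_snvs",
]


@dataclass(frozen=True)
class RepeatFamily:
    """A planted repeat family: near-identical copies of one unit."""

    copy_number: int
    unit_length: int
    orientations: Optional[tuple[str, ...]] = None  # 'direct'/'inverted'
    divergence: int = 0  # number of planted inter-copy SNV sites
    #: explicit 0-based unit offsets of the divergent sites; when given it
    #: overrides the random draw (len must equal ``divergence``)
    divergence_offsets: Optional[tuple[int, ...]] = None

    def orientation_of(self, copy: int) -> str:
        if self.orientations is None:
            return "direct"
        return self.orientations[copy]


@dataclass(frozen=True)
class PlantedMutation:
    """An acquired mutation carried by the sample, absent from the
    reference; ``offset`` is 0-based within the unit, in unit
    orientation."""

    family: int
    copy: int
    offset: int
    alt_base: Optional[str] = None  # None: draw a non-reference base


@dataclass(frozen=True)
class FixtureSpec:
    genome_length: int
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    repeat_families: tuple[RepeatFamily, ...] = ()
    planted_mutations: tuple[PlantedMutation, ...] = ()
    seed: int = 0
    read_length: int = 25  # uniqueness self-scan length
    chrom_name: str = "chr1"


@dataclass(frozen=True)
class CopyInfo:
    family: int
    copy: int
    start: int  # 1-based
    end: int
    orientation: str


@dataclass(frozen=True)
class DivergentSite:
    family: int
    unit_offset: int
    positions: tuple[int, ...]  # 1-based genomic position per copy
    alleles: tuple[str, ...]  # genome forward-strand allele per copy


@dataclass
class FixtureTruth:
    chrom: str
    copies: list[CopyInfo]
    divergent_sites: list[DivergentSite]
    mutations: list[tuple[str, int, str, str]]  # chrom, pos, ref, alt
    seed: int


def _self_scan_unique(codes: np.ndarray, r: int, copy_spans: list[tuple[int, int]]) -> bool:
    """True iff every multialigned r-window lies inside a planted copy
    (extended by read overlap) — i.e. the background is repeat-free."""
    L = len(codes)
    if L < r:
        return True
    counts: dict[bytes, int] = {}
    rc = (3 - codes)[::-1]
    for arr in (codes, rc):
        data = arr.tobytes()
        for i in range(L - r + 1):
            key = data[i : i + r]
            counts[key] = counts.get(key, 0) + 1
    allowed = np.zeros(L, dtype=bool)
    for s0, e0 in copy_spans:
        allowed[max(0, s0 - r + 1) : min(L, e0 + r)] = True
    data = codes.tobytes()
    for i in range(L - r + 1):
        if counts[data[i : i + r]] > 1 and not allowed[i : i + r].all():
            return False
    return True


def make_genome(spec: FixtureSpec) -> tuple[ReferenceGenome, FixtureTruth]:
    """Build a deterministic planted-repeat genome and its ground truth."""
    p = np.asarray(spec.base_composition, dtype=float)
    if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
        raise ValueError("base_composition must be 4 probabilities summing to 1")

    n_elements = sum(f.copy_number for f in spec.repeat_families)
    total_repeat = sum(f.copy_number * f.unit_length for f in spec.repeat_families)
    margin = 2 * spec.read_length
    slack = spec.genome_length - total_repeat - (n_elements + 1) * margin
    if slack < 0:
        raise ValueError(
            "fixture spec infeasible: planted elements plus margins exceed "
            f"genome_length ({total_repeat} repeat nt, {n_elements} elements)"
        )

    for attempt in range(30):
        rng = np.random.default_rng((spec.seed + attempt * 10007) % 2**31)
        codes = rng.choice(4, size=spec.genome_length, p=p).astype(np.uint8)

        # unit sequences and per-copy variant alleles
        family_units = []
        family_sites = []  # per family: list of (offset, carrier_copy, alt_code)
        for fam in spec.repeat_families:
            unit = rng.choice(4, size=fam.unit_length, p=p).astype(np.uint8)
            if fam.divergence and fam.copy_number < 2:
                raise ValueError("divergence requires at least 2 copies")
            if fam.divergence_offsets is not None:
                if len(fam.divergence_offsets) != fam.divergence:
                    raise ValueError("divergence_offsets length must equal divergence")
                if len(set(fam.divergence_offsets)) != fam.divergence:
                    raise ValueError("divergence_offsets must be distinct")
                offsets = np.asarray(fam.divergence_offsets)
            else:
                offsets = rng.choice(
                    fam.unit_length, size=fam.divergence, replace=False
                )
            sites = []
            for i, off in enumerate(sorted(int(o) for o in offsets)):
                carrier = 1 + (i % (fam.copy_number - 1)) if fam.copy_number > 1 else 0
                alt = int((unit[off] + rng.integers(1, 4)) % 4)
                sites.append((off, carrier, alt))
            family_units.append(unit)
            family_sites.append(sites)

        # placement: split the slack over the gaps, keep the fixed margins
        if n_elements:
            cuts = np.sort(rng.integers(0, slack + 1, size=n_elements))
            gaps = np.diff(np.concatenate(([0], cuts, [slack]))) + margin
        else:
            gaps = np.array([spec.genome_length])
        copies: list[CopyInfo] = []
        copy_arrays: list[np.ndarray] = []
        pos = 0
        idx = 0
        for fi, fam in enumerate(spec.repeat_families):
            for ci in range(fam.copy_number):
                pos += int(gaps[idx])
                idx += 1
                copy_unit = family_units[fi].copy()
                for off, carrier, alt in family_sites[fi]:
                    if carrier == ci:
                        copy_unit[off] = alt
                orient = fam.orientation_of(ci)
                planted = copy_unit if orient == "direct" else (3 - copy_unit)[::-1]
                codes[pos : pos + fam.unit_length] = planted
                copies.append(
                    CopyInfo(fi, ci, pos + 1, pos + fam.unit_length, orient)
                )
                copy_arrays.append(planted)
                pos += fam.unit_length

        spans = [(c.start - 1, c.end - 1) for c in copies]
        if _self_scan_unique(codes, spec.read_length, spans):
            break
    else:
        raise RuntimeError("could not generate a repeat-free background")

    genome = ReferenceGenome([(spec.chrom_name, codes_to_seq(codes))])

    def genome_pos(copy: CopyInfo, fam: RepeatFamily, off: int) -> int:
        if copy.orientation == "direct":
            return copy.start + off
        return copy.start + (fam.unit_length - 1 - off)

    sites: list[DivergentSite] = []
    for fi, fam in enumerate(spec.repeat_families):
        fam_copies = [c for c in copies if c.family == fi]
        for off, carrier, alt in family_sites[fi]:
            positions = tuple(genome_pos(c, fam, off) for c in fam_copies)
            alleles = tuple(
                genome.sequence(spec.chrom_name)[pos - 1] for pos in positions
            )
            sites.append(DivergentSite(fi, off, positions, alleles))

    rng_mut = np.random.default_rng((spec.seed + 777) % 2**31)
    mutations: list[tuple[str, int, str, str]] = []
    for mut in spec.planted_mutations:
        fam = spec.repeat_families[mut.family]
        copy = next(
            c for c in copies if c.family == mut.family and c.copy == mut.copy
        )
        pos = genome_pos(copy, fam, mut.offset)
        ref = genome.sequence(spec.chrom_name)[pos - 1]
        if mut.alt_base is not None:
            alt = (
                mut.alt_base
                if copy.orientation == "direct"
                else reverse_complement(mut.alt_base)
            )
        else:
            alt = _CODE_BASE[int((BASE_CODE[ref] + rng_mut.integers(1, 4)) % 4)]
        if alt == ref:
            alt = _CODE_BASE[(BASE_CODE[ref] + 1) % 4]
        mutations.append((spec.chrom_name, pos, ref, alt))

    truth = FixtureTruth(
        chrom=spec.chrom_name,
        copies=copies,
        divergent_sites=sites,
        mutations=mutations,
        seed=spec.seed,
    )
    return genome, truth


def apply_mutations(
    genome: ReferenceGenome,
    mutations: Sequence[tuple[str, int, str, str]],
) -> ReferenceGenome:
    """Return the sample genome carrying the planted acquired mutations."""
    seqs = {name: list(seq) for name, seq in genome}
    for chrom, pos, ref, alt in mutations:
        if seqs[chrom][pos - 1] != ref:
            raise ValueError(f"mutation ref mismatch at {chrom}:{pos}")
        seqs[chrom][pos - 1] = alt
    return ReferenceGenome([(name, "".join(seqs[name])) for name, _ in genome])


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    chrom: str
    start: int  # 1-based origin on the forward strand
    strand: str


def simulate_reads(
    genome: ReferenceGenome,
    read_length: int,
    depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
    prefix: str = "sim",
) -> Iterator[SimRead]:
    """Simulate single-end error-bearing reads at a target fold-coverage.

    Start positions are uniform over both strands; substitution errors
    are i.i.d. per base at ``error_rate``.  Deterministic for a fixed
    seed.  Windows overlapping N are skipped.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed % 2**31)
    for chrom, seq in genome:
        L = len(seq)
        if L < read_length:
            continue
        n_reads = int(round(depth * L / read_length))
        starts = rng.integers(0, L - read_length + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        nmask = genome.n_mask(chrom)
        for i in range(n_reads):
            s0 = int(starts[i])
            if nmask[s0 : s0 + read_length].any():
                continue
            window = seq[s0 : s0 + read_length]
            strand = "+" if strands[i] == 0 else "-"
            payload = window if strand == "+" else reverse_complement(window)
            if error_rate > 0:
                errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                if len(errs):
                    chars = list(payload)
                    for j in errs:
                        old = BASE_CODE[chars[j]]
                        chars[j] = _CODE_BASE[(old + int(rng.integers(1, 4))) % 4]
                    payload = "".join(chars)
            yield SimRead(
                read_id=f"{prefix}:{chrom}:{s0 + 1}:{strand}:{i}",
                sequence=payload,
                chrom=chrom,
                start=s0 + 1,
                strand=strand,
            )


# ---------------------------------------------------------------------------
# naive brute-force oracles (window/genome orientation throughout)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BruteAlignment:
    chrom: str
    start: int  # 1-based
    strand: str
    n_mismatch: int
    # (window_offset, ref symbol, aligned symbol on the forward genome)
    window_mismatches: tuple[tuple[int, str, str], ...]


def brute_force_alignments(
    seq: str,
    genome: ReferenceGenome,
    k: int,
    space: str = "base",
) -> list[BruteAlignment]:
    """All <=k-mismatch ungapped placements by naive sliding comparison."""
    from .sequence_model import seq_to_codes

    r = len(seq)
    fwd = seq_to_codes(seq)
    if space == "base":
        patterns = {"+": fwd, "-": (3 - fwd)[::-1]}
        symbols = _CODE_BASE
    else:
        cc = codes_to_colors(fwd)
        patterns = {"+": cc, "-": cc[::-1]}
        symbols = "01234"
    out = []
    for chrom in genome.names:
        garr = genome.codes(chrom) if space == "base" else genome.colors(chrom)
        L = genome.length(chrom)
        if L < r:
            continue
        m = len(patterns["+"])
        sw = sliding_window_view(garr, m)[: L - r + 1]
        for strand, pattern in patterns.items():
            neq = sw != pattern
            mm = neq.sum(axis=1)
            for p0 in np.nonzero(mm <= k)[0]:
                diffs = tuple(
                    (int(j), symbols[sw[p0][j]], symbols[pattern[j]])
                    for j in np.nonzero(neq[p0])[0]
                )
                out.append(
                    BruteAlignment(chrom, int(p0) + 1, strand, int(mm[p0]), diffs)
                )
    return out


def _all_windows(genome: ReferenceGenome, chrom: str, r: int) -> Iterator[int]:
    nmask = genome.n_mask(chrom)
    L = genome.length(chrom)
    for p0 in range(L - r + 1):
        if not nmask[p0 : p0 + r].any():
            yield p0


def oracle_m_intervals(
    genome: ReferenceGenome,
    read_length: int,
    k: int,
    space: str = "base",
) -> dict[str, list[tuple[int, int]]]:
    """Ambiguous-coverage M intervals by exhaustive naive alignment of
    every virtual read."""
    marked = {c: np.zeros(n, dtype=bool) for c, n in genome.lengths.items()}
    for chrom in genome.names:
        seq = genome.sequence(chrom)
        for p0 in _all_windows(genome, chrom, read_length):
            alns = brute_force_alignments(
                seq[p0 : p0 + read_length], genome, k, space
            )
            if len(alns) > 1:
                for a in alns:
                    marked[a.chrom][a.start - 1 : a.start - 1 + read_length] = True
    out = {}
    for chrom, arr in marked.items():
        intervals = []
        idx = np.nonzero(arr)[0]
        if len(idx):
            breaks = np.nonzero(np.diff(idx) > 1)[0]
            starts = np.concatenate(([idx[0]], idx[breaks + 1]))
            ends = np.concatenate((idx[breaks], [idx[-1]]))
            intervals = [(int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)]
        out[chrom] = intervals
    return out


def oracle_snvs(
    genome: ReferenceGenome,
    read_length: int,
    k: int,
) -> set[tuple[str, int, str, str]]:
    """Directed intragenomic SNV keys by naive base-space alignment of
    every virtual read (window-orientation mismatches map directly to
    genome coordinates)."""
    keys: set[tuple[str, int, str, str]] = set()
    for chrom in genome.names:
        seq = genome.sequence(chrom)
        for p0 in _all_windows(genome, chrom, read_length):
            alns = brute_force_alignments(seq[p0 : p0 + read_length], genome, k)
            if len(alns) > 1:
                for a in alns:
                    for j, ref, aligned in a.window_mismatches:
                        keys.add((a.chrom, a.start + j, ref, aligned))
    return keys
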
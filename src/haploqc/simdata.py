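"""Synthetic diploid genomes, long reads and redundant assemblies with known truth.

The generator emulates the statistical structure the k-mer assessment assumes:
a diploid genome with a tunable per-base heterozygosity, optional highly
divergent regions (HDRs) where the local SNP rate is elevated, per-haplotype
long-read coverage with substitution/indel error, and an "assembly" consisting
of a fragmented primary haplotype plus a known fraction of redundant
alternate-haplotype contigs (haplotigs).

All generators are pure functions of their inputs and a seed; coordinates in
truth records are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codons import (
    CODON_TO_AA,
    SENSE_CODONS,
    nonsynonymous_neighbors,
    synonymous_neighbors,
)
from .errors import GenerationError, InputError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class HDRBlock:
    """A highly divergent region: [start, end) with its own per-base SNP rate."""

    start: int
    end: int
    rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InputError(f"invalid HDR interval [{self.start}, {self.end})")
        if not 0.0 <= self.rate < 1.0:
            raise InputError(f"HDR rate {self.rate} outside [0, 1)")


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults mirror the regime the assessment is designed for: a moderately
    heterozygous diploid (r ~ 1.1% per base), noisy long reads at 25x coverage
    per haplotype, and an assembly retaining half of the alternate haplotype
    as redundant contigs.
    """

    genome_length: int = 500_000
    gc_fraction: float = 0.42
    r: float = 0.011
    hdr_blocks: list[HDRBlock] = field(default_factory=list)
    read_length: int = 1_000
    per_hap_coverage: float = 25.0
    error_sub: float = 0.01
    error_ins: float = 0.0
    error_del: float = 0.0
    redundancy_fraction: float = 0.5
    n_primary_contigs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 0:
            raise InputError("genome_length must be nonnegative")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InputError("gc_fraction must lie in [0, 1]")
        for p, name in [(self.r, "r"), (self.error_sub, "error_sub"),
                        (self.error_ins, "error_ins"), (self.error_del, "error_del")]:
            if not 0.0 <= p < 1.0:
                raise InputError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.redundancy_fraction <= 1.0:
            raise InputError("redundancy_fraction must lie in [0, 1]")
        if self.n_primary_contigs < 1:
            raise InputError("n_primary_contigs must be >= 1")
        _check_hdr_blocks(self.hdr_blocks, self.genome_length)


def _check_hdr_blocks(blocks: list[HDRBlock], genome_length: int) -> None:
    ordered = sorted(blocks, key=lambda b: b.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise InputError(
                f"overlapping HDR blocks [{prev.start},{prev.end}) and [{cur.start},{cur.end})"
            )
    if ordered and ordered[-1].end > genome_length:
        raise InputError("HDR block extends past the end of the genome")


@dataclass
class DiploidTruth:
    """Ground truth for a simulated diploid: both haplotypes and the SNP map."""

    hap1: str
    hap2: str
    variant_positions: list[int]

    @property
    def n_het_sites(self) -> int:
        return len(self.variant_positions)


@dataclass
class Contig:
    id: str
    seq: str


@dataclass
class AssemblyTruth:
    """What the simulated assembly contains, in hap1/hap2 coordinates."""

    contigs: list[Contig]
    primary_breakpoints: list[int]
    #: (contig_id, hap2_start, hap2_end), 0-based half-open
    redundant_blocks: list[tuple[str, int, int]]
    realized_f: float


@dataclass
class Read:
    """A simulated read; the id encodes haplotype and coordinates of origin."""

    id: str
    seq: str


def generate_haploid(length: int, gc_fraction: float, seed: int) -> str:
    """Draw an i.i.d. random sequence with the requested GC content.

    G and C each get gc_fraction/2 probability, A and T the remainder split
    evenly. Identical (length, gc_fraction, seed) reproduce the identical
    sequence.
    """
    if length < 0:
        raise InputError("length must be nonnegative")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InputError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return _codes_to_seq(codes)


def diploidize(seq: str, r: float, hdr_blocks: list[HDRBlock] | None = None,
               seed: int = 0) -> DiploidTruth:
    """Derive a second haplotype by placing heterozygous SNPs on a template.

    Each base mutates independently with probability ``r`` (or the block rate
    inside an HDR); the substituted base is uniform over the three
    alternatives. Heterozygosity is SNP-only: hap1 and hap2 are colinear and
    differ exactly at the recorded variant positions.
    """
    if not 0.0 <= r < 1.0:
        raise InputError("r must lie in [0, 1)")
    hdr_blocks = hdr_blocks or []
    _check_hdr_blocks(hdr_blocks, len(seq))
    rng = np.random.default_rng(seed)
    n = len(seq)
    rate = np.full(n, r)
    for block in hdr_blocks:
        rate[block.start:block.end] = block.rate
    is_var = rng.random(n) < rate
    positions = np.flatnonzero(is_var)
    codes = _seq_to_codes(seq)
    if np.any(codes[positions] > 3):
        raise InputError("template sequence contains non-ACGT symbols at variant sites")
    alt = (codes[positions] + rng.integers(1, 4, size=positions.size)) % 4
    hap2 = codes.copy()
    hap2[positions] = alt.astype(np.uint8)
    return DiploidTruth(hap1=seq, hap2=_codes_to_seq(hap2),
                        variant_positions=[int(p) for p in positions])


def _apply_read_errors(codes: np.ndarray, error_sub: float, error_ins: float,
                       error_del: float, rng: np.random.Generator) -> np.ndarray:
    if error_sub > 0:
        hit = rng.random(codes.size) < error_sub
        n = int(hit.sum())
        if n:
            codes = codes.copy()
            codes[hit] = (codes[hit] + rng.integers(1, 4, size=n)) % 4
    if error_del > 0:
        keep = rng.random(codes.size) >= error_del
        codes = codes[keep]
    if error_ins > 0:
        ins = rng.random(codes.size) < error_ins
        idx = np.flatnonzero(ins)
        if idx.size:
            codes = np.insert(codes, idx + 1,
                              rng.integers(0, 4, size=idx.size).astype(np.uint8))
    return codes


_RC = np.array([3, 2, 1, 0], dtype=np.uint8)


def simulate_reads(hap1: str, hap2: str, read_length: int, per_hap_coverage: float,
                   error_sub: float = 0.0, error_ins: float = 0.0,
                   error_del: float = 0.0, seed: int = 0) -> list[Read]:
    """Sample error-prone reads uniformly from both haplotypes and strands.

    Enough reads are drawn from each haplotype to reach at least
    ``per_hap_coverage`` mean base coverage. Read ids encode the haplotype,
    serial number, 0-based half-open template interval and strand, so
    truth-aware tests can trace every read back to its origin.
    """
    if read_length < 1:
        raise InputError("read_length must be >= 1")
    if per_hap_coverage <= 0:
        raise InputError("per_hap_coverage must be positive")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for hap_no, hap in ((1, hap1), (2, hap2)):
        if read_length > len(hap):
            raise InputError("read_length exceeds haplotype length")
        codes = _seq_to_codes(hap)
        n_reads = int(np.ceil(per_hap_coverage * len(hap) / read_length))
        starts = rng.integers(0, len(hap) - read_length + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for i in range(n_reads):
            s = int(starts[i])
            frag = codes[s:s + read_length]
            if strands[i]:
                frag = _RC[frag[::-1]]
            frag = _apply_read_errors(frag, error_sub, error_ins, error_del, rng)
            strand = "-" if strands[i] else "+"
            rid = f"hap{hap_no}_{i:06d}_{s}_{s + read_length}_{strand}"
            reads.append(Read(id=rid, seq=_codes_to_seq(frag)))
    return reads


def make_assembly(hap1: str, hap2: str, redundancy_fraction: float,
                  n_primary_contigs: int, seed: int = 0,
                  n_haplotigs: int = 4) -> tuple[list[Contig], AssemblyTruth]:
    """Build an assembly with a known fraction of redundant haplotigs.

    Primary contigs are hap1 split at uniformly random breakpoints. Redundant
    haplotigs are non-overlapping contiguous blocks of hap2 totalling
    ``round(redundancy_fraction * genome_length)`` bases, emitted as extra
    contigs. ``realized_f`` in the returned truth is the exact length ratio.
    """
    if not 0.0 <= redundancy_fraction <= 1.0:
        raise InputError("redundancy_fraction must lie in [0, 1]")
    if n_primary_contigs < 1:
        raise InputError("n_primary_contigs must be >= 1")
    if len(hap1) != len(hap2):
        raise InputError("haplotypes must have equal length (SNP-only diploid)")
    rng = np.random.default_rng(seed)
    genome_length = len(hap1)

    if n_primary_contigs > 1:
        breakpoints = sorted(
            int(b) + 1
            for b in rng.choice(genome_length - 1, size=n_primary_contigs - 1, replace=False)
        )
    else:
        breakpoints = []
    bounds = [0, *breakpoints, genome_length]
    contigs = [
        Contig(id=f"primary_{i:04d}", seq=hap1[bounds[i]:bounds[i + 1]])
        for i in range(n_primary_contigs)
    ]

    total_red = int(round(redundancy_fraction * genome_length))
    redundant_blocks: list[tuple[str, int, int]] = []
    if total_red > 0:
        n_blocks = max(1, min(n_haplotigs, total_red))
        if n_blocks > 1:
            cuts = sorted(int(c) + 1 for c in
                          rng.choice(total_red - 1, size=n_blocks - 1, replace=False))
        else:
            cuts = []
        lengths = np.diff([0, *cuts, total_red])
        free = genome_length - total_red
        gaps = rng.multinomial(free, np.full(n_blocks + 1, 1.0 / (n_blocks + 1)))
        pos = 0
        for i, length in enumerate(lengths):
            pos += int(gaps[i])
            start, end = pos, pos + int(length)
            cid = f"haplotig_{i:04d}"
            contigs.append(Contig(id=cid, seq=hap2[start:end]))
            redundant_blocks.append((cid, start, end))
            pos = end

    truth = AssemblyTruth(
        contigs=contigs,
        primary_breakpoints=breakpoints,
        redundant_blocks=redundant_blocks,
        realized_f=total_red / genome_length if genome_length else 0.0,
    )
    return contigs, truth


@dataclass
class CodingChange:
    codon_index: int
    kind: str  # "synonymous" | "nonsynonymous"
    from_codon: str
    to_codon: str


def generate_coding_pair(n_codons: int, n_syn: int, n_nonsyn: int,
                         seed: int = 0) -> tuple[str, str, list[CodingChange]]:
    """A random stop-free CDS and a copy carrying known single-nt changes.

    Exactly ``n_syn`` synonymous and ``n_nonsyn`` nonsynonymous substitutions
    are applied, each at a distinct codon. Codons with no neighbor of the
    requested type (e.g. ATG for a synonymous change) are resampled; if no
    codon in the sequence can host a remaining change, a GenerationError is
    raised.
    """
    if n_codons < 1:
        raise InputError("n_codons must be >= 1")
    if n_syn + n_nonsyn > n_codons:
        raise InputError("more requested changes than codons")
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=n_codons)]
    cds1 = "".join(codons)
    mutated = list(codons)
    changes = _mutate_codons(mutated, n_syn, n_nonsyn, rng)
    return cds1, "".join(mutated), changes


def _mutate_codons(codons: list[str], n_syn: int, n_nonsyn: int,
                   rng: np.random.Generator) -> list[CodingChange]:
    """Apply the requested changes in place; each codon is used at most once."""
    pool = list(range(len(codons)))
    changes: list[CodingChange] = []
    for kind, count, neighbor_fn in (
        ("synonymous", n_syn, synonymous_neighbors),
        ("nonsynonymous", n_nonsyn, nonsynonymous_neighbors),
    ):
        for _ in range(count):
            placed = False
            while pool:
                j = pool.pop(int(rng.integers(0, len(pool))))
                options = neighbor_fn(codons[j])
                if options:
                    new = options[int(rng.integers(0, len(options)))]
                    changes.append(CodingChange(j, kind, codons[j], new))
                    codons[j] = new
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"no codon available for a {kind} change "
                    f"({n_syn} syn + {n_nonsyn} nonsyn requested)"
                )
    changes.sort(key=lambda c: c.codon_index)
    return changes


def translate_cds(cds: str) -> str:
    """Translate a CDS (no gap handling); '*' marks stops."""
    if len(cds) % 3:
        raise InputError("CDS length not divisible by 3")
    return "".join(CODON_TO_AA[cds[i:i + 3]] for i in range(0, len(cds), 3))


def kmer_coverage(per_hap_coverage: float, read_length: int, k: int) -> float:
    """Expected haploid k-mer coverage for a given base coverage and read length.

    Each read of length L contributes L - k + 1 k-mer windows, so the k-mer
    coverage is the base coverage scaled by (L - k + 1) / L.
    """
    return per_hap_coverage * (read_length - k + 1) / read_length
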
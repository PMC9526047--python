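"""Canonical k-mer counting, multiplicity histograms, and the spectra-cn partition.

k-mers are packed 2 bits per base into a 64-bit word (k <= 31); the canonical
form of a k-mer is the lexicographic minimum of the k-mer and its reverse
complement under A < C < G < T, matching the behavior of common k-mer
counters. Windows containing any non-ACGT symbol contribute nothing.

The spectra-cn partition classifies every distinct read k-mer by its copy
number in an assembly: class 0 holds read k-mers absent from the assembly,
class c holds k-mers occurring c times, and the final class ``Cmax+`` is
open-ended. Column sums over classes reproduce the read histogram exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import InputError

MAX_K = 31

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Packed codes of all valid (ACGT-only) k-windows of ``seq``, in order."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = raw.size
    if n < k:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty
    b = _CODE[raw]
    valid = b < 4
    m = n - k + 1
    # a window is valid iff it contains no invalid base
    bad = (~valid).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    window_ok = (cs[k:] - cs[:-k]) == 0
    bb = np.where(valid, b, 0).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd |= bb[j:j + m] << np.uint64(2 * (k - 1 - j))
        rev |= (three - bb[j:j + m]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[window_ok], fwd[window_ok]


def decode_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit code back to its ACGT string."""
    return "".join("ACGT"[(int(code) >> (2 * (k - 1 - j))) & 3] for j in range(k))


@dataclass
class KmerCountTable:
    """Distinct k-mers (packed, sorted) with their multiplicities."""

    k: int
    canonical: bool
    codes: np.ndarray   # sorted uint64
    counts: np.ndarray  # int64, same length

    @property
    def total_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total_instances(self) -> int:
        return int(self.counts.sum())

    def multiplicity(self, codes: np.ndarray) -> np.ndarray:
        """Multiplicity of each query code in this table (0 when absent)."""
        idx = np.searchsorted(self.codes, codes)
        idx = np.minimum(idx, max(self.codes.size - 1, 0))
        out = np.zeros(codes.size, dtype=np.int64)
        if self.codes.size:
            hit = self.codes[idx] == codes
            out[hit] = self.counts[idx[hit]]
        return out

    def to_dict(self) -> dict[str, int]:
        """Decoded {kmer: multiplicity}; intended for small tables and tests."""
        return {decode_kmer(c, self.k): int(n) for c, n in zip(self.codes, self.counts)}


def count_kmers(sequences: str | Iterable[str], k: int, canonical: bool = True) -> KmerCountTable:
    """Count k-mers over one or more sequences.

    Every length-k window consisting solely of A/C/G/T (case-insensitive)
    contributes one count to its canonical form; other windows are skipped.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if k > MAX_K:
        raise InputError(f"k must be <= {MAX_K} for the packed representation")
    if isinstance(sequences, str):
        sequences = [sequences]
    chunks = []
    for seq in sequences:
        canon, fwd = _window_codes(seq, k)
        chunks.append(canon if canonical else fwd)
    if not chunks:
        all_codes = np.empty(0, dtype=np.uint64)
    else:
        all_codes = np.concatenate(chunks)
    codes, counts = np.unique(all_codes, return_counts=True)
    return KmerCountTable(k=k, canonical=canonical, codes=codes,
                          counts=counts.astype(np.int64))


@dataclass
class KmerHistogram:
    """Distinct-k-mer counts indexed by read multiplicity x >= 1."""

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for x, n in self.counts.items():
            if x < 1 or n < 0:
                raise InputError("histogram keys must be >= 1 and values >= 0")

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())

    @property
    def total_instances(self) -> int:
        return sum(x * n for x, n in self.counts.items())

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts, default=0)

    def dense(self, x_max: int | None = None) -> np.ndarray:
        """Counts on 1..x_max as an array (index 0 <-> multiplicity 1)."""
        if x_max is None:
            x_max = self.max_multiplicity
        out = np.zeros(x_max, dtype=np.int64)
        for x, n in self.counts.items():
            if x <= x_max:
                out[x - 1] = n
        return out

    def items(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.counts.items()))


def histogram(table: KmerCountTable) -> KmerHistogram:
    """Collapse a count table to its multiplicity histogram."""
    mult, n = np.unique(table.counts, return_counts=True)
    return KmerHistogram(k=table.k, counts={int(x): int(c) for x, c in zip(mult, n)})


@dataclass
class SpectraCN:
    """Read k-mer histogram partitioned by assembly copy number.

    ``table`` maps copy class c (0..cmax, the last open-ended) to a
    multiplicity histogram {x: distinct k-mers}; ``assembly_exclusive`` tallies
    assembly k-mers never seen in the reads, by assembly multiplicity.
    """

    k: int
    cmax: int
    table: dict[int, dict[int, int]]
    assembly_exclusive: dict[int, int]
    metadata: dict = field(default_factory=dict)

    @property
    def class_labels(self) -> list[str]:
        return [str(c) for c in range(self.cmax)] + [f"{self.cmax}+"]

    def class_dense(self, c: int, x_max: int) -> np.ndarray:
        out = np.zeros(x_max, dtype=np.int64)
        for x, n in self.table.get(c, {}).items():
            if x <= x_max:
                out[x - 1] = n
        return out

    def column_sums(self) -> dict[int, int]:
        """Per-multiplicity totals over classes; equals the read histogram."""
        out: dict[int, int] = {}
        for col in self.table.values():
            for x, n in col.items():
                out[x] = out.get(x, 0) + n
        return out

    @property
    def max_multiplicity(self) -> int:
        return max((max(col, default=0) for col in self.table.values()), default=0)


def spectra_cn(read_counts: KmerCountTable, assembly_counts: KmerCountTable,
               cmax: int = 4) -> SpectraCN:
    """Partition distinct read k-mers by their assembly copy number.

    A read k-mer with assembly multiplicity a lands in class min(a, cmax);
    class 0 collects read k-mers absent from the assembly.
    """
    if read_counts.k != assembly_counts.k:
        raise InputError(
            f"k mismatch: reads k={read_counts.k}, assembly k={assembly_counts.k}")
    if read_counts.canonical != assembly_counts.canonical:
        raise InputError("canonicalization mismatch between read and assembly tables")
    if cmax < 1:
        raise InputError("cmax must be >= 1")

    asm_mult = assembly_counts.multiplicity(read_counts.codes)
    classes = np.minimum(asm_mult, cmax)
    table: dict[int, dict[int, int]] = {}
    for c in range(cmax + 1):
        mask = classes == c
        mult, n = np.unique(read_counts.counts[mask], return_counts=True)
        table[c] = {int(x): int(cnt) for x, cnt in zip(mult, n)}

    # assembly k-mers with zero read support (the 0-read column of spectra-cn)
    in_reads = np.isin(assembly_counts.codes, read_counts.codes, assume_unique=True)
    excl_mult, excl_n = np.unique(assembly_counts.counts[~in_reads], return_counts=True)
    assembly_exclusive = {int(a): int(n) for a, n in zip(excl_mult, excl_n)}

    return SpectraCN(k=read_counts.k, cmax=cmax, table=table,
                     assembly_exclusive=assembly_exclusive)
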
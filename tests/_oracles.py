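"""Independent brute-force oracles used to validate the implementation.

Everything here is written against the plain definitions (string
dictionaries, explicit path enumeration, per-codon translation via
Bio.Seq), deliberately sharing no code with the package internals.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Seq import Seq

_COMP = str.maketrans("ACGT", "TGCA")


def naive_kmer_counts(sequences, k, canonical=True) -> dict[str, int]:
    """Dictionary k-mer counting straight from the definition."""
    if isinstance(sequences, str):
        sequences = [sequences]
    counts: dict[str, int] = {}
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if any(ch not in "ACGT" for ch in w):
                continue
            if canonical:
                rc = w.translate(_COMP)[::-1]
                w = min(w, rc)
            counts[w] = counts.get(w, 0) + 1
    return counts


def brute_force_align_score(a: str, b: str, matrix, gap_open: float,
                            gap_extend: float) -> float:
    """Optimal global affine-gap score by explicit enumeration of all paths.

    A gap of length L costs gap_open + (L - 1) * gap_extend; a gap character
    costs gap_open when it opens a gap (previous step was not the same gap
    type) and gap_extend when it extends one.
    """
    n, m = len(a), len(b)
    best = [float("-inf")]

    def rec(i: int, j: int, last: str, acc: float) -> None:
        if i == n and j == m:
            if acc > best[0]:
                best[0] = acc
            return
        if i < n and j < m:
            rec(i + 1, j + 1, "M", acc + float(matrix[a[i], b[j]]))
        if j < m:
            cost = gap_extend if last == "X" else gap_open
            rec(i, j + 1, "X", acc - cost)
        if i < n:
            cost = gap_extend if last == "Y" else gap_open
            rec(i + 1, j, "Y", acc - cost)

    rec(0, 0, "", 0.0)
    return best[0]


_AA_CACHE: dict[str, str] = {}


def _aa(codon: str) -> str:
    if codon not in _AA_CACHE:
        _AA_CACHE[codon] = str(Seq(codon).translate())
    return _AA_CACHE[codon]


def _syn_sites(codon: str) -> float:
    syn = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                syn += 1
    return syn / 3.0


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    open_paths = []
    all_paths = []
    for order in permutations(diff):
        cur, sd, nd, blocked = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*":
                blocked = True
            if _aa(nxt) == _aa(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        all_paths.append((sd, nd))
        if not blocked:
            open_paths.append((sd, nd))
    use = open_paths if open_paths else all_paths
    return (sum(p[0] for p in use) / len(use),
            sum(p[1] for p in use) / len(use))


def ng86_oracle(codon_aln1: str, codon_aln2: str) -> dict:
    """Independent Nei-Gojobori enumerator for a gapless-or-gapped codon
    alignment; returns site/difference counts and JC-corrected distances."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(codon_aln1), 3):
        c1, c2 = codon_aln1[i:i + 3].upper(), codon_aln2[i:i + 3].upper()
        if "-" in c1 or "-" in c2:
            continue
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if _aa(c1) == "*" or _aa(c2) == "*":
            continue
        s = (_syn_sites(c1) + _syn_sites(c2)) / 2.0
        S += s
        N += 3.0 - s
        sd, nd = _path_diffs(c1, c2)
        Sd += sd
        Nd += nd

    def jc(p):
        return None if p >= 0.75 else -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    return {
        "S": S, "N": N, "Sd": Sd, "Nd": Nd, "ps": ps, "pn": pn,
        "ds": jc(ps) if ps is not None else None,
        "dn": jc(pn) if pn is not None else None,
    }
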
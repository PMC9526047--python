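"""Divergence between duplicated gene copies: NG86 dN/dS and Canberra distance.

Duplicated gene copies (e.g. from a BUSCO-style screen of a draft assembly)
are compared two ways:

* alignment-based — the two proteins are globally aligned (affine gaps,
  BLOSUM62), the alignment is back-threaded onto the coding sequences, and
  synonymous/nonsynonymous sites and differences are counted with the
  Nei–Gojobori (1986) method, including equal-weight pathway averaging for
  codons differing at 2–3 positions and the Jukes–Cantor correction;
* alignment-free — overlapping dinucleotide (word size 2 by default) count
  vectors of the full genomic spans (introns included) compared with the
  Canberra distance.

Pairs are partitioned into ``tandem`` (both copies on the same contig —
plausibly a real duplication) and ``unique`` (copies on different contigs —
the haplotig signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices

from ._codons import CODON_TO_AA, STOP_CODONS
from .errors import InputError, ThreadingError

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP = "-"


# ---------------------------------------------------------------------------
# gene pairs

@dataclass
class GeneCopy:
    """One copy of a gene: location plus extracted sequence(s)."""

    contig_id: str
    start: int   # 0-based
    end: int     # half-open
    strand: str
    genomic: str
    cds: str | None = None


@dataclass
class GenePair:
    gene_id: str
    copy1: GeneCopy
    copy2: GeneCopy

    @property
    def placement(self) -> str:
        return "tandem" if self.copy1.contig_id == self.copy2.contig_id else "unique"


_REVCOMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def extract_gene_pairs(full_table: str | Path,
                       assembly: Mapping[str, str],
                       coordinate_base: int = 1) -> tuple[list[GenePair], dict]:
    """Gene pairs from a BUSCO-style full table and an assembly.

    Only genes with status ``Duplicated`` and exactly two copies are kept.
    Rows use the full_table v5 layout (id, status, sequence, start, end,
    strand, ...); coordinates are taken verbatim from the table and
    interpreted with the given ``coordinate_base`` (1 = 1-based inclusive,
    the BUSCO convention; 0 = 0-based half-open). Genomic spans are
    strand-normalized: minus-strand spans are reverse-complemented. Rows with
    coordinates outside their contig, and genes with more than two copies,
    are skipped and counted.

    This path yields genomic spans only (for the alignment-free comparison);
    coding sequences come from paired CDS FASTA input.
    """
    rows: dict[str, list[tuple[str, int, int, str]]] = {}
    skipped = {"out_of_bounds": 0, "multi_copy_genes": 0, "bad_rows": 0}
    with open(full_table) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                skipped["bad_rows"] += 1
                continue
            gene_id, status = parts[0], parts[1]
            if status != "Duplicated":
                continue
            if len(parts) < 6:
                skipped["bad_rows"] += 1
                continue
            try:
                contig = parts[2]
                start, end = int(parts[3]), int(parts[4])
                strand = parts[5]
            except ValueError:
                skipped["bad_rows"] += 1
                continue
            rows.setdefault(gene_id, []).append((contig, start, end, strand))

    pairs: list[GenePair] = []
    for gene_id, copies in sorted(rows.items()):
        if len(copies) != 2:
            skipped["multi_copy_genes"] += 1
            continue
        extracted = []
        for contig, start, end, strand in copies:
            if coordinate_base == 1:
                start0, end0 = start - 1, end
            else:
                start0, end0 = start, end
            seq = assembly.get(contig)
            if seq is None or not (0 <= start0 < end0 <= len(seq)):
                extracted = []
                skipped["out_of_bounds"] += 1
                break
            span = seq[start0:end0]
            if strand == "-":
                span = _revcomp(span)
            extracted.append(GeneCopy(contig_id=contig, start=start0, end=end0,
                                      strand=strand, genomic=span))
        if len(extracted) == 2:
            pairs.append(GenePair(gene_id=gene_id, copy1=extracted[0], copy2=extracted[1]))
    return pairs, skipped


def read_paired_fasta(records: Mapping[str, str]) -> list[tuple[str, str, str]]:
    """Pair records named ``<gene>__copy1`` / ``<gene>__copy2``.

    Returns (gene_id, seq1, seq2) triples; genes lacking either copy are
    dropped.
    """
    genes: dict[str, dict[str, str]] = {}
    for name, seq in records.items():
        if "__copy" not in name:
            continue
        gene, copy = name.rsplit("__", 1)
        genes.setdefault(gene, {})[copy] = seq
    out = []
    for gene in sorted(genes):
        d = genes[gene]
        if "copy1" in d and "copy2" in d:
            out.append((gene, d["copy1"], d["copy2"]))
    return out


# ---------------------------------------------------------------------------
# protein alignment (global, affine gaps)

@dataclass
class ProteinAlignment:
    aligned1: str
    aligned2: str
    score: float
    degenerate: bool = False


def _sub_score(a: str, b: str, matrix) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        return float(matrix["X", "X"])


def align_proteins(aa1: str, aa2: str, gap_open: float = 11.0,
                   gap_extend: float = 1.0, matrix=None) -> ProteinAlignment:
    """Global protein alignment with affine gap penalties (Gotoh).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. Default
    scoring is BLOSUM62 with open 11 / extend 1. Ties during traceback are
    broken deterministically: substitution is preferred over a gap, and a gap
    in the first sequence over a gap in the second. Aligning against an empty
    sequence yields the degenerate all-gap alignment, flagged.
    """
    if matrix is None:
        matrix = _BLOSUM62
    n, m = len(aa1), len(aa2)
    if n == 0 or m == 0:
        longer = max(n, m)
        score = 0.0 if longer == 0 else -(gap_open + (longer - 1) * gap_extend)
        return ProteinAlignment(aligned1=aa1 or GAP * m, aligned2=aa2 or GAP * n,
                                score=score, degenerate=True)

    neg = float("-inf")
    # M: ends in substitution; X: gap in aa1 (consumes aa2); Y: gap in aa2
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        Y[i, 0] = -(gap_open + (i - 1) * gap_extend)

    for i in range(1, n + 1):
        a = aa1[i - 1]
        row_scores = [_sub_score(a, b, matrix) for b in aa2]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            Mi[j] = row_scores[j - 1] + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mi[j - 1] - gap_open, Xi[j - 1] - gap_extend,
                        Yi[j - 1] - gap_open)
            Yi[j] = max(Mp[j] - gap_open, Xp[j] - gap_open, Yp[j] - gap_extend)

    # traceback; preference order encodes the tie-breaking contract
    i, j = n, m
    out1: list[str] = []
    out2: list[str] = []
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i, j])
    # explicit preference on exact ties: M, then X (gap in first), then Y
    for cand in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[cand][i, j] == max(M[i, j], X[i, j], Y[i, j]):
            state = cand
            break
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            out1.append(aa1[i - 1])
            out2.append(aa2[j - 1])
            target = M[i, j] - _sub_score(aa1[i - 1], aa2[j - 1], matrix)
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], target)
        elif state == "X" and j > 0:
            out1.append(GAP)
            out2.append(aa2[j - 1])
            val = X[i, j]
            j -= 1
            if i == 0 and j == 0:
                state = "M"
                continue
            if np.isclose(M[i, j] - gap_open, val):
                state = "M"
            elif np.isclose(X[i, j] - gap_extend, val):
                state = "X"
            else:
                state = "Y"
        elif state == "Y" and i > 0:
            out1.append(aa1[i - 1])
            out2.append(GAP)
            val = Y[i, j]
            i -= 1
            if i == 0 and j == 0:
                state = "M"
                continue
            if np.isclose(M[i, j] - gap_open, val):
                state = "M"
            elif np.isclose(Y[i, j] - gap_extend, val):
                state = "Y"
            else:
                state = "X"
        else:  # boundary rows/columns
            state = "X" if j > 0 else "Y"
    score = max(M[n, m], X[n, m], Y[n, m])
    return ProteinAlignment(aligned1="".join(reversed(out1)),
                            aligned2="".join(reversed(out2)), score=float(score))


def _pick_state(m: float, x: float, y: float, target: float) -> str:
    for name, val in (("M", m), ("X", x), ("Y", y)):
        if np.isclose(val, target):
            return name
    # fall back to the best predecessor (float drift)
    return max((("M", m), ("X", x), ("Y", y)), key=lambda t: t[1])[0]


# ---------------------------------------------------------------------------
# codon threading

def _trim_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def _translate(cds: str) -> str:
    return "".join(CODON_TO_AA.get(cds[i:i + 3].upper(), "X")
                   for i in range(0, len(cds) - len(cds) % 3, 3))


def thread_codons(alignment: ProteinAlignment, cds1: str, cds2: str) -> tuple[str, str]:
    """Back-thread a protein alignment onto its coding sequences.

    Terminal stop codons are trimmed first; each aligned residue maps to its
    source codon and each gap to ``---``. The translation of each CDS must
    equal the corresponding ungapped protein, and internal stops are hard
    errors.
    """
    out = []
    for aligned, cds in ((alignment.aligned1, cds1), (alignment.aligned2, cds2)):
        cds = _trim_terminal_stop(cds)
        if len(cds) % 3:
            raise ThreadingError("CDS length not divisible by 3 after stop trimming")
        protein = _translate(cds)
        ungapped = aligned.replace(GAP, "")
        if len(protein) != len(ungapped):
            raise ThreadingError(
                f"protein length {len(ungapped)} does not match CDS ({len(protein)} codons)")
        stop_at = protein.find("*")
        if stop_at != -1:
            raise ThreadingError(f"internal stop codon at residue {stop_at}")
        for idx, (p, u) in enumerate(zip(protein, ungapped)):
            if p != u:
                raise ThreadingError(
                    f"translation mismatch at residue {idx}: CDS gives {p!r}, protein has {u!r}")
        pieces = []
        pos = 0
        for ch in aligned:
            if ch == GAP:
                pieces.append("---")
            else:
                pieces.append(cds[3 * pos:3 * pos + 3])
                pos += 1
        out.append("".join(pieces))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# NG86

@dataclass
class DnDsResult:
    """Nei–Gojobori site/difference counts and derived distances.

    ``dn``/``ds`` are None when the Jukes–Cantor correction is undefined
    (p >= 3/4); ``ratio`` is None when dS is zero or undefined, with the raw
    counts still available so either downstream convention can be derived.
    ``flag`` explains any undefined value.
    """

    n_sites: float
    s_sites: float
    n_diff: float
    s_diff: float
    pn: float | None
    ps: float | None
    dn: float | None
    ds: float | None
    ratio: float | None
    n_codons_used: int
    flag: str = ""


def _syn_site_count(codon: str) -> float:
    """Fractional synonymous sites: synonymous single-nt neighbors / 3 per position.

    Neighbors creating stop codons count as nonsynonymous, so sites always
    satisfy N + S = 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
    return syn / 3.0


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutation pathways.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded. Should every pathway hit a stop (rare),
    all pathways are used with stop transitions counted as nonsynonymous.
    """
    from itertools import permutations

    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    d = len(diff_pos)
    if d == 0:
        return 0.0, 0.0
    if d == 1:
        same = CODON_TO_AA[c1] == CODON_TO_AA[c2]
        return (1.0, 0.0) if same else (0.0, 1.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        syn = nonsyn = 0.0
        cur = c1
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn, blocked

    results = [walk(order) for order in permutations(diff_pos)]
    open_paths = [r for r in results if not r[2]]
    use = open_paths if open_paths else results
    syn = sum(r[0] for r in use) / len(use)
    nonsyn = sum(r[1] for r in use) / len(use)
    return syn, nonsyn


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86(codon_aln1: str, codon_aln2: str) -> DnDsResult:
    """Nei–Gojobori (1986) dN/dS from a pair of aligned coding sequences.

    Codon pairs containing gaps, ambiguous bases, or stop codons are excluded.
    Site counts are averaged over the two sequences; multi-position codon
    differences are averaged over equally weighted mutation pathways (paths
    through stops excluded). pN and pS receive the Jukes–Cantor correction
    where defined (p < 3/4).
    """
    if len(codon_aln1) != len(codon_aln2):
        raise InputError("aligned sequences differ in length")
    if len(codon_aln1) % 3:
        raise InputError("aligned length not divisible by 3")

    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(codon_aln1), 3):
        c1 = codon_aln1[i:i + 3].upper()
        c2 = codon_aln2[i:i + 3].upper()
        if GAP in c1 or GAP in c2:
            continue
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        used += 1
        s_sites = (_syn_site_count(c1) + _syn_site_count(c2)) / 2.0
        S += s_sites
        N += 3.0 - s_sites
        sd, nd = _pathway_diffs(c1, c2)
        Sd += sd
        Nd += nd

    if used == 0:
        return DnDsResult(0.0, 0.0, 0.0, 0.0, None, None, None, None, None, 0,
                          flag="no_usable_codons")

    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    ds = _jc_correct(ps) if ps is not None else None
    dn = _jc_correct(pn) if pn is not None else None

    flag = ""
    ratio: float | None = None
    if ps is not None and ps >= 0.75:
        flag = "ps_saturated"
    if pn is not None and pn >= 0.75:
        flag = (flag + ";" if flag else "") + "pn_saturated"
    if dn is not None and ds is not None:
        if ds > 0:
            ratio = float(dn / ds)
        elif dn == 0:
            flag = (flag + ";" if flag else "") + "no_differences"
        else:
            flag = (flag + ";" if flag else "") + "ds_zero"

    return DnDsResult(n_sites=N, s_sites=S, n_diff=Nd, s_diff=Sd,
                      pn=pn, ps=ps,
                      dn=float(dn) if dn is not None else None,
                      ds=float(ds) if ds is not None else None,
                      ratio=ratio, n_codons_used=used, flag=flag)


# ---------------------------------------------------------------------------
# alignment-free comparison

_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i


def word_vector(seq: str, w: int = 2) -> np.ndarray:
    """Counts of all overlapping length-w ACGT words, indexed over 4**w words.

    Windows containing any other symbol are skipped. Index order is
    lexicographic (AA..A first).
    """
    if w < 1:
        raise InputError("word size must be >= 1")
    vec = np.zeros(4 ** w, dtype=np.int64)
    b = _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = b.size - w + 1
    if m <= 0:
        return vec
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(w):
        win = b[j:j + m]
        ok &= win < 4
        codes = codes * 4 + np.where(win < 4, win, 0)
    np.add.at(vec, codes[ok], 1)
    return vec


def canberra(v1: np.ndarray, v2: np.ndarray, normalize: bool = False) -> float:
    """Canberra distance sum |x - y| / (x + y); 0/0 terms contribute nothing.

    With ``normalize`` the sum is divided by the number of nonzero-denominator
    terms, for comparability across sequences of different lengths.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise InputError("vectors must have equal dimension")
    if np.any(a < 0) or np.any(b < 0):
        raise InputError("Canberra distance requires nonnegative entries")
    den = a + b
    nz = den > 0
    terms = np.abs(a - b)[nz] / den[nz]
    total = float(terms.sum())
    if normalize:
        n = int(nz.sum())
        return total / n if n else 0.0
    return total


# ---------------------------------------------------------------------------
# per-pair pipeline

@dataclass
class GenePairDivergence:
    gene_id: str
    placement: str
    dnds: DnDsResult | None
    canberra: float | None
    word_size: int
    error: str = ""


def pair_divergence(pair: GenePair, word_size: int = 2,
                    gap_open: float = 11.0, gap_extend: float = 1.0) -> GenePairDivergence:
    """Full divergence assessment of one duplicated gene pair.

    Runs protein alignment -> codon threading -> NG86 on the coding sequences
    (when present) and the word-vector Canberra distance on the genomic
    spans. Stage failures are captured in the ``error`` field rather than
    raised, so batch processing continues over the remaining pairs.
    """
    dnds: DnDsResult | None = None
    error = ""
    if pair.copy1.cds and pair.copy2.cds:
        try:
            cds1 = _trim_terminal_stop(pair.copy1.cds)
            cds2 = _trim_terminal_stop(pair.copy2.cds)
            aln = align_proteins(_translate(cds1), _translate(cds2),
                                 gap_open=gap_open, gap_extend=gap_extend)
            ca1, ca2 = thread_codons(aln, cds1, cds2)
            dnds = ng86(ca1, ca2)
        except (InputError, ThreadingError) as exc:
            error = str(exc)

    dist: float | None = None
    if pair.copy1.genomic and pair.copy2.genomic:
        dist = canberra(word_vector(pair.copy1.genomic, word_size),
                        word_vector(pair.copy2.genomic, word_size))
    return GenePairDivergence(gene_id=pair.gene_id, placement=pair.placement,
                              dnds=dnds, canberra=dist, word_size=word_size,
                              error=error)


def divergence_table(results: list[GenePairDivergence]) -> "pandas.DataFrame":  # noqa: F821
    """Tidy per-gene table of divergence statistics."""
    import pandas as pd

    rows = []
    for res in results:
        d = res.dnds
        rows.append({
            "gene_id": res.gene_id,
            "placement": res.placement,
            "n_sites": d.n_sites if d else np.nan,
            "s_sites": d.s_sites if d else np.nan,
            "n_diff": d.n_diff if d else np.nan,
            "s_diff": d.s_diff if d else np.nan,
            "pn": d.pn if d and d.pn is not None else np.nan,
            "ps": d.ps if d and d.ps is not None else np.nan,
            "dn": d.dn if d and d.dn is not None else np.nan,
            "ds": d.ds if d and d.ds is not None else np.nan,
            "pnps": d.ratio if d and d.ratio is not None else np.nan,
            "flag": d.flag if d else "",
            "canberra": res.canberra if res.canberra is not None else np.nan,
            "error": res.error,
        })
    return pd.DataFrame(rows)
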
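"""Standard genetic code helpers shared by the simulator and the divergence stage."""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stop codons mapped to "*"
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

_NUCS = "ACGT"


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop."""
    return CODON_TO_AA[codon]


def single_nt_neighbors(codon: str) -> list[str]:
    """All 9 codons reachable by a single nucleotide substitution."""
    out = []
    for pos in range(3):
        for nt in _NUCS:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1:])
    return out


def synonymous_neighbors(codon: str) -> list[str]:
    """Single-substitution neighbors encoding the same amino acid (stops excluded)."""
    aa = CODON_TO_AA[codon]
    return [c for c in single_nt_neighbors(codon) if c not in STOP_CODONS and CODON_TO_AA[c] == aa]


def nonsynonymous_neighbors(codon: str) -> list[str]:
    """Single-substitution sense neighbors encoding a different amino acid."""
    aa = CODON_TO_AA[codon]
    return [c for c in single_nt_neighbors(codon) if c not in STOP_CODONS and CODON_TO_AA[c] != aa]
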
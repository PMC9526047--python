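"""Alignment, codon threading, NG86 and Canberra against brute-force oracles."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from haploqc import divergence, simdata
from haploqc.errors import InputError, ThreadingError

from _oracles import brute_force_align_score, naive_kmer_counts, ng86_oracle

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# protein alignment

class TestAlignProteins:
    def test_identical_sequences_align_without_gaps(self):
        aln = divergence.align_proteins("MKTAYIAK", "MKTAYIAK")
        assert aln.aligned1 == aln.aligned2 == "MKTAYIAK"
        assert not aln.degenerate

    def test_empty_sequence_degenerate(self):
        aln = divergence.align_proteins("A", "")
        assert (aln.aligned1, aln.aligned2) == ("A", "-")
        assert aln.degenerate

    @pytest.mark.parametrize("pair_seed", range(12))
    def test_score_matches_exhaustive_enumeration(self, pair_seed):
        rng = np.random.default_rng(200 + pair_seed)
        a = "".join(rng.choice(list(AA20), size=rng.integers(1, 9)))
        b = "".join(rng.choice(list(AA20), size=rng.integers(1, 9)))
        aln = divergence.align_proteins(a, b)
        oracle = brute_force_align_score(a, b, BLOSUM62, 11.0, 1.0)
        assert aln.score == pytest.approx(oracle)
        # and the reported alignment actually achieves that score
        assert _score_alignment(aln.aligned1, aln.aligned2) == pytest.approx(oracle)

    def test_gap_costs_are_affine(self):
        # one long gap must beat two short ones when extend << open
        aln = divergence.align_proteins("MKTWWWWAYI", "MKTAYI")
        gaps = aln.aligned2.count("-")
        assert gaps == 4
        assert "----" in aln.aligned2


def _score_alignment(a1: str, a2: str, gap_open=11.0, gap_extend=1.0) -> float:
    score = 0.0
    last = ""
    for x, y in zip(a1, a2):
        if x == "-" or y == "-":
            kind = "X" if x == "-" else "Y"
            score -= gap_extend if last == kind else gap_open
            last = kind
        else:
            score += float(BLOSUM62[x, y])
            last = "M"
    return score


# ---------------------------------------------------------------------------
# threading

class TestThreadCodons:
    def test_gapless_alignment_concatenates_codons(self):
        cds1, cds2, _ = simdata.generate_coding_pair(20, 1, 1, 3)
        aln = divergence.align_proteins(simdata.translate_cds(cds1),
                                        simdata.translate_cds(cds2))
        ca1, ca2 = divergence.thread_codons(aln, cds1, cds2)
        assert (ca1, ca2) == (cds1, cds2)

    def test_gap_maps_to_triple_dash(self):
        aln = divergence.ProteinAlignment("MK-F", "MKLF", 0.0)
        ca1, ca2 = divergence.thread_codons(aln, "ATGAAATTT", "ATGAAACTGTTT")
        assert ca1 == "ATGAAA---TTT"
        assert ca2 == "ATGAAACTGTTT"

    def test_internal_stop_rejected(self):
        aln = divergence.ProteinAlignment("M*F", "M*F", 0.0)
        with pytest.raises(ThreadingError):
            divergence.thread_codons(aln, "ATGTAATTT", "ATGTAATTT")

    def test_translation_mismatch_names_residue(self):
        aln = divergence.ProteinAlignment("MKF", "MKF", 0.0)
        with pytest.raises(ThreadingError, match="residue"):
            divergence.thread_codons(aln, "ATGAAATTT", "ATGCGCTTT")

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_with_codon_deletions(self, seed):
        rng = np.random.default_rng(300 + seed)
        cds1, cds2, _ = simdata.generate_coding_pair(40, 2, 2, seed)
        # delete a few codons from copy 2 to force alignment gaps
        codons = [cds2[i:i + 3] for i in range(0, len(cds2), 3)]
        for idx in sorted(rng.choice(40, size=3, replace=False), reverse=True):
            del codons[idx]
        cds2 = "".join(codons)
        aln = divergence.align_proteins(simdata.translate_cds(cds1),
                                        simdata.translate_cds(cds2))
        ca1, ca2 = divergence.thread_codons(aln, cds1, cds2)
        assert len(ca1) == len(ca2)
        assert len(ca1) % 3 == 0
        assert _translate_gapped(ca1) == aln.aligned1
        assert _translate_gapped(ca2) == aln.aligned2


def _translate_gapped(codon_aln: str) -> str:
    out = []
    for i in range(0, len(codon_aln), 3):
        codon = codon_aln[i:i + 3]
        out.append("-" if codon == "---" else simdata.translate_cds(codon))
    return "".join(out)


# ---------------------------------------------------------------------------
# NG86

class TestNG86:
    def test_identical_sequences_have_no_differences(self):
        cds1, _, _ = simdata.generate_coding_pair(30, 0, 0, 4)
        res = divergence.ng86(cds1, cds1)
        assert res.n_diff == 0 and res.s_diff == 0
        assert res.dn == 0.0 and res.ds == 0.0
        assert res.ratio is None and "no_differences" in res.flag

    def test_single_codon_synonymous_saturation(self):
        # TTT vs TTC: one synonymous difference over 1/3 synonymous sites
        res = divergence.ng86("TTT", "TTC")
        assert res.s_diff == 1.0 and res.n_diff == 0.0
        assert res.s_sites == pytest.approx(1 / 3)
        assert res.n_sites == pytest.approx(8 / 3)
        assert res.ps == pytest.approx(3.0)
        assert res.ds is None and "ps_saturated" in res.flag

    def test_sites_sum_to_three_per_codon(self):
        cds1, cds2, _ = simdata.generate_coding_pair(100, 3, 3, 5)
        res = divergence.ng86(cds1, cds2)
        assert res.n_sites + res.s_sites == pytest.approx(3 * res.n_codons_used, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        n_changes = int(rng.integers(0, 6))
        n_syn = int(rng.integers(0, n_changes + 1))
        cds1, cds2, _ = simdata.generate_coding_pair(100, n_syn, n_changes - n_syn, seed)
        res = divergence.ng86(cds1, cds2)
        oracle = ng86_oracle(cds1, cds2)
        assert res.s_sites == pytest.approx(oracle["S"], abs=1e-12)
        assert res.n_sites == pytest.approx(oracle["N"], abs=1e-12)
        assert res.s_diff == pytest.approx(oracle["Sd"], abs=1e-12)
        assert res.n_diff == pytest.approx(oracle["Nd"], abs=1e-12)
        for key, got in (("ps", res.ps), ("pn", res.pn), ("ds", res.ds), ("dn", res.dn)):
            if oracle[key] is None:
                assert got is None
            else:
                assert got == pytest.approx(oracle[key], abs=1e-12)

    def test_gapped_and_ambiguous_codons_excluded(self):
        res = divergence.ng86("ATG---AANTTT", "ATGAAAAAATTC")
        assert res.n_codons_used == 2

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            divergence.ng86("ATGAAA", "ATG")


# ---------------------------------------------------------------------------
# alignment-free comparison

class TestWordVector:
    def test_direct_read_off(self):
        vec = divergence.word_vector("AAT", 2)
        assert vec[0] == 1 and vec[3] == 1 and vec.sum() == 2  # AA, AT

    def test_empty_sequence(self):
        assert divergence.word_vector("", 2).sum() == 0

    def test_window_count_identity(self):
        seq = simdata.generate_haploid(5_000, 0.5, 12)
        for w in (1, 2, 4):
            assert divergence.word_vector(seq, w).sum() == len(seq) - w + 1

    def test_matches_kmer_dictionary(self):
        seq = simdata.generate_haploid(2_000, 0.4, 13)
        vec = divergence.word_vector(seq, 3)
        oracle = naive_kmer_counts(seq, 3, canonical=False)
        alphabet = "ACGT"
        for idx, count in enumerate(vec):
            word = "".join(alphabet[(idx >> (2 * (2 - j))) & 3] for j in range(3))
            assert count == oracle.get(word, 0)


class TestCanberra:
    def test_worked_example(self):
        d = divergence.canberra(divergence.word_vector("AAT"),
                                divergence.word_vector("ATT"))
        assert d == 2.0

    def test_identity(self):
        v = divergence.word_vector("ACGTACGT")
        assert divergence.canberra(v, v) == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(InputError):
            divergence.canberra(np.array([-1.0, 0.0]), np.array([1.0, 1.0]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4),
           st.lists(st.integers(0, 50), min_size=4, max_size=4),
           st.lists(st.integers(0, 50), min_size=4, max_size=4))
    def test_metric_properties(self, a, b, c):
        va, vb, vc = (np.array(v, dtype=float) for v in (a, b, c))
        dab = divergence.canberra(va, vb)
        assert dab == divergence.canberra(vb, va)
        assert (dab == 0.0) == bool(np.all(va == vb))
        assert dab <= divergence.canberra(va, vc) + divergence.canberra(vc, vb) + 1e-12


# ---------------------------------------------------------------------------
# gene pairs and per-pair pipeline

def _write_table(path, rows):
    lines = ["# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength"]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


class TestExtractGenePairs:
    @pytest.fixture()
    def assembly(self):
        rng = 17
        return {"ctgA": simdata.generate_haploid(2_000, 0.5, rng),
                "ctgB": simdata.generate_haploid(2_000, 0.5, rng + 1)}

    def test_complete_genes_ignored(self, tmp_path, assembly):
        table = tmp_path / "full_table.tsv"
        _write_table(table, [("g1", "Complete", "ctgA", 1, 300, "+", 100, 300)])
        pairs, _ = divergence.extract_gene_pairs(table, assembly)
        assert pairs == []

    def test_unique_and_tandem_placement(self, tmp_path, assembly):
        table = tmp_path / "full_table.tsv"
        _write_table(table, [
            ("g1", "Duplicated", "ctgA", 1, 300, "+", 100, 300),
            ("g1", "Duplicated", "ctgB", 11, 310, "+", 100, 300),
            ("g2", "Duplicated", "ctgA", 401, 700, "+", 100, 300),
            ("g2", "Duplicated", "ctgA", 901, 1200, "-", 100, 300),
        ])
        pairs, skipped = divergence.extract_gene_pairs(table, assembly)
        by_id = {p.gene_id: p for p in pairs}
        assert by_id["g1"].placement == "unique"
        assert by_id["g2"].placement == "tandem"
        assert by_id["g1"].copy1.genomic == assembly["ctgA"][0:300]
        # minus strand spans are reverse-complemented
        span = assembly["ctgA"][900:1200]
        rc = span.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert by_id["g2"].copy2.genomic == rc

    def test_out_of_bounds_and_multicopy_skipped(self, tmp_path, assembly):
        table = tmp_path / "full_table.tsv"
        _write_table(table, [
            ("g1", "Duplicated", "ctgA", 1, 99_999, "+", 100, 300),
            ("g1", "Duplicated", "ctgB", 1, 300, "+", 100, 300),
            ("g3", "Duplicated", "ctgA", 1, 300, "+", 100, 300),
            ("g3", "Duplicated", "ctgA", 301, 600, "+", 100, 300),
            ("g3", "Duplicated", "ctgB", 1, 300, "+", 100, 300),
        ])
        pairs, skipped = divergence.extract_gene_pairs(table, assembly)
        assert pairs == []
        assert skipped["out_of_bounds"] == 1
        assert skipped["multi_copy_genes"] == 1


class TestPairDivergence:
    def _pair(self, cds1, cds2, span1=None, span2=None, contigs=("A", "B")):
        return divergence.GenePair(
            gene_id="g",
            copy1=divergence.GeneCopy(contigs[0], 0, 10, "+", span1 or cds1, cds1),
            copy2=divergence.GeneCopy(contigs[1], 0, 10, "+", span2 or cds2, cds2))

    def test_identical_copies(self):
        cds, _, _ = simdata.generate_coding_pair(30, 0, 0, 21)
        res = divergence.pair_divergence(self._pair(cds, cds, contigs=("A", "A")))
        assert res.placement == "tandem"
        assert res.canberra == 0.0
        assert res.dnds.ratio is None and "no_differences" in res.dnds.flag

    def test_nonsynonymous_enriched_pair(self):
        cds1, cds2, _ = simdata.generate_coding_pair(100, 0, 4, 22)
        res = divergence.pair_divergence(self._pair(cds1, cds2))
        assert res.dnds.n_diff == 4.0 and res.dnds.s_diff == 0.0
        assert res.placement == "unique"

    def test_synonymous_enriched_pair(self):
        cds1, cds2, _ = simdata.generate_coding_pair(100, 4, 0, 23)
        res = divergence.pair_divergence(self._pair(cds1, cds2))
        assert res.dnds.s_diff == 4.0 and res.dnds.n_diff == 0.0
        if res.dnds.ratio is not None:
            assert res.dnds.ratio < 1.0

    def test_errors_collected_not_raised(self):
        res = divergence.pair_divergence(self._pair("ATGTAATTT", "ATGTAATTT"))
        assert res.error != ""
        assert res.canberra is not None


class TestDivergenceContrast:
    def test_nonsyn_enriched_pairs_score_higher(self):
        ratios = {"nonsyn": [], "syn": []}
        for seed in range(30):
            c1, c2, _ = simdata.generate_coding_pair(100, 1, 3, 1000 + seed)
            r = divergence.ng86(c1, c2).ratio
            if r is not None:
                ratios["nonsyn"].append(r)
            c1, c2, _ = simdata.generate_coding_pair(100, 3, 1, 2000 + seed)
            r = divergence.ng86(c1, c2).ratio
            if r is not None:
                ratios["syn"].append(r)
        assert np.median(ratios["nonsyn"]) > np.median(ratios["syn"])
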
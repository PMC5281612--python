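"""UTR pair construction: extraction, SNP application, diffing, summaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirdiv.io_formats import BedInterval, SnpRecord, UtrRecord
from mirdiv.utr_builder import (
    CoordinateError,
    PairError,
    UtrPair,
    annotation_percentages,
    apply_snps,
    build_pair,
    diff_utrs,
    extract_utr,
    summarize_snp_stats,
)


def interval(chrom="chr1", start=0, end=4, name="g1", strand="+"):
    return BedInterval(chrom, start, end, name, "0", strand)


class TestExtractUtr:
    def test_plus_strand_slice(self):
        utr = extract_utr({"chr1": "AACCGGTT"}, interval(start=2, end=6))
        assert utr.sequence == "CCGG"

    def test_minus_strand_reverse_complements(self):
        utr = extract_utr({"chr1": "AAACGTTT"}, interval(start=1, end=5, strand="-"))
        assert utr.sequence == "CGTT"  # revcomp("AACG")

    def test_palindromic_interval_identical_on_both_strands(self):
        genome = {"chr1": "AACCGGTT"}
        plus = extract_utr(genome, interval(start=2, end=6, strand="+"))
        minus = extract_utr(genome, interval(start=2, end=6, strand="-"))
        assert plus.sequence == minus.sequence == "CCGG"

    def test_missing_chromosome_and_out_of_bounds(self):
        with pytest.raises(CoordinateError, match="absent"):
            extract_utr({"chr1": "ACGT"}, interval(chrom="chr2"))
        with pytest.raises(CoordinateError, match="bounds"):
            extract_utr({"chr1": "ACGT"}, interval(start=2, end=9))

    @given(st.text(alphabet="ACGT", min_size=6, max_size=40))
    def test_minus_equals_revcomp_of_plus(self, chrom_seq):
        from mirdiv.io_formats import reverse_complement_dna

        genome = {"chr1": chrom_seq}
        iv_plus = interval(start=1, end=len(chrom_seq) - 1, strand="+")
        iv_minus = interval(start=1, end=len(chrom_seq) - 1, strand="-")
        assert extract_utr(genome, iv_minus).sequence == reverse_complement_dna(
            extract_utr(genome, iv_plus).sequence
        )


class TestApplySnps:
    def test_substitutes_alt(self):
        utr = UtrRecord("g1", "A", "ACGT")
        pair = apply_snps(utr, [SnpRecord("g1", 1, "C", "T")])
        assert (pair.utr_a.sequence, pair.utr_b.sequence) == ("ACGT", "ATGT")

    def test_ref_mismatch_names_gene_and_position(self):
        utr = UtrRecord("g1", "A", "ACGT")
        with pytest.raises(PairError, match=r"gene 'g1' at pos 1: expected 'G', found 'C'"):
            apply_snps(utr, [SnpRecord("g1", 1, "G", "T")])

    def test_duplicate_position_rejected(self):
        utr = UtrRecord("g1", "A", "ACGT")
        with pytest.raises(PairError, match="two SNPs at position 1"):
            apply_snps(utr, [SnpRecord("g1", 1, "C", "T"), SnpRecord("g1", 1, "C", "G")])

    def test_empty_snp_list_is_identity(self):
        utr = UtrRecord("g1", "A", "ACGT")
        pair = apply_snps(utr, [])
        assert pair.utr_b.sequence == utr.sequence
        assert pair.snps == ()


class TestDiffUtrs:
    def test_single_transition(self):
        diff = diff_utrs(UtrRecord("g1", "A", "ACGT"), UtrRecord("g1", "B", "ATGT"))
        assert [(s.pos, s.ref, s.alt, s.mut_class) for s in diff.snps] == [
            (1, "C", "T", "transition")
        ]
        assert diff.n_masked == 0

    def test_ambiguous_position_masked_not_called(self):
        diff = diff_utrs(UtrRecord("g1", "A", "ACNT"), UtrRecord("g1", "B", "ACAT"))
        assert diff.snps == []
        assert diff.n_masked == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(PairError, match="unequal length"):
            diff_utrs(UtrRecord("g1", "A", "ACGT"), UtrRecord("g1", "B", "ACG"))

    @given(
        st.text(alphabet="ACGT", min_size=3, max_size=60).flatmap(
            lambda seq: st.tuples(
                st.just(seq),
                st.lists(
                    st.tuples(
                        st.integers(min_value=0, max_value=len(seq) - 1),
                        st.sampled_from("ACGT"),
                    ),
                    max_size=10,
                    unique_by=lambda t: t[0],
                ),
            )
        )
    )
    def test_apply_then_diff_round_trips(self, seq_and_muts):
        seq, muts = seq_and_muts
        utr = UtrRecord("g1", "A", seq)
        snps = [
            SnpRecord("g1", pos, seq[pos], alt) for pos, alt in muts if seq[pos] != alt
        ]
        pair = apply_snps(utr, snps)
        assert diff_utrs(pair.utr_a, pair.utr_b).snps == sorted(snps, key=lambda s: s.pos)

    def test_pair_invariant_enforced(self):
        # SNP list not matching the sequence difference is rejected
        with pytest.raises(PairError, match="does not match sequence differences"):
            UtrPair("g1", UtrRecord("g1", "A", "ACGT"), UtrRecord("g1", "B", "ATGT"), ())


class TestSnpSummary:
    def test_printed_count_percentages(self):
        assert annotation_percentages(19994, 11761, 3066) == (59, 26)

    def _pairs(self, snp_counts):
        pairs = []
        for i, n in enumerate(snp_counts):
            seq = "ACGT" * 10
            snps = [SnpRecord(f"g{i}", j, seq[j], "T" if seq[j] != "T" else "A") for j in range(n)]
            utr = UtrRecord(f"g{i}", "A", seq)
            pairs.append(apply_snps(utr, snps))
        return pairs

    def test_mean_median_max_both_denominators(self):
        pairs = self._pairs([0, 1, 3])
        per_utr = summarize_snp_stats(pairs, denominator="genes-with-utr")
        assert per_utr.mean_snps_per_utr == pytest.approx(4 / 3, abs=1e-9)
        per_snp_gene = summarize_snp_stats(pairs, denominator="genes-with-snp")
        assert per_snp_gene.mean_snps_per_utr == pytest.approx(2.0)
        for summary in (per_utr, per_snp_gene):
            assert summary.median_snps_per_utr == 1.0
            assert summary.max_snps_per_utr == 3
            assert summary.total_snps == 4
            assert summary.n_genes_with_snp == 2

    def test_percentages_wired_through_summary(self):
        pairs = self._pairs([0, 1, 3])
        summary = summarize_snp_stats(pairs, n_genes_total=6)
        assert summary.pct_genes_with_utr == 50  # 3 of 6
        assert summary.pct_utr_genes_with_snp == 67  # 2 of 3

    def test_empty_input_rejected(self):
        with pytest.raises(PairError):
            summarize_snp_stats([])
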
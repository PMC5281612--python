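"""Cross-taxon site matching, event classification and Venn aggregation."""

import pytest

from mirdiv.context_scoring import ScoredSite
from mirdiv.diff_classifier import (
    classify_mirna_events,
    compare_gene_mirna,
    match_sites,
    summarize_gene_events,
    venn_counts,
)


def make_site(start, site_type="8mer", gene="g1", mirna="m1", taxon="A", score=-0.3):
    length = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[site_type]
    return ScoredSite(
        gene_id=gene,
        mirna_name=mirna,
        site_type=site_type,
        start=start,
        end=start + length,
        taxon=taxon,
        f_type=score,
        f_au=0.0,
        f_3p=0.0,
        f_pos=0.0,
        context_score=score,
    )


class TestMatchSites:
    def test_identical_site_matches(self):
        m = match_sites([make_site(3)], [make_site(3, taxon="B")])
        assert (len(m.common), len(m.only_a), len(m.only_b)) == (1, 0, 0)

    def test_site_in_one_taxon_only(self):
        m = match_sites([make_site(3)], [])
        assert (len(m.common), len(m.only_a), len(m.only_b)) == (0, 1, 0)

    def test_type_change_at_same_position_is_polymorphic(self):
        m = match_sites([make_site(3, "7mer-A1")], [make_site(3, "8mer", taxon="B")])
        assert (len(m.common), len(m.only_a), len(m.only_b)) == (0, 1, 1)
        assert len(m.type_shifts) == 1

    def test_conservation_identity(self):
        sites_a = [make_site(3), make_site(20), make_site(40)]
        sites_b = [make_site(3, taxon="B"), make_site(60, taxon="B")]
        m = match_sites(sites_a, sites_b)
        assert len(sites_a) + len(sites_b) == 2 * len(m.common) + len(m.only_a) + len(m.only_b)


class TestClassifyEvents:
    @pytest.mark.parametrize(
        "starts_a,starts_b,expected",
        [
            ([3], [], {"gain"}),
            ([], [3], {"loss"}),
            ([3, 20], [3], {"increase"}),
            ([3], [3, 20], {"decrease"}),
            ([3], [3], set()),                      # shared only
            ([3], [20], {"gain", "loss"}),          # disjoint, nothing common
            ([3, 20, 40], [3, 60], {"increase", "decrease"}),
        ],
    )
    def test_category_rules(self, starts_a, starts_b, expected):
        m = match_sites(
            [make_site(s) for s in starts_a],
            [make_site(s, taxon="B") for s in starts_b],
        )
        assert classify_mirna_events(m) == frozenset(expected)

    @pytest.mark.parametrize(
        "starts_a,starts_b",
        [([3], []), ([], [3]), ([3, 20], [3]), ([3], [20]), ([3, 20, 40], [3, 60])],
    )
    def test_swapping_taxa_mirrors_categories(self, starts_a, starts_b):
        swap = {"gain": "loss", "loss": "gain", "increase": "decrease", "decrease": "increase"}
        fwd = classify_mirna_events(
            match_sites([make_site(s) for s in starts_a], [make_site(s) for s in starts_b])
        )
        rev = classify_mirna_events(
            match_sites([make_site(s) for s in starts_b], [make_site(s) for s in starts_a])
        )
        assert rev == frozenset(swap[c] for c in fwd)


class TestGeneSummaries:
    def test_thirteen_mirnas_each_losing_sites(self):
        comparisons = [
            compare_gene_mirna("g1", f"m{i:02d}", [], [make_site(10 * i, mirna=f"m{i:02d}", taxon="B")])
            for i in range(13)
        ]
        summary = summarize_gene_events(comparisons)
        assert summary.n_loss == 13
        assert summary.n_gain == summary.n_increase == summary.n_decrease == 0
        assert summary.psn == 13 and summary.csn == 0

    def test_gain_and_loss_at_same_position_counts_position_once(self):
        comparisons = [
            compare_gene_mirna("g1", "m1", [make_site(5, mirna="m1")], []),
            compare_gene_mirna("g1", "m2", [], [make_site(5, mirna="m2", taxon="B")]),
        ]
        summary = summarize_gene_events(comparisons)
        assert summary.categories == frozenset({"gain", "loss"})
        assert summary.psn == 1  # one polymorphic position shared by two miRNAs

    def test_matched_and_unmatched_positions_partition(self):
        comparisons = [
            compare_gene_mirna(
                "g1", "m1", [make_site(5), make_site(30)], [make_site(5, taxon="B")]
            )
        ]
        summary = summarize_gene_events(comparisons)
        assert (summary.psn, summary.csn) == (1, 1)

    def test_no_events_gives_empty_summary(self):
        comparisons = [compare_gene_mirna("g1", "m1", [make_site(5)], [make_site(5, taxon="B")])]
        summary = summarize_gene_events(comparisons)
        assert summary.categories == frozenset()
        assert summary.psn == 0 and summary.csn == 1

    def test_mixed_genes_rejected(self):
        comps = [
            compare_gene_mirna("g1", "m1", [make_site(5)], []),
            compare_gene_mirna("g2", "m1", [make_site(5, gene="g2")], []),
        ]
        with pytest.raises(ValueError, match="multiple genes"):
            summarize_gene_events(comps)


class TestVennCounts:
    def _summary(self, gene, category, position):
        if category == "gain":
            comp = compare_gene_mirna(gene, "m1", [make_site(position, gene=gene)], [])
        else:
            comp = compare_gene_mirna(gene, "m1", [], [make_site(position, gene=gene, taxon="B")])
        return summarize_gene_events([comp])

    def test_disjoint_gain_and_loss_sets(self):
        summaries = [self._summary(f"ga{i}", "gain", 10) for i in range(10)]
        summaries += [self._summary(f"lo{i}", "loss", 10) for i in range(5)]
        counts = venn_counts(summaries)
        assert counts["gain"] == 10
        assert counts["loss"] == 5
        assert counts["gain&loss"] == 0

    def test_gene_with_both_gain_and_loss(self):
        comps = [
            compare_gene_mirna("g1", "m1", [make_site(5)], []),
            compare_gene_mirna("g1", "m2", [], [make_site(40, mirna="m2", taxon="B")]),
        ]
        counts = venn_counts([summarize_gene_events(comps)])
        assert counts["gain"] == counts["loss"] == counts["gain&loss"] == 1

    def test_empty_input_all_zero(self):
        counts = venn_counts([])
        assert set(counts.values()) == {0}
        assert len(counts) == 15  # all non-empty subsets of 4 categories
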
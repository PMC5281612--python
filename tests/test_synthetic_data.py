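"""Synthetic dataset generator: determinism, planted truth, SNP process."""

import math

import pytest

from mirdiv.site_scanner import find_seed_sites, target_motifs
from mirdiv.synthetic_data import (
    SimulationConfig,
    SimulationError,
    emit_dataset,
    generate_mirnas,
    generate_pair_with_truth,
    read_dataset,
)
from mirdiv.utr_builder import diff_utrs

SMALL = SimulationConfig(
    n_genes=20,
    n_mirnas=8,
    planted_events=(("gain", 5), ("loss", 5), ("increase", 3), ("decrease", 3), ("shared", 4)),
    rng_seed=11,
)


@pytest.fixture(scope="module")
def small_dataset():
    return generate_pair_with_truth(SMALL)


class TestGenerateMirnas:
    def test_deterministic_for_fixed_seed(self):
        a = generate_mirnas(SMALL)
        b = generate_mirnas(SMALL)
        assert [(m.name, m.sequence) for m in a] == [(m.name, m.sequence) for m in b]

    def test_seeds_pairwise_distinct(self):
        mirnas = generate_mirnas(SimulationConfig(n_mirnas=2, rng_seed=0))
        assert len({m.seed6 for m in mirnas}) == 2

    def test_default_length_defines_three_prime_region(self):
        for m in generate_mirnas(SMALL):
            assert m.three_prime_region is not None

    def test_capacity_exceeded_rejected(self):
        with pytest.raises(SimulationError, match="distinct"):
            generate_mirnas(SimulationConfig(n_mirnas=4**6 + 1))


class TestGeneratePairWithTruth:
    def test_deterministic_dataset(self, small_dataset):
        pairs, truth = small_dataset
        pairs2, truth2 = generate_pair_with_truth(SMALL)
        assert [(p.utr_a.sequence, p.utr_b.sequence, p.snps) for p in pairs] == [
            (p.utr_a.sequence, p.utr_b.sequence, p.snps) for p in pairs2
        ]
        assert truth.records == truth2.records

    def test_planted_gain_visible_to_scanner_in_taxon_a_only(self, small_dataset):
        pairs, truth = small_dataset
        by_gene = {p.gene_id: p for p in pairs}
        mirnas = {m.name: m for m in truth.mirnas}
        checked = 0
        for record in truth.records:
            if record.category != "gain":
                continue
            pair = by_gene[record.gene_id]
            mirna = mirnas[record.mirna_name]
            starts_a = {s.start for s in find_seed_sites(pair.utr_a, mirna)}
            starts_b = {s.start for s in find_seed_sites(pair.utr_b, mirna)}
            assert starts_a == set(record.sites_a)
            assert starts_b == set(record.sites_b) == set()
            checked += 1
        assert checked > 0

    def test_gain_loss_events_carry_a_seed_region_snp(self, small_dataset):
        pairs, truth = small_dataset
        for record in truth.records:
            if record.category == "shared":
                assert record.snps == ()
                continue
            assert len(record.snps) >= 1
            motif_positions = set()
            for start in (*record.sites_a, *record.sites_b):
                motif_positions.update(range(start, start + 8))
            for snp in record.snps:
                assert snp.pos in motif_positions

    def test_shared_sites_contain_no_snps(self, small_dataset):
        pairs, truth = small_dataset
        snps_by_gene = {p.gene_id: {s.pos for s in p.snps} for p in pairs}
        for record in truth.records:
            for start in set(record.sites_a) & set(record.sites_b):
                span = set(range(start, start + 8))
                assert not (span & snps_by_gene[record.gene_id])

    def test_no_accidental_seed_cores_off_the_plant(self, small_dataset):
        # scanner output must equal planted truth for every (gene, miRNA)
        pairs, truth = small_dataset
        expected = truth.by_gene_mirna()
        mirnas = {m.name: m for m in truth.mirnas}
        for pair in pairs:
            for name, mirna in mirnas.items():
                rec = expected.get((pair.gene_id, name))
                want_a = set(rec.sites_a) if rec else set()
                want_b = set(rec.sites_b) if rec else set()
                assert {s.start for s in find_seed_sites(pair.utr_a, mirna)} == want_a
                assert {s.start for s in find_seed_sites(pair.utr_b, mirna)} == want_b

    def test_zero_snp_rate_with_shared_events_only(self):
        config = SimulationConfig(
            n_genes=4,
            n_mirnas=3,
            snp_rate=0.0,
            planted_events=(("shared", 4),),
            rng_seed=2,
        )
        pairs, truth = generate_pair_with_truth(config)
        for pair in pairs:
            assert pair.snps == ()
            assert diff_utrs(pair.utr_a, pair.utr_b).snps == []

    def test_utr_too_short_rejected(self):
        config = SimulationConfig(
            n_genes=1,
            n_mirnas=2,
            utr_length_range=(30, 30),
            planted_events=(("increase", 1), ("decrease", 1)),
            rng_seed=0,
        )
        with pytest.raises(SimulationError, match="too short"):
            generate_pair_with_truth(config)


class TestSnpProcess:
    def test_background_density_matches_rate(self):
        length, rate, n_genes = 300, 0.0055, 400
        config = SimulationConfig(
            n_genes=n_genes,
            n_mirnas=10,
            utr_length_range=(length, length),
            snp_rate=rate,
            planted_events=(),
            rng_seed=9,
        )
        pairs, _ = generate_pair_with_truth(config)
        mean = sum(len(p.snps) for p in pairs) / n_genes
        expected = rate * length
        se = math.sqrt(expected / n_genes)  # Poisson-like SE of the mean
        assert abs(mean - expected) <= 3 * se

    def test_emitted_snp_titv_tracks_weight(self, tmp_path):
        from mirdiv.divergence_stats import titv_ratio
        from mirdiv.io_formats import read_snp_table

        weight = 1.93
        config = SimulationConfig(
            n_genes=150,
            n_mirnas=10,
            utr_length_range=(300, 300),
            snp_rate=0.05,
            planted_events=(),
            titv_weight=weight,
            rng_seed=13,
        )
        pairs, truth = generate_pair_with_truth(config)
        emit_dataset(pairs, truth, tmp_path)
        snps = read_snp_table(tmp_path / "snps.tsv")
        assert len(snps) > 1500
        report = titv_ratio(snps)
        p = weight / (1 + weight)
        se_ratio = math.sqrt(p * (1 - p) / len(snps)) / (1 - p) ** 2
        assert abs(report.ratio - weight) <= 3 * se_ratio


class TestEmitDataset:
    def test_round_trip_reproduces_objects(self, small_dataset, tmp_path):
        pairs, truth = small_dataset
        emit_dataset(pairs, truth, tmp_path)
        pairs2, truth2 = read_dataset(tmp_path)
        assert [(p.utr_a.sequence, p.utr_b.sequence, p.snps) for p in pairs] == [
            (p.utr_a.sequence, p.utr_b.sequence, p.snps) for p in pairs2
        ]
        assert truth2.records == truth.records
        assert [(m.name, m.sequence) for m in truth2.mirnas] == [
            (m.name, m.sequence) for m in truth.mirnas
        ]

    def test_truth_row_count_equals_planted_events(self, small_dataset, tmp_path):
        pairs, truth = small_dataset
        paths = emit_dataset(pairs, truth, tmp_path)
        n_rows = len(paths["truth"].read_text().splitlines()) - 1  # header
        assert n_rows == sum(n for _, n in SMALL.planted_events)

    def test_emission_is_byte_deterministic(self, small_dataset, tmp_path):
        pairs, truth = small_dataset
        p1 = emit_dataset(pairs, truth, tmp_path / "one")
        p2 = emit_dataset(pairs, truth, tmp_path / "two")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
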
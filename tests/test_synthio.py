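"""Generator correctness: determinism, distributional targets, structure."""

import numpy as np
import pytest
from scipy import stats

from hopkit import synthio
from hopkit._codon import STOP_CODONS
from hopkit.annotmerge import write_gff3
from hopkit.ksdating import CodonAlignment, ks_ng86
from hopkit.synthio import (
    BlockSpec,
    GenomeSpec,
    KmerSpec,
    LabelSpec,
    PopgenSpec,
    SimConfig,
    simulate_block_labels,
    simulate_divergent_pairs,
    simulate_genome,
    simulate_kmer_histogram,
    simulate_mapping_population,
    simulate_synteny_dataset,
    write_fasta,
    write_kmer_histogram,
)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(ks_components=((0.1, 0.3, 0.5), (0.2, 0.3, 0.6)))

    def test_fractions_bounded(self):
        with pytest.raises(ValueError):
            KmerSpec(heterozygosity=1.5)
        with pytest.raises(ValueError):
            LabelSpec(p_terpene=-0.1)

    def test_component_beyond_saturation_bound_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            SimConfig(ks_components=((6.0, 0.3, 1.0),))


class TestGenome:
    def test_placement_non_overlapping_and_valid(self, tmp_path):
        cfg = SimConfig(seed=1, genome_spec=GenomeSpec(
            n_scaffolds=1, scaffold_length=10_000, n_genes=10))
        scaffolds, genes = simulate_genome(cfg)
        assert len(genes) == 10
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert all(e <= 10_000 for _, e in spans)
        write_gff3(genes, tmp_path / "g.gff3")  # must be well-formed

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=9, genome_spec=GenomeSpec(
            scaffold_length=20_000, n_genes=8))
        for run in ("a", "b"):
            scaffolds, genes = simulate_genome(cfg)
            write_fasta(scaffolds.records, tmp_path / f"{run}.fa")
            write_gff3(genes, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_uniform_composition_frequencies(self):
        cfg = SimConfig(seed=2, genome_spec=GenomeSpec(
            scaffold_length=1_000_000, n_genes=0))
        scaffolds, _ = simulate_genome(cfg)
        seq = scaffolds.records[0][1]
        for b in "ACGT":
            assert seq.count(b) / len(seq) == pytest.approx(0.25, abs=0.01)

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(SimConfig(genome_spec=GenomeSpec(
                scaffold_length=500, n_genes=50)))


class TestDivergentPairs:
    def test_zero_divergence_component_gives_identical_pairs(self):
        cfg = SimConfig(seed=3, n_pairs=5, codon_length=60,
                        ks_components=((0.0, 0.0, 1.0),))
        for p in simulate_divergent_pairs(cfg):
            assert p.seq_a == p.seq_b
            assert p.ks_true == 0.0

    def test_no_stop_codons_and_in_frame(self):
        cfg = SimConfig(seed=4, n_pairs=10, codon_length=100,
                        ks_components=((0.5, 0.2, 1.0),))
        for p in simulate_divergent_pairs(cfg):
            assert len(p.seq_a) == len(p.seq_b) == 300
            for seq in (p.seq_a, p.seq_b):
                codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
                assert not codons & STOP_CODONS

    def test_realized_ks_tracks_target(self):
        cfg = SimConfig(seed=5, n_pairs=30, codon_length=300,
                        ks_components=((0.25, 0.0, 1.0),))
        pairs = simulate_divergent_pairs(cfg)
        ests = [
            ks_ng86(CodonAlignment(p.pair_id, p.seq_a, p.seq_b)).ks
            for p in pairs
        ]
        assert np.mean(ests) == pytest.approx(0.25, abs=0.02)

    def test_deterministic_for_seed(self):
        cfg = SimConfig(seed=6, n_pairs=5, codon_length=60)
        p1 = simulate_divergent_pairs(cfg)
        p2 = simulate_divergent_pairs(cfg)
        assert [(a.seq_a, a.seq_b) for a in p1] == [(b.seq_a, b.seq_b) for b in p2]

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError, match="codon_length"):
            simulate_divergent_pairs(SimConfig(codon_length=30))


class TestSyntenyDataset:
    def test_independent_labels_match_binomial_oracle(self):
        cfg = SimConfig(seed=7, block_spec=BlockSpec(n_blocks=400),
                        label_spec=LabelSpec(p_terpene=0.5, p_defense=0.5,
                                             dependence=0.0))
        ds = simulate_synteny_dataset(cfg)
        both = sum(
            1 for ls in ds.block_labels if {"terpene", "defense"} <= ls
        )
        n, p = 400, 0.25
        sd = np.sqrt(n * p * (1 - p))
        assert abs(both - n * p) <= 3 * sd

    def test_zero_ltr_rate_means_no_repeats(self):
        cfg = SimConfig(seed=8, block_spec=BlockSpec(n_blocks=20, ltr_rate=0.0))
        ds = simulate_synteny_dataset(cfg)
        assert ds.repeat_intervals == []

    def test_truth_table_consistent_with_labels(self):
        cfg = SimConfig(seed=9, block_spec=BlockSpec(n_blocks=50))
        ds = simulate_synteny_dataset(cfg)
        for row, labels in zip(ds.truth.itertuples(), ds.block_labels):
            assert row.has_terpene == ("terpene" in labels)
            assert row.has_defense == ("defense" in labels)
        # per-scaffold tallies match the gene labels actually planted
        for scaf, counts in ds.per_scaffold_label_counts.items():
            for label, n in counts.items():
                actual = sum(
                    1 for g in ds.genes_a + ds.genes_b
                    if g.scaffold == scaf and label in g.labels
                )
                assert actual == n

    def test_block_label_dependence_raises_cooccurrence(self, rng):
        rates = []
        for dep in (0.0, 0.5, 1.0):
            mat = simulate_block_labels(4000, 0.3, 0.3, dep,
                                        np.random.default_rng(10))
            rates.append(np.mean(mat[:, 0] & mat[:, 1]))
        assert rates[0] < rates[1] < rates[2]


class TestKmerHistogram:
    def test_haploid_noiseless_single_peak_and_mass(self):
        cfg = SimConfig(seed=11, kmer_spec=KmerSpec(
            genome_size=200_000, heterozygosity=0.0, error_rate=0.0,
            coverage=30.0))
        hist = simulate_kmer_histogram(cfg)
        d, c = hist.arrays()
        assert d[np.argmax(c)] in (29, 30)
        total_mass = float((d * c).sum())
        assert total_mass == pytest.approx(200_000 * 30, rel=0.02)

    def test_het_mass_fraction_monotone_in_heterozygosity(self):
        masses = []
        for het in (0.01, 0.05):
            cfg = SimConfig(seed=12, kmer_spec=KmerSpec(
                genome_size=200_000, heterozygosity=het, error_rate=0.0))
            d, c = simulate_kmer_histogram(cfg).arrays()
            het_region = (d >= 8) & (d <= 22)
            masses.append((d[het_region] * c[het_region]).sum() / (d * c).sum())
        assert masses[0] < masses[1]

    def test_deterministic_for_seed(self, tmp_path):
        cfg = SimConfig(seed=13, kmer_spec=KmerSpec(genome_size=100_000))
        write_kmer_histogram(simulate_kmer_histogram(cfg), tmp_path / "a")
        write_kmer_histogram(simulate_kmer_histogram(cfg), tmp_path / "b")
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()


class TestMappingPopulation:
    def test_segregation_ratios(self):
        cfg = SimConfig(seed=14, popgen_spec=PopgenSpec(
            n_markers=400, sex_linked_fraction=0.0, missing_rate=0.0))
        gm, _ = simulate_mapping_population(cfg)
        # aggregate A:H ratio over test-cross markers (those without B)
        has_b = (gm.genotypes == "B").any(axis=1)
        tc = gm.genotypes[~has_b]
        n_a, n_h = (tc == "A").sum(), (tc == "H").sum()
        assert n_a / (n_a + n_h) == pytest.approx(0.5, abs=0.02)
        f2 = gm.genotypes[has_b]
        counts = [(f2 == g).sum() for g in "AHB"]
        total = sum(counts)
        assert counts[0] / total == pytest.approx(0.25, abs=0.02)
        assert counts[1] / total == pytest.approx(0.50, abs=0.02)

    def test_fully_sex_linked_marker_has_tiny_p(self):
        """Closed-form chi-squared on the perfect 2x2 table at n=281."""
        cfg = SimConfig(seed=15, popgen_spec=PopgenSpec(
            n_markers=50, sex_linked_fraction=0.02, missing_rate=0.0))
        gm, truth = simulate_mapping_population(cfg)
        i = gm.marker_ids.index(truth["sex_linked_markers"][0])
        row = gm.genotypes[i]
        sex = np.asarray(gm.sex)
        table = np.array([
            [(row[sex == s] == g).sum() for s in ("female", "male")]
            for g in ("A", "H")
        ])
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(281, abs=1e-9)  # perfect association
        assert p < 1e-10

    def test_sex_linked_markers_on_designated_scaffold(self):
        cfg = SimConfig(seed=16)
        gm, truth = simulate_mapping_population(cfg)
        idx = [gm.marker_ids.index(m) for m in truth["sex_linked_markers"]]
        assert all(gm.scaffolds[i] == truth["sex_scaffold"] for i in idx)

    def test_deterministic_for_seed(self):
        cfg = SimConfig(seed=17, popgen_spec=PopgenSpec(n_markers=100))
        g1, _ = simulate_mapping_population(cfg)
        g2, _ = simulate_mapping_population(cfg)
        assert np.array_equal(g1.genotypes, g2.genotypes)
        assert g1.sex == g2.sex
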
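"""Synthetic-data generators: determinism, bounds, planted truth."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proxiscape.context import normalize_contact_vector
from proxiscape.features import filter_edit_events
from proxiscape.simulate import (
    EditSimConfig,
    SimulationConfig,
    plant_labeled_clusters,
    simulate_context,
    simulate_editing,
    simulate_gene_universe,
    simulate_proteome,
)
from proxiscape.types import LabelStatus


class TestGeneUniverse:
    def test_counts_and_bounds(self, small_genome):
        genes, cfg = small_genome
        assert len(genes) == 500
        for rec in genes:
            assert 0 <= rec.start < rec.end <= 50_000_000
            assert rec.tpm >= 0

    def test_deterministic_per_seed(self, small_genome):
        genes, cfg = small_genome
        again = simulate_gene_universe(cfg)
        assert genes.to_frame().equals(again.to_frame())

    def test_different_seed_differs(self, small_genome):
        genes, cfg = small_genome
        other = simulate_gene_universe(
            SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        )
        assert not genes.to_frame().equals(other.to_frame())

    def test_capacity_violation_errors(self):
        with pytest.raises(ValueError):
            simulate_gene_universe(
                SimulationConfig(n_chroms=1, chrom_length_bp=1000, n_genes=5000, n_labeled=0)
            )

    def test_midpoints_distinct_within_chromosome(self, small_genome):
        genes, _ = small_genome
        df = genes.to_frame()
        df["mid"] = (df.start + df.end) // 2
        for _, grp in df.groupby("chrom"):
            assert grp.mid.is_unique


class TestPlantedClusters:
    def test_cluster_placement_binomially_consistent(self):
        """60 labeled at cluster_fraction 0.7: inside-count falls in the
        central 99.9% interval of Bin(60, 0.7)."""
        cfg = SimulationConfig(
            n_chroms=2, chrom_length_bp=50_000_000, n_genes=2000, n_labeled=60,
            cluster_regions=[("chr1", 10_000_000, 15_000_000)], cluster_fraction=0.7, seed=13,
        )
        lo, hi = sps.binom.ppf([0.0005, 0.9995], 60, 0.7)
        assert (lo, hi) == (30, 53)  # frozen from the binomial quantile oracle
        genes = simulate_gene_universe(cfg)
        plant = plant_labeled_clusters(genes, cfg)
        assert lo <= len(plant.in_cluster_ids) <= hi
        assert len(plant.labeled_ids) == 60

    def test_zero_fraction_no_planting(self):
        cfg = SimulationConfig(
            n_chroms=2, chrom_length_bp=50_000_000, n_genes=1000, n_labeled=40,
            cluster_regions=[("chr1", 10_000_000, 15_000_000)], cluster_fraction=0.0, seed=3,
        )
        genes = simulate_gene_universe(cfg)
        plant = plant_labeled_clusters(genes, cfg)
        assert plant.in_cluster_ids == []

    def test_full_fraction_single_chromosome(self):
        cfg = SimulationConfig(
            n_chroms=2, chrom_length_bp=50_000_000, n_genes=1000, n_labeled=10,
            cluster_regions=[("chr1", 0, 50_000_000)], cluster_fraction=1.0, seed=3,
        )
        genes = simulate_gene_universe(cfg)
        plant = plant_labeled_clusters(genes, cfg)
        by_id = {r.gene_id: r.chrom for r in genes}
        assert all(by_id[g] == "chr1" for g in plant.labeled_ids)

    def test_status_covers_every_gene(self, clustered_genome):
        genes, plant, _ = clustered_genome
        assert set(plant.status) == set(genes.gene_ids)
        n_lab = sum(1 for s in plant.status.values() if s == LabelStatus.LABELED)
        assert n_lab == 60

    def test_empty_cluster_region_errors(self):
        cfg = SimulationConfig(
            n_chroms=1, chrom_length_bp=10_000_000, n_genes=5, n_labeled=2,
            cluster_regions=[("chr1", 0, 10)], cluster_fraction=0.8, seed=0,
        )
        genes = simulate_gene_universe(cfg)
        with pytest.raises(ValueError, match="no genes"):
            plant_labeled_clusters(genes, cfg)


class TestProteomeSim:
    def test_truth_counts_and_determinism(self):
        m1, t1 = simulate_proteome(300, 3, 50, 2.0, 0.3, seed=1)
        m2, t2 = simulate_proteome(300, 3, 50, 2.0, 0.3, seed=1)
        assert (t1 != "").sum() == 150
        assert np.array_equal(m1.raw_log2fe, m2.raw_log2fe)
        assert np.array_equal(m1.fdr, m2.fdr)

    def test_null_effect_indistinguishable(self):
        """With effect 0 the planted rows carry no enrichment signal."""
        m, t = simulate_proteome(400, 2, 100, 0.0, 0.5, seed=2)
        planted = m.raw_log2fe[(t != "").to_numpy()].ravel()
        background = m.raw_log2fe[(t == "").to_numpy()].ravel()
        assert sps.mannwhitneyu(planted, background).pvalue > 0.01

    def test_dimension_violation_errors(self):
        with pytest.raises(ValueError):
            simulate_proteome(100, 3, 50, 2.0, 0.3, seed=0)


class TestContextSim:
    def test_peak_gain_recovered_in_contact_means(self, clustered_genome):
        genes, plant, cfg = clustered_genome
        ctx = simulate_context(genes, plant.status, cfg.cluster_regions,
                               bin_bp=250_000, peak_gain=4.0, seed=5)
        cv = ctx.contacts["chr1"]
        n_bins = cv.values.size
        in_cluster = np.zeros(n_bins, dtype=bool)
        s, e = 20_000_000, 25_000_000
        in_cluster[s // 250_000 : e // 250_000] = True
        ratio = cv.values[in_cluster].mean() / cv.values[~in_cluster].mean()
        assert n_bins >= 200
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_unit_gain_null_peak_calibration(self, clustered_genome):
        """peak_gain 1: peak calls above the 1.5x median cutoff stay near the
        exponential-tail expectation P(X > 1.5 * median)."""
        genes, plant, cfg = clustered_genome
        ctx = simulate_context(genes, plant.status, cfg.cluster_regions,
                               bin_bp=250_000, peak_gain=1.0, seed=8)
        vals = np.concatenate([ctx.contacts[c].values for c in ctx.contacts])
        _, peaks = normalize_contact_vector(ctx.contacts["chr1"])
        n_bins = ctx.contacts["chr1"].values.size
        expected_rate = np.exp(-1.5 * np.log(2))  # exp tail above 1.5 x its median
        se = np.sqrt(expected_rate * (1 - expected_rate) / n_bins)
        assert abs(peaks.size / n_bins - expected_rate) < 5 * se

    def test_forced_inverted_pair_truth(self, clustered_genome):
        genes, plant, cfg = clustered_genome
        ctx = simulate_context(
            genes, plant.status, cfg.cluster_regions,
            inverted_pair_fraction_labeled=1.0, inverted_pair_fraction_unlabeled=0.0,
            background_repeats_per_mb=0.0, seed=4,
        )
        labeled = {g for g, s in plant.status.items() if s == LabelStatus.LABELED}
        # every labeled gene away from a chromosome edge gets a planted pair
        assert ctx.inverted_pair_truth <= labeled
        assert len(ctx.inverted_pair_truth) == len(labeled)

    def test_polii_shift_for_labeled(self, clustered_genome):
        genes, plant, cfg = clustered_genome
        ctx = simulate_context(genes, plant.status, cfg.cluster_regions,
                               polii_log2_shift=1.0, seed=6)
        lab = [g for g, s in plant.status.items() if s == LabelStatus.LABELED]
        unlab = [g for g, s in plant.status.items() if s == LabelStatus.UNLABELED]
        assert np.median(ctx.polii_density[lab]) > np.median(ctx.polii_density[unlab])


class TestEditingSim:
    def test_counts_truth_and_strand_rule(self, clustered_genome):
        genes, plant, cfg = clustered_genome
        ctx = simulate_context(genes, plant.status, cfg.cluster_regions, seed=4)
        sim = simulate_editing(genes, ctx.repeats, EditSimConfig(n_true_edits=100, n_snps=50, seed=3))
        assert len(sim.events) == 150
        assert sim.truth.sum() == 100
        for ev, is_true in zip(sim.events, sim.truth):
            if is_true:
                expected = ("A", "G") if ev.gene_strand == "+" else ("T", "C")
                assert (ev.ref_base, ev.alt_base) == expected
                assert (ev.chrom, ev.pos) not in sim.snp_positions

    def test_zero_true_edits_filter_retains_nothing(self, clustered_genome):
        genes, plant, cfg = clustered_genome
        ctx = simulate_context(genes, plant.status, cfg.cluster_regions, seed=4)
        sim = simulate_editing(genes, ctx.repeats, EditSimConfig(n_true_edits=0, n_snps=30, seed=1))
        assert filter_edit_events(sim.events, sim.snp_positions) == []

    def test_determinism(self, clustered_genome):
        genes, plant, cfg = clustered_genome
        ctx = simulate_context(genes, plant.status, cfg.cluster_regions, seed=4)
        cfg_e = EditSimConfig(n_true_edits=40, n_snps=20, seed=9)
        s1 = simulate_editing(genes, ctx.repeats, cfg_e)
        s2 = simulate_editing(genes, ctx.repeats, cfg_e)
        assert s1.events == s2.events
        assert s1.snp_positions == s2.snp_positions
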
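"""Synthetic-data generator: determinism, construction properties, recovery."""

import numpy as np
import pandas as pd
import pytest

import ryescan.simulate as sim
import ryescan.window_stats as ws
from ryescan.recombination import classify_windows
from ryescan.simulate import SimulationConfig
from ryescan.variant_io import MISSING


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(base_fst=0.5, linked_selection_multiplier=3.0)
        with pytest.raises(ValueError):
            SimulationConfig(diversity_scaling_low_rho=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(migration_1to2=1.0)

    def test_chromosome_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            SimulationConfig(chromosome_length=5_000_000)


class TestRecombinationTrack:
    def test_central_block_has_lowest_rho(self, small_config):
        cfg = SimulationConfig(n_chromosomes=1, chromosome_length=100_000_000, seed=3)
        track, windows = sim.generate_recombination_track(cfg)
        assert len(windows) == 10
        rho = track["rho"].to_numpy()
        # the low block is contiguous, central, and strictly below all flanks
        low_mask = rho < 5.0
        idx = np.where(low_mask)[0]
        assert 2 <= len(idx) <= 5
        assert np.all(np.diff(idx) == 1)
        assert rho[low_mask].max() < rho[~low_mask].min()

    def test_deterministic_given_seed(self, small_config):
        t1, _ = sim.generate_recombination_track(small_config)
        t2, _ = sim.generate_recombination_track(small_config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_lowest_quartile_fraction_over_60_windows(self, small_config):
        track, windows = sim.generate_recombination_track(small_config)
        assert len(windows) == 60
        classes = classify_windows(track["rho"].to_numpy()).classes
        assert (classes == "low").sum() == 15


class TestSimulateVariants:
    def test_determinism_bit_identical(self, small_config):
        track, _ = sim.generate_recombination_track(small_config)
        m1, _, t1 = sim.simulate_variants(small_config, track)
        m2, _, t2 = sim.simulate_variants(small_config, track)
        np.testing.assert_array_equal(m1.genotypes, m2.genotypes)
        np.testing.assert_array_equal(m1.pos, m2.pos)
        pd.testing.assert_frame_equal(t1, t2)

    def test_dosage_domain_and_truth_record(self, small_config):
        track, _ = sim.generate_recombination_track(small_config)
        m, pops, truth = sim.simulate_variants(small_config, track)
        assert set(np.unique(m.genotypes)) <= {0, 1, 2}
        assert len(truth) == 60
        assert ((truth["f_w"] > 0) & (truth["f_w"] < 1)).all()
        assert truth.loc[truth.rec_class == "low", "f_w"].unique().tolist() == [
            pytest.approx(small_config.base_fst * small_config.linked_selection_multiplier)
        ]
        assert len(pops.pop1) == 50 and len(pops.pop2) == 50

    def test_near_zero_differentiation_centres_on_zero(self):
        cfg = SimulationConfig(
            n_chromosomes=6, chromosome_length=400_000_000,
            n_samples_pop1=40, n_samples_pop2=40,
            base_fst=1e-4, linked_selection_multiplier=1.0,
            diversity_scaling_low_rho=1.0, migration_1to2=0.0, migration_2to1=0.0,
            missing_rate=0.0, seed=5,
        )
        track, windows = sim.generate_recombination_track(cfg)
        assert len(windows) >= 200
        m, pops, _ = sim.simulate_variants(cfg, track)
        df = ws.compute_window_stats(m, pops.pop1, pops.pop2, windows)
        assert abs(np.nanmean(df["fst"])) < 0.02

    def test_pooled_fst_recovers_base(self, small_config):
        cfg = SimulationConfig(
            n_chromosomes=6, chromosome_length=100_000_000,
            n_samples_pop1=50, n_samples_pop2=50,
            snvs_per_window_mean=100.0, base_fst=0.2,
            linked_selection_multiplier=1.0, diversity_scaling_low_rho=1.0,
            migration_1to2=0.0, migration_2to1=0.0, missing_rate=0.0, seed=6,
        )
        track, _ = sim.generate_recombination_track(cfg)
        m, pops, _ = sim.simulate_variants(cfg, track)
        assert m.n_sites >= 5000
        whole = ws.GenomicWindow("all", 0, m.n_sites + 1)
        # pool every site into one ratio-of-sums estimate
        fst = ws.hudson_fst(
            ws.VariantMatrix(
                chrom=np.full(m.n_sites, "all", dtype=object),
                pos=np.arange(1, m.n_sites + 1),
                ref=m.ref, alt=m.alt, genotypes=m.genotypes, depth=m.depth,
                samples=m.samples,
            ),
            pops.pop1, pops.pop2, whole,
        )
        assert fst == pytest.approx(0.2, abs=0.02)

    def test_diversity_scaling_reduces_dxy_in_low_windows(self, small_config):
        cfg = SimulationConfig(
            n_chromosomes=6, chromosome_length=100_000_000,
            n_samples_pop1=50, n_samples_pop2=50,
            diversity_scaling_low_rho=0.3, migration_1to2=0.0, migration_2to1=0.0,
            missing_rate=0.0, seed=7,
        )
        track, windows = sim.generate_recombination_track(cfg)
        m, pops, truth = sim.simulate_variants(cfg, track)
        df = ws.compute_window_stats(m, pops.pop1, pops.pop2, windows)
        low = truth["rec_class"].to_numpy() == "low"
        assert low.sum() >= 10 and (~low).sum() >= 40
        assert np.nanmean(df.loc[low, "dxy"]) < np.nanmean(df.loc[~low, "dxy"])

    def test_windowed_fst_regression_slope_near_one(self):
        cfg = SimulationConfig(
            n_chromosomes=6, chromosome_length=300_000_000,
            n_samples_pop1=60, n_samples_pop2=60,
            snvs_per_window_mean=40.0, base_fst=0.15,
            linked_selection_multiplier=3.0, diversity_scaling_low_rho=1.0,
            migration_1to2=0.0, migration_2to1=0.0, missing_rate=0.0, seed=8,
        )
        track, windows = sim.generate_recombination_track(cfg)
        m, pops, truth = sim.simulate_variants(cfg, track)
        df = ws.compute_window_stats(m, pops.pop1, pops.pop2, windows)
        use = (df["n_snvs"] >= 30) & df["fst"].notna()
        assert use.sum() >= 100
        slope = np.polyfit(truth.loc[use, "f_w"], df.loc[use, "fst"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_zero_samples_rejected(self, small_config):
        track, _ = sim.generate_recombination_track(small_config)
        cfg = SimulationConfig(
            n_chromosomes=6, chromosome_length=100_000_000, n_samples_pop2=0, seed=1
        )
        with pytest.raises(ValueError, match="population"):
            sim.simulate_variants(cfg, track)


class TestGbsNoise:
    def test_zero_missing_rate_is_identity(self, small_config):
        track, _ = sim.generate_recombination_track(small_config)
        m, _, _ = sim.simulate_variants(small_config, track)
        out = sim.apply_gbs_noise(m, small_config)  # missing_rate = 0
        np.testing.assert_array_equal(out.genotypes, m.genotypes)

    def test_missing_fraction_concentrates(self):
        cfg = SimulationConfig(
            n_chromosomes=1, chromosome_length=100_000_000,
            n_samples_pop1=50, n_samples_pop2=50,
            snvs_per_window_mean=15.0, missing_rate=0.3, seed=9,
        )
        track, _ = sim.generate_recombination_track(cfg)
        m, _, _ = sim.simulate_variants(cfg, track)
        out = sim.apply_gbs_noise(m, cfg)
        frac = (out.genotypes == MISSING).mean()
        assert out.genotypes.size >= 10_000
        assert 0.28 <= frac <= 0.32

    def test_depth_band_coverage(self):
        cfg = SimulationConfig(
            n_chromosomes=6, chromosome_length=100_000_000,
            depth_mean=50.0, depth_dispersion=20.0, seed=10,
        )
        track, _ = sim.generate_recombination_track(cfg)
        m, _, _ = sim.simulate_variants(cfg, track)
        out = sim.apply_gbs_noise(m, cfg)
        inside = np.mean((out.depth >= 10) & (out.depth <= 100))
        assert inside > 0.9

    def test_already_missing_rejected(self, small_config):
        track, _ = sim.generate_recombination_track(small_config)
        m, _, _ = sim.simulate_variants(small_config, track)
        m.genotypes[0, 0] = MISSING
        with pytest.raises(ValueError, match="missing"):
            sim.apply_gbs_noise(m, small_config)


class TestAnnotation:
    def test_mean_gene_density(self, small_config):
        track, windows = sim.generate_recombination_track(small_config)
        ann = sim.generate_annotation(small_config, track, n_genes=1000)
        counts = ws.gene_density(ann, windows)
        assert counts.sum() == 1000
        assert counts.mean() == pytest.approx(1000 / 60)

    def test_planted_term_positively_associated(self, small_config):
        track, _ = sim.generate_recombination_track(small_config)
        ann = sim.generate_annotation(
            small_config, track, planted_term="GO:7999999", planted_windows=[0, 1, 2],
            n_genes=1200, n_terms=30,
        )
        g2g = ann.gene2go
        carriers = set(g2g.loc[g2g.go_id == "GO:7999999", "gene_id"])
        in_planted = ann.genes["start"] < 30_000_000
        on_first_chrom = ann.genes["chrom"] == "chr1R"
        planted_genes = set(ann.genes.loc[in_planted & on_first_chrom, "gene_id"])
        a = len(planted_genes & carriers)
        b = len(planted_genes) - a
        c = len(carriers - planted_genes)
        d = len(ann.genes) - len(planted_genes) - c
        assert (a * d) > (b * c)  # odds ratio > 1 by construction

    def test_planted_without_windows_rejected(self, small_config):
        track, _ = sim.generate_recombination_track(small_config)
        with pytest.raises(ValueError, match="planted"):
            sim.generate_annotation(small_config, track, planted_term="GO:1", planted_windows=[])


class TestCorrelationStructure:
    def test_linked_selection_signs(self):
        """multiplier > 1 and scaling < 1 force r(FST,rho) < 0 < r(dxy,rho)."""
        cfg = SimulationConfig(
            n_chromosomes=6, chromosome_length=100_000_000,
            n_samples_pop1=50, n_samples_pop2=50,
            linked_selection_multiplier=2.0, diversity_scaling_low_rho=0.5,
            missing_rate=0.0, migration_1to2=0.0, migration_2to1=0.0, seed=12,
        )
        track, windows = sim.generate_recombination_track(cfg)
        m, pops, _ = sim.simulate_variants(cfg, track)
        df = ws.compute_window_stats(m, pops.pop1, pops.pop2, windows)
        df["rho"] = track["rho"].to_numpy()
        sub = df.dropna(subset=["fst", "dxy"])
        assert len(sub) >= 60
        assert np.corrcoef(sub["fst"], sub["rho"])[0, 1] < 0
        assert np.corrcoef(sub["dxy"], sub["rho"])[0, 1] > 0
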
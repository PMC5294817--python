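import numpy as np
import pandas as pd
import pytest

from cistrovar.intervals import merge_consensus, overlap_snps
from cistrovar.motif import default_dr3_model, scan
from cistrovar.simulate import (
    SimConfig,
    sim_catalog_and_peaks,
    sim_genotype_binding,
    sim_panel,
    sim_regdb,
    sim_sequences_with_motifs,
    write_fixtures,
)


class TestDeterminism:
    def test_same_seed_bitwise_identical_panel(self):
        a, b = sim_panel(SimConfig(seed=5)), sim_panel(SimConfig(seed=5))
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.sites == b.sites

    def test_different_seeds_differ(self):
        a, b = sim_panel(SimConfig(seed=5)), sim_panel(SimConfig(seed=6))
        assert not np.array_equal(a.haplotypes, b.haplotypes)

    def test_generators_use_independent_substreams(self):
        cfg = SimConfig(seed=5)
        panel = sim_panel(cfg)
        g1, _ = sim_genotype_binding(cfg)
        # drawing the panel again does not shift the genotype stream
        sim_panel(cfg)
        g2, _ = sim_genotype_binding(cfg)
        assert g1.equals(g2)


class TestPanelLdStructure:
    def test_within_block_r2_high_across_seeds(self):
        vals = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_blocks=8, founder_freq_range=(0.2, 0.5))
            panel = sim_panel(cfg)
            for b in range(cfg.n_blocks):
                base = b * cfg.sites_per_block
                for j in range(1, cfg.sites_per_block):
                    vals.append(panel.r2(base, base + j))
        assert np.median(vals) > 0.8

    def test_cross_block_r2_near_zero(self):
        cfg = SimConfig(seed=3, n_blocks=10, founder_freq_range=(0.2, 0.5))
        panel = sim_panel(cfg)
        vals = []
        rng = np.random.default_rng(0)
        for _ in range(200):
            b1, b2 = rng.choice(cfg.n_blocks, size=2, replace=False)
            i = b1 * cfg.sites_per_block + rng.integers(cfg.sites_per_block)
            j = b2 * cfg.sites_per_block + rng.integers(cfg.sites_per_block)
            vals.append(panel.r2(int(i), int(j)))
        assert np.mean(vals) < 0.05

    def test_mafs_straddle_the_filter(self):
        panel = sim_panel(SimConfig(seed=1))
        mafs = panel.mafs()
        assert (mafs < 0.05).any() and (mafs >= 0.05).any()


class TestCatalogAndPeaks:
    def test_planted_trait_size_and_partition(self):
        cfg = SimConfig(seed=2)
        panel = sim_panel(cfg)
        assocs, peak_sets, truth = sim_catalog_and_peaks(cfg, panel)
        assert len(assocs) == panel.n_sites  # every site on exactly one trait
        planted = truth[truth.trait == cfg.planted_trait]
        assert len(planted) == cfg.planted_trait_snp_count
        assert len(peak_sets) >= 2

    def test_truth_coverage_matches_overlap_stage(self):
        cfg = SimConfig(seed=4)
        panel = sim_panel(cfg)
        assocs, peak_sets, truth = sim_catalog_and_peaks(cfg, panel)
        loci = merge_consensus(peak_sets)
        assign, n = overlap_snps(
            [(s.snp_id, s.chrom, s.pos) for s in panel.sites], loci
        )
        assert set(assign.snp_id) == set(truth[truth.covered].snp_id)
        assert n == int(truth.covered.sum())

    def test_null_factor_matches_background_rate(self):
        # enrichment_factor 1: planted coverage within binomial noise of background
        diffs = []
        for seed in range(30):
            cfg = SimConfig(seed=seed, enrichment_factor=1.0)
            panel = sim_panel(cfg)
            _, _, truth = sim_catalog_and_peaks(cfg, panel)
            planted = truth[truth.trait == cfg.planted_trait]
            bg = truth[truth.trait != cfg.planted_trait]
            diffs.append(planted.covered.mean() - bg.covered.mean())
        # mean difference across seeds ~ 0 (3 SE bound with n=30 seeds)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-9

    def test_excessive_factor_rejected(self):
        cfg = SimConfig(seed=0, n_peaks=3000, enrichment_factor=50.0)
        panel = sim_panel(cfg)
        with pytest.raises(ValueError):
            sim_catalog_and_peaks(cfg, panel)


class TestSequencesWithMotifs:
    def test_plants_recorded_and_scannable(self):
        cfg = SimConfig(seed=6)
        panel = sim_panel(cfg)
        _, peak_sets, _ = sim_catalog_and_peaks(cfg, panel)
        loci = merge_consensus(peak_sets)
        model = default_dr3_model()
        seq, plants, overrides = sim_sequences_with_motifs(cfg, loci, model, panel)
        assert len(seq) == cfg.genome_length_bp
        assert len(plants) == cfg.motif_plant_count
        for _, row in plants.iterrows():
            hits = scan(seq[row.start : row.end], model, origin=row.start)
            assert any(
                h.start == row.start and h.strand == row.strand for h in hits
            ), row
        # overridden alleles match the planted genome
        for snp_id, (ref, alt) in overrides.items():
            site = next(s for s in panel.sites if s.snp_id == snp_id)
            assert seq[site.pos] == ref and alt != ref

    def test_minus_strand_plant_scores_like_plus(self):
        cfg = SimConfig(seed=6)
        panel = sim_panel(cfg)
        _, peak_sets, _ = sim_catalog_and_peaks(cfg, panel)
        loci = merge_consensus(peak_sets)
        model = default_dr3_model()
        seq, plants, _ = sim_sequences_with_motifs(cfg, loci, model, panel)
        assert {"+", "-"} <= set(plants.strand) or len(plants) < 4
        for _, row in plants.iterrows():
            hits = scan(seq[row.start : row.end], model, origin=row.start)
            best = max(h.score for h in hits)
            assert best == pytest.approx(model.max_score())


class TestGenotypeBinding:
    def test_zero_noise_alt_hom_signal_exactly_zero(self):
        g, s = sim_genotype_binding(
            SimConfig(seed=8), allele_freq=0.6, n_samples=40, noise_sd=0.0
        )
        merged = g.merge(s, on="sample")
        alt_hom = merged[merged.genotype == 2]
        assert not alt_hom.empty and (alt_hom.signal == 0).all()

    def test_allele_freq_zero_all_ref_hom(self):
        g, _ = sim_genotype_binding(SimConfig(seed=8), allele_freq=0.0)
        assert (g.genotype == 0).all()

    def test_class_means_ordered_with_dosage(self):
        ok = total = 0
        for seed in range(200):
            g, s = sim_genotype_binding(
                SimConfig(seed=seed), allele_freq=0.5, n_samples=30,
                base_signal=10.0, noise_sd=1.0,
            )
            merged = g.merge(s, on="sample")
            means = merged.groupby("genotype").signal.mean()
            if len(means) == 3:
                total += 1
                if means[0] > means[1] > means[2]:
                    ok += 1
        assert total > 150 and ok / total >= 0.99


class TestRegdbAndFixtures:
    def test_regdb_vocabulary_and_structure(self):
        cfg = SimConfig(seed=1)
        df = sim_regdb(cfg, [f"rs{i}" for i in range(500)])
        from cistrovar.annotation import ALL_CATEGORIES

        assert set(df.category) <= set(ALL_CATEGORIES)
        # eQTL genes only on category-1 records
        has_genes = df[df.eqtl_genes != ""]
        assert (has_genes.category.str.startswith("1")).all()

    def test_write_fixtures_roundtrips_through_readers(self, tmp_path):
        from cistrovar import io as cio

        cfg = SimConfig(seed=9, n_blocks=10, n_peaks=60, motif_plant_count=5)
        paths = write_fixtures(cfg, tmp_path)
        panel, stats = cio.read_panel_vcf(paths["panel_vcf"])
        assert panel.n_haplotypes == cfg.n_haplotypes
        assert panel.n_sites == cfg.n_blocks * cfg.sites_per_block
        assocs, leads, dropped = cio.read_gwas_catalog(paths["gwas_catalog"])
        assert dropped == 0 and len(assocs) == panel.n_sites
        for p in paths["peak_beds"]:
            assert len(cio.read_bed(p)) > 0
        genome = cio.read_fasta(paths["genome_fasta"])
        assert len(genome[cfg.chrom]) == cfg.genome_length_bp
        # planted alleles in the VCF agree with the genome sequence
        truth = pd.read_csv(tmp_path / "truth" / "allele_overrides.tsv", sep="\t")
        for _, row in truth.iterrows():
            site = panel.sites[panel.find(row.snp_id)]
            assert str(genome[cfg.chrom][site.pos]) == site.ref == row.ref
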
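from dataclasses import replace

import numpy as np
import pytest

import regulomap as rm
from regulomap import io as rio


class TestGenerateGenome:
    def test_degenerate_zero_genes(self):
        cfg = rm.SimulationConfig(length=100_000, n_genes=0, seed=1)
        genome, genes = rm.generate_genome(cfg)
        assert genome.length == 100_000
        assert len(genes) == 0

    def test_gc_content_and_nonoverlap(self):
        cfg = rm.SimulationConfig(length=200_000, gc_fraction=0.72, n_genes=100, seed=7)
        genome, genes = rm.generate_genome(cfg)
        gc = (genome.sequence.count("G") + genome.sequence.count("C")) / genome.length
        assert 0.70 <= gc <= 0.74
        assert len(genes) == 100
        assert (genes["end"] >= genes["start"]).all()
        assert (genes["start"].to_numpy()[1:] > genes["end"].to_numpy()[:-1]).all()
        assert set(genes["strand"]) == {"+", "-"}

    def test_infeasible_packing_rejected(self):
        cfg = rm.SimulationConfig(length=20_000, n_genes=100, seed=1)
        with pytest.raises(ValueError, match="pack"):
            rm.generate_genome(cfg)

    def test_byte_identical_fasta_and_gff_for_same_seed(self, tmp_path):
        cfg = rm.SimulationConfig(length=50_000, n_genes=20, n_sites=5, seed=11)
        outputs = []
        for run in ("a", "b"):
            genome0, genes = rm.generate_genome(cfg)
            sites, genome = rm.plant_sites(genome0, genes, cfg)
            fa, gff = tmp_path / f"{run}.fasta", tmp_path / f"{run}.gff3"
            rio.write_fasta(genome.sequence, fa)
            rio.write_gff3(genes, gff)
            outputs.append((fa.read_bytes(), gff.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_gff_roundtrip(self, tmp_path):
        cfg = rm.SimulationConfig(length=50_000, n_genes=20, seed=3)
        _, genes = rm.generate_genome(cfg)
        path = tmp_path / "genes.gff3"
        rio.write_gff3(genes, path)
        back = rio.read_gff3(path)
        assert back["gene_id"].tolist() == genes["gene_id"].tolist()
        assert back["start"].tolist() == genes["start"].tolist()
        assert back["strand"].tolist() == genes["strand"].tolist()


class TestPlantSites:
    def test_zero_sites_empty_truth(self):
        cfg = rm.SimulationConfig(
            length=50_000, n_genes=20, n_sites=0, n_artifact_sites=0, seed=1
        )
        genome, genes = rm.generate_genome(cfg)
        sites, _ = rm.plant_sites(genome, genes, cfg)
        assert sites == []

    def test_sites_target_distinct_genes_with_motif(self):
        cfg = rm.SimulationConfig(length=200_000, n_genes=100, n_sites=50, seed=3)
        genome0, genes = rm.generate_genome(cfg)
        sites, genome = rm.plant_sites(genome0, genes, cfg)
        true = [s for s in sites if not s.artifact]
        assert len(true) == 50
        assert len({s.target_gene for s in true}) == 50
        for s in true:
            window = genome.sequence[s.pos - 11 : s.pos + 10]
            assert rm.count_motif(window, "GACAC") >= 1

    def test_sites_upstream_within_300_of_start_codon(self):
        cfg = rm.SimulationConfig(length=200_000, n_genes=100, n_sites=50, seed=3)
        genome0, genes = rm.generate_genome(cfg)
        sites, _ = rm.plant_sites(genome0, genes, cfg)
        by_id = genes.set_index("gene_id")
        for s in sites:
            if s.artifact:
                continue
            row = by_id.loc[s.target_gene]
            start_codon = row["start"] if row["strand"] == "+" else row["end"]
            assert 0 < abs(start_codon - s.pos) <= 300
            # upstream in the gene's own orientation
            if row["strand"] == "+":
                assert s.pos < row["start"]
            else:
                assert s.pos > row["end"]

    def test_artifact_flags_and_modes(self):
        cfg = rm.SimulationConfig(
            length=200_000, n_genes=100, n_sites=50, n_artifact_sites=5, seed=9
        )
        genome0, genes = rm.generate_genome(cfg)
        sites, _ = rm.plant_sites(genome0, genes, cfg)
        artifacts = [s for s in sites if s.artifact]
        true = [s for s in sites if not s.artifact]
        assert len(artifacts) == 5
        modes = [s.mode for s in true]
        assert modes.count("activated") == 25
        assert modes.count("repressed") == 25
        lo, hi = cfg.enrichment_range
        assert all(lo <= s.enrichment <= hi for s in sites)


class TestGenotype:
    @pytest.mark.parametrize(
        "genotype,allowed",
        [
            (rm.WILD_TYPE, True),
            (rm.DELTA_WHIA, False),
            (rm.DELTA_WHIB, False),
            (rm.FOUR_CS, False),
        ],
    )
    def test_occupancy_requires_both_factors_and_cluster(self, genotype, allowed):
        assert genotype.occupancy_allowed is allowed


class TestSimulateCoverage:
    def test_zero_depth_gives_zero_track(self):
        cfg = rm.SimulationConfig(length=20_000, n_genes=0, mean_depth=0.0, seed=1)
        t = rm.simulate_coverage(20_000, [], rm.WILD_TYPE, "IP", cfg)
        assert np.all(t.counts == 0)

    def test_nonbinding_genotype_expectation_equals_baseline(self):
        cfg = rm.SimulationConfig(length=50_000, n_genes=20, n_sites=5, seed=4)
        genome0, genes = rm.generate_genome(cfg)
        sites, genome = rm.plant_sites(genome0, genes, cfg)
        for gt in (rm.DELTA_WHIA, rm.DELTA_WHIB, rm.FOUR_CS):
            e_ip = rm.expected_coverage(genome, sites, gt, "IP", cfg)
            e_in = rm.expected_coverage(genome, sites, gt, "input", cfg)
            true_sites = [s for s in sites if not s.artifact]
            # away from artifacts, IP and input expectations are identical
            mask = np.ones_like(e_ip, dtype=bool)
            centers = (
                np.arange(e_ip.size) * cfg.bin_size
                + 1
                + np.minimum((np.arange(e_ip.size) + 1) * cfg.bin_size, 50_000)
            ) // 2
            for s in sites:
                if s.artifact:
                    mask &= np.abs(centers - s.pos) > cfg.fragment_sd
            np.testing.assert_allclose(e_ip[mask], e_in[mask])
            for s in true_sites:
                b = np.argmin(np.abs(centers - s.pos))
                assert e_ip[b] == pytest.approx(e_in[b])

    def test_artifact_sites_enrich_all_ip_roles_and_genotypes(self):
        cfg = rm.SimulationConfig(
            length=50_000, n_genes=10, n_sites=0, n_artifact_sites=2, seed=6
        )
        genome0, genes = rm.generate_genome(cfg)
        sites, genome = rm.plant_sites(genome0, genes, cfg)
        art = sites[0]
        b = (art.pos - 1) // cfg.bin_size
        for gt in (rm.WILD_TYPE, rm.DELTA_WHIB):
            for role in ("IP", "control_IP"):
                e = rm.expected_coverage(genome, sites, gt, role, cfg)
                e_in = rm.expected_coverage(genome, sites, gt, "input", cfg)
                assert e[b] > 2 * e_in[b]

    def test_site_center_mean_count_matches_poisson_model(self):
        """Monte-Carlo mean at the site's center bin across replicate seeds."""
        totals = []
        for seed in range(500):
            cfg = rm.SimulationConfig(
                length=30_000,
                n_genes=10,
                n_sites=1,
                n_artifact_sites=0,
                mean_depth=30.0,
                enrichment_range=(10.0, 10.0),
                seed=10_000 + seed,
            )
            genome0, genes = rm.generate_genome(cfg)
            sites, genome = rm.plant_sites(genome0, genes, cfg)
            site = sites[0]
            track = rm.simulate_coverage(genome, sites, rm.WILD_TYPE, "IP", cfg)
            b = int(np.argmin(np.abs(track.bin_centers - site.pos)))
            totals.append(track.counts[b])
        assert 270 <= np.mean(totals) <= 330

    def test_matched_ip_input_share_shear_field(self):
        cfg = rm.SimulationConfig(
            length=1_000_000, n_genes=0, n_sites=0, n_artifact_sites=0,
            mean_depth=100.0, shear_bias_scale=0.5, seed=21,
        )
        ip = rm.simulate_coverage(1_000_000, [], rm.WILD_TYPE, "IP", cfg)
        inp = rm.simulate_coverage(1_000_000, [], rm.WILD_TYPE, "input", cfg)
        r = np.corrcoef(ip.counts, inp.counts)[0, 1]
        assert r > 0.9

    def test_deterministic_for_fixed_seed(self):
        cfg = rm.SimulationConfig(length=50_000, n_genes=20, n_sites=5, seed=8)
        genome0, genes = rm.generate_genome(cfg)
        sites, genome = rm.plant_sites(genome0, genes, cfg)
        a = rm.simulate_coverage(genome, sites, rm.WILD_TYPE, "IP", cfg)
        b = rm.simulate_coverage(genome, sites, rm.WILD_TYPE, "IP", cfg)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = rm.simulate_coverage(genome, sites, rm.WILD_TYPE, "IP", cfg, replicate=1)
        assert not np.array_equal(a.counts, c.counts)


class TestSimulateExpression:
    def test_noise_free_effect_is_exact(self, study_conditions):
        cfg = replace(study_conditions, noise_sd=0.0)
        genome0, genes = rm.generate_genome(cfg)
        sites, _ = rm.plant_sites(genome0, genes, cfg)
        wt = rm.simulate_expression(genes, sites, rm.WILD_TYPE, cfg, "WT")
        mut = rm.simulate_expression(genes, sites, rm.DELTA_WHIB, cfg, "dB")
        act = next(s for s in sites if s.mode == "activated")
        diff = mut.data.loc[act.target_gene, 18.0] - wt.data.loc[act.target_gene, 18.0]
        assert diff == pytest.approx(-cfg.effect_log2)

    def test_most_targets_exceed_twofold_at_18h(self):
        cfg = rm.SimulationConfig(
            length=500_000, n_genes=200, n_sites=50, effect_log2=2.0,
            noise_sd=0.3, seed=11,
        )
        genome0, genes = rm.generate_genome(cfg)
        sites, _ = rm.plant_sites(genome0, genes, cfg)
        wt = rm.simulate_expression(genes, sites, rm.WILD_TYPE, cfg, "WT")
        mut = rm.simulate_expression(genes, sites, rm.DELTA_WHIB, cfg, "dB")
        lf = rm.logfc_profile(mut, wt)
        targets = [s.target_gene for s in sites if not s.artifact]
        frac = (lf.loc[targets, 18.0].abs() >= 1.0).mean()
        assert frac >= 0.9
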
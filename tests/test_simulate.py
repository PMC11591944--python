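"""Generator contracts: HWE structure, planted truth, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from snp2tf.epistasis import mi_mixed
from snp2tf.io import read_transfac, write_transfac
from snp2tf.motifs import consensus_to_pwm, extract_promoters, reverse_complement
from snp2tf.simulate import (
    ConfigError,
    MotifPlantConfig,
    SimConfig,
    plant_promoters,
    simulate_annotation,
    simulate_genotypes,
    simulate_phenotype,
)


class TestSimulateGenotypes:
    def test_hwe_proportions_at_half(self):
        cfg = SimConfig(n_animals=100_000, n_snps=1, maf_range=(0.5, 0.5),
                        missing_rate=0.0, n_additive=0, n_epistatic_pairs=0, seed=1)
        G = simulate_genotypes(cfg)
        counts = np.bincount(G.codes[:, 0], minlength=3)
        for observed, expected_p in zip(counts, (0.25, 0.5, 0.25)):
            sd = np.sqrt(cfg.n_animals * expected_p * (1 - expected_p))
            assert abs(observed - cfg.n_animals * expected_p) < 3 * sd

    def test_no_missing_when_rate_zero(self):
        cfg = SimConfig(n_animals=200, n_snps=50, missing_rate=0.0,
                        n_additive=0, n_epistatic_pairs=0, seed=2)
        assert (simulate_genotypes(cfg).codes >= 0).all()

    def test_seed_determinism(self):
        cfg = SimConfig(n_animals=100, n_snps=40, seed=3,
                        n_additive=2, n_epistatic_pairs=1)
        G1, G2 = simulate_genotypes(cfg), simulate_genotypes(cfg)
        assert np.array_equal(G1.codes, G2.codes)
        pd.testing.assert_frame_equal(G1.snps, G2.snps)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"maf_range": (0.001, 0.5)}, "maf_range"),
            ({"n_snps": 5, "n_additive": 4, "n_epistatic_pairs": 1}, "n_additive"),
            ({"heritability": 1.5}, "heritability"),
            ({"epistasis_model": "and"}, "epistasis_model"),
            ({"missing_rate": 1.0}, "missing_rate"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            simulate_genotypes(SimConfig(**kwargs))

    def test_hwe_filter_recovery(self):
        """Simulated SNPs nearly always pass the exact HWE filter at n=500."""
        from snp2tf.qc import snp_stats

        cfg = SimConfig(n_animals=500, n_snps=300, maf_range=(0.05, 0.5),
                        missing_rate=0.01, n_additive=0, n_epistatic_pairs=0, seed=4)
        stats = snp_stats(simulate_genotypes(cfg))
        assert (stats["hwe_p"] > 1e-6).mean() >= 0.99


class TestSimulatePhenotype:
    def test_null_heritability_independent(self):
        cfg = SimConfig(n_animals=2000, n_snps=20, missing_rate=0.0,
                        n_additive=3, n_epistatic_pairs=0, heritability=0.0, seed=5)
        G = simulate_genotypes(cfg)
        y, truth = simulate_phenotype(G, cfg)
        j = list(G.snps["snp_id"]).index(truth["additive_snps"][0])
        assert abs(mi_mixed(G.codes[:, j], y.to_numpy(), seed=0)) < 0.02

    def test_full_heritability_is_linear(self):
        cfg = SimConfig(n_animals=300, n_snps=20, missing_rate=0.0,
                        n_additive=4, n_epistatic_pairs=0, heritability=1.0, seed=6)
        G = simulate_genotypes(cfg)
        y, truth = simulate_phenotype(G, cfg)
        cols = [list(G.snps["snp_id"]).index(s) for s in truth["additive_snps"]]
        X = np.column_stack([G.codes[:, cols].astype(float), np.ones(G.n_animals)])
        resid = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[1]
        assert float(resid[0]) < 1e-18

    def test_xor_pair_hides_marginal_signal(self):
        """At MAF 0.5 the xor construction leaves ~zero per-SNP correlation
        while the pair's 9-cell genotype means differ (enumeration of the
        balanced-indicator xor: cells with exactly one heterozygote sit at
        +e, all others at -e)."""
        cfg = SimConfig(n_animals=20_000, n_snps=4, maf_range=(0.5, 0.5),
                        missing_rate=0.0, n_additive=0, n_epistatic_pairs=1,
                        epistasis_model="xor", heritability=1.0, seed=7)
        G = simulate_genotypes(cfg)
        y, truth = simulate_phenotype(G, cfg)
        ids = list(G.snps["snp_id"])
        ja, jb = (ids.index(s) for s in truth["epistatic_pairs"][0])
        ga, gb = G.codes[:, ja].astype(float), G.codes[:, jb].astype(float)
        yv = y.to_numpy()
        for g in (ga, gb):
            r = np.corrcoef(g, yv)[0, 1]
            assert r**2 < 1e-3
        cell_means = {
            (a, b): yv[(ga == a) & (gb == b)].mean()
            for a in range(3) for b in range(3)
        }
        # exactly-one-het cells high, all others low
        high = [cell_means[c] for c in [(1, 0), (1, 2), (0, 1), (2, 1)]]
        low = [cell_means[c] for c in [(0, 0), (0, 2), (2, 0), (2, 2), (1, 1)]]
        assert min(high) > max(low) + 1.0


class TestAnnotation:
    def test_single_gene_small_chromosome(self):
        genes, genome = simulate_annotation(1, [10_000], seed=1)
        assert len(genes) == 1
        assert len(genome["1"]) == 10_000

    def test_promoter_round_trip_length(self):
        genes, genome = simulate_annotation(5, [40_000], seed=2)
        proms = extract_promoters(genes, genome)
        assert len(proms) == 5
        assert (proms["sequence"].str.len() == 600).all()
        assert not proms["truncated"].any()

    def test_minus_strand_is_reverse_complement(self):
        genes, genome = simulate_annotation(8, [60_000], seed=3)
        minus = genes[genes["strand"] == "-"]
        if minus.empty:  # strand draw is random; seed 3 places both strands
            pytest.skip("no minus-strand gene drawn")
        proms = extract_promoters(genes, genome).set_index("gene_id")
        for rec in minus.itertuples(index=False):
            contig = genome[rec.chrom]
            window = contig[rec.end - 100 : rec.end + 500]
            assert proms.loc[rec.gene_id, "sequence"] == reverse_complement(window).upper()

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_annotation(10, [5_000], seed=4)


class TestPlantPromoters:
    def test_plant_everywhere_fixed_spacer(self):
        cfg = MotifPlantConfig(n_promoters=30, motif_pairs=[("TATAAT", "GGGCGG")],
                               spacer_range=(5, 5), plant_fraction=1.0, seed=1)
        seqs, truth = plant_promoters(cfg)
        assert set(truth["chrom"]) == set(seqs)
        for prom, grp in truth.groupby("chrom"):
            grp = grp.sort_values("start")
            assert len(grp) == 2
            gap = grp["start"].iloc[1] - grp["end"].iloc[0]
            assert gap == 5
            for rec in grp.itertuples(index=False):
                planted = seqs[prom][rec.start : rec.end]
                expected = rec.name if rec.strand == "+" else reverse_complement(rec.name)
                assert planted == expected

    def test_plant_fraction_zero_empty_truth(self):
        cfg = MotifPlantConfig(n_promoters=10, plant_fraction=0.0, seed=2)
        _, truth = plant_promoters(cfg)
        assert truth.empty

    def test_spacer_uniform_over_window(self):
        cfg = MotifPlantConfig(n_promoters=10_000, plant_fraction=1.0,
                               spacer_range=(5, 20), seed=3)
        _, truth = plant_promoters(cfg)
        spacers = truth.drop_duplicates(["chrom", "pair"])["spacer"]
        counts = spacers.value_counts().reindex(range(5, 21), fill_value=0)
        assert chisquare(counts).pvalue > 1e-3

    def test_motif_longer_than_promoter_raises(self):
        with pytest.raises(ConfigError, match="promoter_length"):
            MotifPlantConfig(promoter_length=20,
                             motif_pairs=[("A" * 15, "C" * 15)]).validate()


class TestConsensusPWM:
    def test_zero_pseudocount_identity(self):
        pwm = consensus_to_pwm("ACGT", pseudocount=0.0)
        assert np.allclose(pwm.frequencies(), np.eye(4))

    def test_columns_sum_to_one(self):
        pwm = consensus_to_pwm("TTGACA", pseudocount=0.3)
        assert np.allclose(pwm.frequencies().sum(axis=1), 1.0, atol=1e-12)

    def test_transfac_round_trip(self, tmp_path):
        pwms = [consensus_to_pwm("TATAAT", 0.25, matrix_id="M1", tf_name="TATA"),
                consensus_to_pwm("GGGCGG", 0.0, matrix_id="M2", tf_name="SP1")]
        path = tmp_path / "lib.transfac"
        write_transfac(pwms, path)
        back = read_transfac(path)
        assert [p.matrix_id for p in back] == ["M1", "M2"]
        for a, b in zip(pwms, back):
            assert np.allclose(a.counts, b.counts, atol=1e-4)
            assert a.tf_name == b.tf_name
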
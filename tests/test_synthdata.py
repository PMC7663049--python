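import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omnileaf import quantgen
from omnileaf.synthdata import (
    ExprConfig,
    SimConfig,
    read_vcf,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
    write_bundle,
)


def hudson_fst(d1, d2):
    """Mean Hudson F_ST estimator over SNPs for two population samples."""

    p1 = d1.mean(axis=0) / 2
    p2 = d2.mean(axis=0) / 2
    n1, n2 = 2 * d1.shape[0], 2 * d2.shape[0]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(np.sum(num[ok]) / np.sum(den[ok]))


class TestConfig:
    def test_fst_out_of_range(self):
        with pytest.raises(ValueError, match="fst"):
            SimConfig(fst=1.0)

    def test_negative_variance(self):
        with pytest.raises(ValueError, match="negative variance"):
            SimConfig(variance_components={"t": {"V_geno": -1.0}})

    def test_rg_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimConfig(
                variance_components={
                    "a": {"V_geno": 1.0}, "b": {"V_geno": 1.0}
                },
                rG_matrix=np.array([[1.0, 0.5], [0.2, 1.0]]),
            )
        with pytest.raises(ValueError, match="unit diagonal"):
            SimConfig(
                variance_components={
                    "a": {"V_geno": 1.0}, "b": {"V_geno": 1.0}
                },
                rG_matrix=np.array([[2.0, 0.0], [0.0, 2.0]]),
            )


class TestSimulateGenotypes:
    def test_empty_snp_set(self):
        geno = simulate_genotypes(SimConfig(n_snp=0, n_geno=10, n_gene=5))
        assert geno.dosages.shape == (10, 0)
        assert len(geno.snps) == 0

    def test_dosages_in_range(self):
        geno = simulate_genotypes(SimConfig(n_snp=100, n_geno=30, n_gene=10))
        assert set(np.unique(geno.dosages)) <= {0, 1, 2}

    def test_fst_zero_homogeneous(self):
        cfg = SimConfig(n_geno=500, n_snp=300, n_gene=20, n_pop=2, fst=0.0,
                        seed=1)
        geno = simulate_genotypes(cfg)
        pops = geno.populations.to_numpy()
        d1 = geno.dosages[pops == "pop1"].astype(float)
        d2 = geno.dosages[pops == "pop2"].astype(float)
        n_sig = 0
        for j in range(cfg.n_snp):
            table = np.array(
                [
                    [d1[:, j].sum(), 2 * d1.shape[0] - d1[:, j].sum()],
                    [d2[:, j].sum(), 2 * d2.shape[0] - d2[:, j].sum()],
                ]
            )
            if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
                _, p, _, _ = stats.chi2_contingency(table)
                n_sig += p < 0.01
        assert n_sig <= 0.01 * cfg.n_snp + 2  # >=99% homogeneous

    def test_fst_ordering_hudson_oracle(self):
        ests = {}
        for fst in (0.01, 0.3):
            cfg = SimConfig(n_geno=200, n_snp=400, n_gene=20, n_pop=2,
                            fst=fst, seed=2)
            geno = simulate_genotypes(cfg)
            pops = geno.populations.to_numpy()
            ests[fst] = hudson_fst(
                geno.dosages[pops == "pop1"].astype(float),
                geno.dosages[pops == "pop2"].astype(float),
            )
        assert ests[0.3] > ests[0.01]
        assert abs(ests[0.3] - 0.3) < 0.1

    def test_snp_positions_within_genome(self):
        geno = simulate_genotypes(SimConfig(n_snp=200, n_geno=20, n_gene=30))
        for chrom, grp in geno.snps.groupby("chrom"):
            assert grp["pos"].between(1, geno.chrom_lengths[chrom]).all()
            assert grp["pos"].is_unique


class TestSimulatePhenotypes:
    def test_pure_noise_no_heritability(self):
        cfg = SimConfig(
            n_geno=100, n_snp=20, n_gene=10, n_rep=3, seed=3,
            variance_components={
                "t": {"V_pop": 0, "V_geno": 0, "V_gxe": 0, "V_plant": 0,
                      "V_res": 1.0}
            },
        )
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(cfg, geno)
        assert truth.true_h2["t"] == 0.0
        sub = pheno[(pheno.garden == cfg.gardens[0]) & (pheno.year == cfg.years[0])]
        h2, ci = quantgen.heritability(sub, "t")
        assert h2 < 0.1
        assert ci[0] <= 0.05

    def test_rg_one_identical_effects(self):
        cfg = SimConfig(
            n_geno=200, n_snp=20, n_gene=10, n_rep=3, seed=4,
            variance_components={
                "a": {"V_geno": 1.0, "V_res": 0.2},
                "b": {"V_geno": 1.0, "V_res": 0.2},
            },
            rG_matrix=np.array([[1.0, 1.0], [1.0, 1.0]]),
        )
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(cfg, geno)
        ga = pd.Series(truth.genotype_effects["a"])
        gb = pd.Series(truth.genotype_effects["b"])
        assert np.allclose(ga, gb, atol=1e-10)
        sub = pheno[(pheno.garden == cfg.gardens[0]) & (pheno.year == cfg.years[0])]
        gc = quantgen.genetic_correlation(sub, "a", "b")
        assert gc.rG > 0.9

    def test_h2_recovery(self):
        ests = []
        for seed in range(6):
            cfg = SimConfig(
                n_geno=200, n_snp=10, n_gene=5, n_rep=4,
                gardens=("g1",), years=(2008,), seed=100 + seed,
                block_effect_sd=0.0,
                variance_components={
                    "t": {"V_pop": 0, "V_geno": 0.7, "V_gxe": 0,
                          "V_plant": 0, "V_res": 0.3}
                },
            )
            geno = simulate_genotypes(cfg)
            pheno, truth = simulate_phenotypes(cfg, geno)
            assert truth.true_h2["t"] == pytest.approx(0.7)
            h2, _ = quantgen.heritability(pheno, "t")
            ests.append(h2)
        assert abs(np.mean(ests) - 0.7) < 0.05

    def test_realized_components_converge(self):
        cfg = SimConfig(
            n_geno=1000, n_snp=10, n_gene=5, n_rep=1, gardens=("g1",),
            years=(2008,), seed=5,
            variance_components={
                "t": {"V_pop": 0, "V_geno": 2.0, "V_gxe": 0, "V_plant": 0,
                      "V_res": 0.5}
            },
        )
        geno = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(cfg, geno)
        realized = np.var(list(truth.genotype_effects["t"].values()))
        assert abs(realized - 2.0) / 2.0 < 0.1

    def test_mismatched_trait_rg_errors(self):
        with pytest.raises(ValueError, match="shape"):
            SimConfig(
                variance_components={"a": {"V_geno": 1.0}},
                rG_matrix=np.eye(2),
            )


class TestSimulateExpression:
    def test_null_log2fc_no_excess_degs(self):
        from omnileaf import degx

        total_deg, total_possible = 0, 0
        for seed in range(5):
            cfg = SimConfig(
                n_geno=80, n_snp=10, n_gene=100, n_rep=2, seed=seed,
                expr=ExprConfig(n_modules=0, module_size=0, n_deg=20,
                                deg_log2fc=0.0),
            )
            geno, pheno, expr, truth = simulate_cohort(cfg)
            blups = pheno.groupby("genotype")[cfg.traits[0]].mean()
            groups = degx.select_extremes(
                blups, cfg.traits[0], sample_map=expr.sample_map
            )
            de = degx.nb_test(expr.counts, groups)
            total_deg += int(de["is_deg"].fillna(False).sum())
            total_possible += len(de)
        assert total_deg <= 0.05 * total_possible * 2

    def test_module_size_one_no_shared_modules(self):
        cfg = SimConfig(
            n_geno=30, n_snp=10, n_gene=50, seed=6,
            expr=ExprConfig(n_modules=5, module_size=1, n_deg=0),
        )
        geno, pheno, expr, truth = simulate_cohort(cfg)
        counts = pd.Series(truth.module_of).value_counts()
        assert (counts == 1).all()

    def test_deg_genes_respond_to_trait(self):
        from omnileaf import degx

        cfg = SimConfig(
            n_geno=100, n_snp=10, n_gene=100, seed=7,
            expr=ExprConfig(n_modules=0, module_size=0, n_deg=20,
                            deg_log2fc=2.0),
        )
        geno, pheno, expr, truth = simulate_cohort(cfg)
        blups = pheno.groupby("genotype")[cfg.traits[0]].mean()
        groups = degx.select_extremes(
            blups, cfg.traits[0], sample_map=expr.sample_map
        )
        de = degx.nb_test(expr.counts, groups)
        found = de.loc[truth.deg_genes, "is_deg"].fillna(False).mean()
        assert found > 0.8

    def test_egene_cis_effect(self):
        cfg = SimConfig(
            n_geno=150, n_snp=400, n_gene=60, seed=8,
            expr=ExprConfig(n_modules=0, module_size=0, n_deg=0,
                            n_egenes=10, egene_log2fc_per_allele=1.0),
        )
        geno, pheno, expr, truth = simulate_cohort(cfg)
        assert len(truth.egenes) <= 10
        # at least one eGene's expression correlates with a cis SNP dosage
        if truth.egenes:
            gmap = {g.gene_id: g for g in geno.genes}
            hits = 0
            logx = np.log2(expr.counts.to_numpy(dtype=float) + 1.0)
            samp_geno_idx = [
                geno.genotype_ids.index(g) for g in expr.sample_map.to_numpy()
            ]
            for gid in truth.egenes:
                g = gmap[gid]
                inside = (
                    (geno.snps["chrom"] == g.chrom)
                    & geno.snps["pos"].between(g.start, g.end)
                )
                if not inside.any():
                    continue
                gi = list(expr.counts.index).index(gid)
                for j in np.nonzero(inside.to_numpy())[0]:
                    dos = geno.dosages[samp_geno_idx, j].astype(float)
                    if dos.std() == 0:
                        continue
                    r = np.corrcoef(logx[gi], dos)[0, 1]
                    if abs(r) > 0.5:
                        hits += 1
                        break
            assert hits >= 1


class TestWriteBundle:
    def test_round_trip_and_counts(self, small_cohort, tmp_path):
        cfg, geno = small_cohort["cfg"], small_cohort["geno"]
        manifest = write_bundle(
            tmp_path, cfg, geno, small_cohort["pheno"],
            expr=small_cohort["expr"], truth=small_cohort["truth"],
        )
        assert manifest["seed"] == cfg.seed
        dosages, snps, samples = read_vcf(tmp_path / "genotypes.vcf")
        assert samples == geno.genotype_ids
        assert np.array_equal(dosages, geno.dosages)
        body = [
            line for line in (tmp_path / "genotypes.vcf").read_text().splitlines()
            if not line.startswith("#")
        ]
        assert len(body) == cfg.n_snp

    def test_gff3_length_accounting(self, small_cohort, tmp_path):
        from omnileaf.annotate import context_lengths

        cfg, geno = small_cohort["cfg"], small_cohort["geno"]
        write_bundle(tmp_path, cfg, geno, small_cohort["pheno"])
        # independent accounting: sum feature lengths straight from the text
        sums = {"five_prime_UTR": 0, "three_prime_UTR": 0, "CDS": 0}
        spans = 0
        for line in (tmp_path / "genes.gff3").read_text().splitlines():
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            ftype, start, end = parts[2], int(parts[3]), int(parts[4])
            if ftype in sums:
                sums[ftype] += end - start + 1
            elif ftype == "gene":
                spans += end - start + 1
        lengths = context_lengths(geno.genes, window=2000)
        assert lengths["5'UTR"] == sums["five_prime_UTR"]
        assert lengths["3'UTR"] == sums["three_prime_UTR"]
        assert lengths["exon"] == sums["CDS"]
        assert lengths["intron"] == spans - sum(sums.values())

    def test_ground_truth_json(self, small_cohort, tmp_path):
        write_bundle(
            tmp_path, small_cohort["cfg"], small_cohort["geno"],
            small_cohort["pheno"], truth=small_cohort["truth"],
        )
        data = json.loads((tmp_path / "ground_truth.json").read_text())
        assert set(data["true_h2"]) == set(small_cohort["cfg"].traits)

    def test_checksums_present(self, small_cohort, tmp_path):
        manifest = write_bundle(
            tmp_path, small_cohort["cfg"], small_cohort["geno"],
            small_cohort["pheno"],
        )
        for entry in manifest["files"].values():
            assert len(entry["sha256"]) == 64
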
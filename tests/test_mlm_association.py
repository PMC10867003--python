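"""SNP QC, LD utilities, kinship, REML, and the mixed-model scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epimethqtl as eq
from epimethqtl.containers import GenotypeMatrix, VarianceComponents
from epimethqtl.mlm_association import (
    bonferroni_threshold,
    emmax_scan,
    kinship,
    ld_decay,
    ld_prune,
    ld_r2,
    mlm_gwas,
    reml_fit,
    snp_qc,
)

import oracles


def geno_from_dosage(dosage, positions=None, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    snps = pd.DataFrame({"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"})
    snps.index = pd.Index([f"{chrom}_{p}" for p in positions], name="snp_id")
    return GenotypeMatrix(dosage=dosage, snps=snps,
                          accessions=[f"a{i}" for i in range(n)])


class TestSnpQC:
    def test_maf_boundary_inclusive(self):
        # 10 accessions: one het => maf 0.05 kept; monomorphic removed
        d = np.zeros((10, 2))
        d[0, 0] = 1.0  # maf 0.05
        G = geno_from_dosage(d)
        out = snp_qc(G, maf_min=0.05, missing_max=0.25)
        assert out.snps.index.tolist() == ["chr1_100"]

    def test_missing_rate_boundary(self):
        col = np.array([0.0, 2.0] * 25)  # maf 0.5
        d = np.column_stack([col, col])
        d[:13, 0] = np.nan  # 26% missing -> removed
        d[:12, 1] = np.nan  # 24% -> kept
        out = snp_qc(geno_from_dosage(d), 0.05, 0.25)
        assert out.n_snps == 1

    def test_invalid_thresholds(self):
        G = geno_from_dosage(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            snp_qc(G, maf_min=0.7)
        with pytest.raises(ValueError):
            snp_qc(G, missing_max=1.5)


class TestLdR2:
    def test_self_and_complement(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        gi = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        gj = np.array([0, 1, 0, 1, 2, 2], dtype=float)
        assert ld_r2(gi, gj) == pytest.approx(0.5625)

    def test_undefined_signals(self):
        assert np.isnan(ld_r2([0, 1, np.nan, np.nan], [np.nan, np.nan, 0, 1]))
        assert np.isnan(ld_r2([1, 1, 1, 1], [0, 1, 2, 0]))


class TestLdPrune:
    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(200, 20)).astype(float)
        G = geno_from_dosage(d)
        out = ld_prune(G, 50, 10, 0.1)
        # with n=200 independent SNPs, sample r^2 ~ 1/200 << 0.1
        assert out.n_snps == 20

    def test_duplicate_snp_resolved_to_one(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.3, 100).astype(float)
        d = np.column_stack([col, col])
        out = ld_prune(geno_from_dosage(d), 50, 10, 0.1)
        assert out.n_snps == 1

    @pytest.mark.parametrize("case", range(40))
    def test_matches_bruteforce_reference(self, case):
        rng = np.random.default_rng(1000 + case)
        n, m = 30, int(rng.integers(10, 60))
        # correlated dosages: mixture of shared latent + noise
        latent = rng.binomial(2, 0.5, size=(n, max(m // 5, 1))).astype(float)
        d = np.empty((n, m))
        for j in range(m):
            src = latent[:, rng.integers(latent.shape[1])]
            flip = rng.random(n) < rng.uniform(0.0, 0.6)
            d[:, j] = np.where(flip, rng.binomial(2, 0.5, n), src)
        pos = np.sort(rng.choice(100_000, m, replace=False)) + 1
        G = geno_from_dosage(d, positions=pos)
        window, step = int(rng.integers(5, 20)), int(rng.integers(1, 5))
        got = ld_prune(G, window, step, 0.1).snps.pos.tolist()
        keep = oracles.prune_windowed(d, pos, G.maf(), window, step, 0.1)
        assert got == [pos[i] for i in keep]

    def test_step_exceeding_window_rejected(self):
        G = geno_from_dosage(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            ld_prune(G, window_snps=5, step_snps=10)


class TestKinship:
    def test_identical_accessions_have_equal_rows(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(20, 100)).astype(float)
        d[1] = d[0]
        K = kinship(geno_from_dosage(d)).K
        np.testing.assert_allclose(K[0], K[1], atol=1e-10)
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-9)

    @pytest.mark.parametrize("method", ["centered_grm", "ibs"])
    def test_symmetric_psd(self, method, small_cohort):
        _, G, _ = small_cohort
        K = kinship(G, method=method).K
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K)[0] >= -1e-8

    def test_zero_snps_rejected(self):
        G = geno_from_dosage(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            kinship(G.take_snps(np.array([], dtype=int)))


class TestReml:
    def test_null_trait_has_low_heritability(self):
        rng = np.random.default_rng(3)
        cfg = eq.SimConfig(n_accessions=300, n_snps=500, seed=8, genes=())
        G = eq.simulate_genotypes(cfg)
        K = kinship(G)
        low = 0
        for rep in range(20):
            y = rng.normal(size=300)
            vc = reml_fit(y, K)
            low += vc.heritability < 0.2
        assert low >= 17  # ~95% of seeds

    def test_variance_ratio_recovered(self):
        rng = np.random.default_rng(4)
        cfg = eq.SimConfig(n_accessions=300, n_snps=500, seed=9, genes=())
        G = eq.simulate_genotypes(cfg)
        K = kinship(G)
        L = np.linalg.cholesky(K.K + 1e-8 * np.eye(300))
        deltas = []
        for rep in range(25):
            u = L @ rng.normal(size=300)
            e = rng.normal(size=300)
            vc = reml_fit(u + e, K)
            deltas.append(vc.delta)
        assert 0.5 <= np.median(deltas) <= 2.0
        assert np.mean([0.25 <= d <= 4 for d in deltas]) >= 0.9

    def test_identity_kinship_degenerates_to_ols(self):
        rng = np.random.default_rng(5)
        n, m = 120, 300
        d = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        G = geno_from_dosage(d)
        y = rng.normal(size=n)
        K = np.eye(n)
        vc = reml_fit(y, K)
        res = emmax_scan(y, G, K, vc)
        # plain OLS with intercept
        x = d - d.mean(0)
        yc = y - y.mean()
        b = (x * yc[:, None]).sum(0) / (x ** 2).sum(0)
        rss = (yc ** 2).sum() - b ** 2 * (x ** 2).sum(0)
        se = np.sqrt(rss / (n - 2) / (x ** 2).sum(0))
        p_ols = 2 * stats.t.sf(np.abs(b / se), n - 2)
        dlog = np.abs(np.log10(res.table.p.to_numpy()) - np.log10(p_ols))
        assert np.nanmax(dlog) < 0.05

    def test_insufficient_observations_rejected(self):
        with pytest.raises(ValueError):
            reml_fit(np.zeros(2), np.eye(2))


class TestScan:
    def test_null_pvalues_uniform(self):
        # structured cohort, trait independent of all SNPs
        cfg = eq.SimConfig(n_accessions=300, n_snps=3000, n_chromosomes=10,
                           chrom_length_bp=3_000_000, seed=17, genes=())
        G = eq.simulate_genotypes(cfg)
        K = kinship(ld_prune(snp_qc(G)))
        rng = np.random.default_rng(18)
        sub = eq.synthetic_data.subpop_assignment(300, 2)
        y = rng.normal(size=300) + 0.3 * sub
        vc = reml_fit(y, K)
        res = emmax_scan(y, G, K, vc)
        p = res.table.p.dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01
        assert 0.9 <= res.lambda_gc <= 1.1

    def test_beta_equals_recomputed_whitened_slope(self, planted_cohort):
        cfg, G, genes, truth, sites, traits = planted_cohort
        Gq = snp_qc(G)
        K = kinship(ld_prune(Gq))
        res = mlm_gwas(traits.values.loc["GA:CG"], Gq, K, trait="GA:CG")
        y = traits.values.loc["GA:CG"].to_numpy(dtype=float)
        evals, evecs = np.linalg.eigh(K.K)
        w = res.vc.sigma_g2 * np.clip(evals, 0, None) + res.vc.sigma_e2
        W = evecs @ np.diag(1 / np.sqrt(w)) @ evecs.T
        j = int(np.nanargmin(res.table.p.to_numpy()))
        g = Gq.imputed_dosage()[:, j]
        yw, gw, ow = W @ y, W @ g, W @ np.ones(len(y))
        X = np.column_stack([ow, gw])
        beta = np.linalg.lstsq(X, yw, rcond=None)[0][1]
        assert beta == pytest.approx(res.table.beta.iloc[j], rel=1e-8)

    def test_power_monotone_in_pve_and_n(self):
        def power(pve, n, reps=8):
            hits = 0
            for seed in range(reps):
                cfg = eq.SimConfig(n_accessions=n, n_snps=600, seed=700 + seed,
                                   genes=(eq.GeneSpec("GA", "lncRNA"),))
                G = eq.simulate_genotypes(cfg)
                genes = eq.simulate_genes(cfg)
                truth = eq.make_truth(G, genes,
                                      [eq.QtlSpec("GA", "CG", "cis", pve)], cfg)
                sites = eq.simulate_methylome(G, genes, truth, cfg)
                tm = eq.build_trait_matrix(sites, genes, contexts=("CG",),
                                           min_total=5)
                Gq = snp_qc(G)
                res = mlm_gwas(tm.values.loc["GA:CG"], Gq,
                               kinship(ld_prune(Gq)), trait="GA:CG")
                thr = bonferroni_threshold(0.01, res.table.p.notna().sum())
                causal = truth.causal_snp_id[0]
                if causal in res.table.index and res.table.p[causal] <= thr:
                    hits += 1
            return hits / reps

        assert power(0.25, 500) >= 0.9
        assert power(0.02, 100) <= 0.2


class TestBonferroni:
    def test_published_genomewide_threshold(self):
        thr = bonferroni_threshold(0.01, 1_110_440)
        assert f"{thr:.2e}" == "9.01e-09"

    def test_identity_and_simple_cases(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)
        assert bonferroni_threshold(0.013, 977) * 977 == pytest.approx(0.013)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.01, 0)


class TestLdDecay:
    def test_matches_bruteforce_binned_means(self):
        cfg = eq.SimConfig(n_accessions=80, n_snps=100, n_chromosomes=1,
                           chrom_length_bp=50_000, seed=23, genes=(),
                           missing_genotype_rate=0.0)
        G = eq.simulate_genotypes(cfg)
        tab, _ = ld_decay(G, max_dist_bp=20_000, bin_width_bp=2500)
        pos = G.snps.pos.to_numpy()
        sums = np.zeros(len(tab))
        counts = np.zeros(len(tab))
        for i in range(G.n_snps):
            for j in range(i + 1, G.n_snps):
                dist = pos[j] - pos[i]
                if dist >= 20_000:
                    continue
                r2 = oracles.pearson_r2(G.dosage[:, i], G.dosage[:, j])
                if not np.isnan(r2):
                    b = int(dist // 2500)
                    sums[b] += r2
                    counts[b] += 1
        for b in range(len(tab)):
            if counts[b]:
                assert tab.mean_r2.iloc[b] == pytest.approx(sums[b] / counts[b],
                                                            rel=1e-9)
                assert tab.n_pairs.iloc[b] == counts[b]

    def test_monolithic_ld_has_no_decay_distance(self):
        cfg = eq.SimConfig(n_accessions=60, n_snps=40, n_chromosomes=1,
                           chrom_length_bp=50_000, n_founders=2, n_subpops=1,
                           recomb_rate_per_bp=0.0, missing_genotype_rate=0.0,
                           seed=2, genes=())
        G = eq.simulate_genotypes(cfg)
        tab, decay = ld_decay(G, max_dist_bp=40_000, bin_width_bp=5000)
        assert decay is None
        np.testing.assert_allclose(tab.dropna(subset=["mean_r2"]).mean_r2, 1.0,
                                   atol=1e-9)

    def test_invalid_bin_width(self, small_cohort):
        _, G, _ = small_cohort
        with pytest.raises(ValueError):
            ld_decay(G, 1000, 0)
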
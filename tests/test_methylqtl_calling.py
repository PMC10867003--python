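"""The density / cluster / cap / representative / LD-dedup / classify
cascade, each stage against a naive reference implementation."""

import numpy as np
import pandas as pd
import pytest

import epimethqtl as eq
from epimethqtl.containers import GenotypeMatrix
from epimethqtl.methylqtl_calling import (
    QtlCallParams,
    call_methylqtl,
    classify_distance,
    cluster_snps,
    density_filter,
    estimate_pve,
    ld_dedup,
    pick_representative,
    trait_cluster_filter,
)

import oracles
from conftest import assoc_from_pvalues
from test_mlm_association import geno_from_dosage


def snp_frame(positions, chroms=None, p=None):
    chroms = chroms if chroms is not None else ["chr1"] * len(positions)
    df = pd.DataFrame({"chrom": chroms, "pos": positions})
    if p is not None:
        df["p"] = p
    df.index = pd.Index([f"s{i}" for i in range(len(df))], name="snp_id")
    return df


class TestDensityFilter:
    def test_isolated_snp_removed(self):
        out = density_filter(snp_frame([1000, 500_000]), 16_000, 20)
        assert out.empty

    def test_22_snps_within_1kb_all_kept(self):
        out = density_filter(snp_frame(list(range(1000, 1022))), 16_000, 20)
        assert len(out) == 22  # each has 21 > 20 neighbors

    def test_21_snps_boundary_all_removed(self):
        out = density_filter(snp_frame(list(range(1000, 1021))), 16_000, 20)
        assert out.empty  # each has exactly 20 neighbors, not > 20

    @pytest.mark.parametrize("case", range(50))
    def test_matches_bruteforce_count(self, case):
        rng = np.random.default_rng(2000 + case)
        m = int(rng.integers(5, 120))
        chroms = sorted(rng.choice(["chr1", "chr2"], m))
        pos = []
        for c in ("chr1", "chr2"):
            k = chroms.count(c)
            pos.extend(np.sort(rng.choice(60_000, k, replace=False)) + 1)
        window = int(rng.choice([4000, 16_000, 32_000]))
        min_other = int(rng.integers(0, 25))
        got = density_filter(snp_frame(pos, chroms), window, min_other)
        keep = oracles.density_keep(pos, chroms, window, min_other)
        assert got.pos.tolist() == [p for p, k in zip(pos, keep) if k]


class TestClustering:
    def test_gap_rule_forces_expected_split(self):
        out = cluster_snps(snp_frame([1000, 5000, 20_000]), gap_bp=8000)
        assert out.cluster.tolist() == [0, 0, 1]

    def test_single_snp_single_cluster(self):
        out = cluster_snps(snp_frame([123]), 8000)
        assert out.cluster.tolist() == [0]

    def test_chromosome_change_opens_cluster(self):
        out = cluster_snps(snp_frame([1000, 2000, 1000],
                                     ["chr1", "chr1", "chr2"]), 8000)
        assert out.cluster.tolist() == [0, 0, 1]

    @pytest.mark.parametrize("case", range(40))
    def test_matches_adjacency_oracle(self, case):
        rng = np.random.default_rng(3000 + case)
        m = int(rng.integers(2, 500))
        pos = np.sort(rng.choice(200_000, m, replace=False)) + 1
        out = cluster_snps(snp_frame(pos), 8000)
        assert out.cluster.tolist() == oracles.cluster_ids(
            pos.tolist(), ["chr1"] * m, 8000)


class TestTraitCap:
    @pytest.mark.parametrize("n,kept", [(20, True), (21, False), (0, False),
                                        (1, True)])
    def test_boundaries(self, n, kept):
        assert trait_cluster_filter(n, 20) is kept


class TestRepresentative:
    def test_most_significant_member_wins(self):
        c = snp_frame([10, 20, 30], p=[1e-10, 1e-12, 1e-9])
        assert pick_representative(c).name == "s1"

    def test_tie_broken_by_position(self):
        c = snp_frame([300, 100], p=[1e-8, 1e-8])
        assert pick_representative(c).name == "s1"  # pos 100

    def test_missing_pvalue_is_integrity_error(self):
        c = snp_frame([10, 20], p=[1e-8, np.nan])
        with pytest.raises(ValueError, match="s1"):
            pick_representative(c)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_argmin_oracle(self, case):
        rng = np.random.default_rng(4000 + case)
        m = int(rng.integers(1, 40))
        pos = rng.integers(1, 10_000, m)
        p = 10.0 ** -rng.integers(8, 15, m)
        c = snp_frame(pos.tolist(), p=p.tolist())
        members = [(sid, int(pp), float(pv)) for sid, pp, pv in
                   zip(c.index, c.pos, c.p)]
        assert pick_representative(c).name == oracles.representative(members)


class TestLdDedup:
    def _reps(self, snp_ids, pos, p):
        return pd.DataFrame({"snp_id": snp_ids, "pos": pos, "p": p})

    def test_perfect_ld_keeps_most_significant(self):
        rng = np.random.default_rng(6)
        col = rng.binomial(2, 0.4, 50).astype(float)
        G = geno_from_dosage(np.column_stack([col, col]))
        reps = self._reps(["chr1_100", "chr1_200"], [100, 200], [1e-20, 1e-5])
        out = ld_dedup(reps, G, 0.1)
        assert out.snp_id.tolist() == ["chr1_100"]

    def test_below_threshold_keeps_both(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.4, size=(400, 2)).astype(float)
        G = geno_from_dosage(d)
        reps = self._reps(["chr1_100", "chr1_200"], [100, 200], [1e-20, 1e-5])
        out = ld_dedup(reps, G, 0.1)
        assert len(out) == 2

    @pytest.mark.parametrize("case", range(30))
    def test_matches_greedy_oracle(self, case):
        rng = np.random.default_rng(5000 + case)
        n, m = 40, int(rng.integers(2, 20))
        latent = rng.binomial(2, 0.5, size=(n, 3)).astype(float)
        d = np.empty((n, m))
        for j in range(m):
            src = latent[:, rng.integers(3)]
            flip = rng.random(n) < rng.uniform(0, 0.7)
            d[:, j] = np.where(flip, rng.binomial(2, 0.5, n), src)
        G = geno_from_dosage(d)
        ids = G.snps.index.tolist()
        p = 10.0 ** -rng.integers(6, 16, m)
        reps = self._reps(ids, G.snps.pos.tolist(), p.tolist())
        got = ld_dedup(reps, G, 0.1).snp_id.tolist()
        dosage_by_id = {sid: d[:, j].tolist() for j, sid in enumerate(ids)}
        members = list(zip(ids, G.snps.pos.tolist(), p.tolist()))
        assert sorted(got) == sorted(oracles.dedup_greedy(members, dosage_by_id,
                                                          0.1))


class TestClassification:
    GENE = ("chr1", 50_000, 52_000)

    def test_100kb_boundary_is_strict(self):
        # gene ends at base 51,999 (0-based); 1-based SNP pos 151,999 is
        # 99,999 bp away (proximal), pos 152,000 is exactly 100 kb (distal)
        d1, c1 = classify_distance("chr1", 151_999, self.GENE)
        d2, c2 = classify_distance("chr1", 152_000, self.GENE)
        assert (d1, c1) == (99_999, "proximal")
        assert (d2, c2) == (100_000, "distal")

    def test_inside_gene_body_distance_zero(self):
        d, c = classify_distance("chr1", 51_000, self.GENE)
        assert (d, c) == (0.0, "proximal")

    def test_other_chromosome_always_distal(self):
        d, c = classify_distance("chr2", 51_000, self.GENE)
        assert np.isinf(d) and c == "distal"

    def test_reflection_symmetry_about_gene_midpoint(self):
        for off in (1, 500, 5000, 99_000, 120_000):
            left = classify_distance("chr1", 50_000 - off, self.GENE)
            right = classify_distance("chr1", 52_000 + off, self.GENE)
            # 1-based position just right of the gene end mirrors just left
            assert left[0] == right[0] + 1 or left == right


class TestPve:
    def test_zero_t_gives_zero(self):
        assert estimate_pve(0.0, 100) == 0.0

    def test_t_squared_equal_df_gives_half(self):
        assert estimate_pve(10.0, 100) == pytest.approx(0.5)

    def test_monotone_in_t_and_bounded(self):
        ts = np.linspace(0, 50, 40)
        pves = [estimate_pve(t, 200) for t in ts]
        assert all(0 <= v <= 1 for v in pves)
        assert all(a <= b for a, b in zip(pves, pves[1:]))

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            estimate_pve(1.0, 0)


class TestFullCascade:
    def _naive_cascade(self, res, dosage_by_id, params):
        """Direct transcription of the published filtering order."""
        thr = params.alpha / len(res.table)
        sig = res.table[res.table.p <= thr].sort_values(["chrom", "pos"])
        keep = oracles.density_keep(sig.pos.tolist(), sig.chrom.tolist(),
                                    params.window_bp, params.min_other_neighbors)
        dense = sig[np.asarray(keep, dtype=bool)] if len(sig) else sig
        if dense.empty:
            return []
        cids = oracles.cluster_ids(dense.pos.tolist(), dense.chrom.tolist(),
                                   params.gap_bp)
        n_clusters = len(set(cids))
        if n_clusters > params.max_clusters:
            return []
        reps = []
        for cid in sorted(set(cids)):
            members = [(sid, int(pp), float(pv)) for (sid, pp, pv), c in
                       zip(zip(dense.index, dense.pos, dense.p), cids) if c == cid]
            rep_id = oracles.representative(members)
            reps.append((rep_id, int(dense.pos[rep_id]), float(dense.p[rep_id])))
        return oracles.dedup_greedy(reps, dosage_by_id, params.dedup_r2)

    @pytest.mark.parametrize("case", range(40))
    def test_matches_naive_reference(self, case):
        rng = np.random.default_rng(6000 + case)
        n, m = 50, 400
        latent = rng.binomial(2, 0.5, size=(n, 8)).astype(float)
        d = np.empty((n, m))
        for j in range(m):
            src = latent[:, rng.integers(8)]
            flip = rng.random(n) < rng.uniform(0, 0.5)
            d[:, j] = np.where(flip, rng.binomial(2, 0.5, n), src)
        pos = np.sort(rng.choice(150_000, m, replace=False)) + 1
        G = geno_from_dosage(d, positions=pos)
        # synthetic p-values: a few dense significant blocks + noise
        p = rng.uniform(0.1, 1.0, m)
        for _ in range(int(rng.integers(1, 4))):
            c = rng.integers(m)
            lo, hi = max(c - 30, 0), min(c + 30, m)
            p[lo:hi] = 10.0 ** -rng.uniform(8, 14, hi - lo)
        res = assoc_from_pvalues("GA:CG", ["chr1"] * m, pos, p)
        genes = pd.DataFrame([("GA", "chr1", 70_000, 72_000, "+", "lncRNA")],
                             columns=["gene_id", "chrom", "start", "end",
                                      "strand", "nc_class"])
        params = QtlCallParams(alpha=0.01, min_other_neighbors=5)
        qtl, audit = call_methylqtl([res], G, genes, params)
        dosage_by_id = {sid: d[:, j].tolist()
                        for j, sid in enumerate(G.snps.index)}
        expect = self._naive_cascade(res, dosage_by_id, params)
        assert sorted(qtl.rep_snp.tolist()) == sorted(expect)
        # cascade monotonicity
        row = audit.iloc[0]
        assert row.n_sig >= row.n_after_density >= row.n_clusters >= row.n_qtl

    def test_planted_cis_and_trans_recovered_with_ordered_pve(self):
        cfg = eq.SimConfig(n_accessions=500, n_snps=3000, seed=31,
                           genes=(eq.GeneSpec("GA", "lncRNA"),
                                  eq.GeneSpec("GB", "miRNA")))
        G = eq.simulate_genotypes(cfg)
        genes = eq.simulate_genes(cfg)
        truth = eq.make_truth(G, genes,
                              [eq.QtlSpec("GA", "CG", "cis", 0.20),
                               eq.QtlSpec("GA", "CHG", "trans", 0.08)], cfg)
        sites = eq.simulate_methylome(G, genes, truth, cfg)
        tm = eq.build_trait_matrix(sites, genes, min_total=5)
        from epimethqtl.mlm_association import kinship, ld_prune, mlm_gwas, snp_qc
        Gq = snp_qc(G)
        K = kinship(ld_prune(Gq))
        res = [mlm_gwas(tm.values.loc[t], Gq, K, trait=t)
               for t in ("GA:CG", "GA:CHG")]
        qtl, _ = call_methylqtl(res, Gq, genes)
        cis = qtl[(qtl.trait == "GA:CG") & (qtl.qtl_class == "proximal")]
        trans = qtl[(qtl.trait == "GA:CHG") & (qtl.qtl_class == "distal")]
        assert len(cis) >= 1 and len(trans) >= 1
        assert cis.pve.max() > trans.pve.max()
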
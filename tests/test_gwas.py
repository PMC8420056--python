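"""Kinship, mixed-model scan, Meff, mQTL clustering and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mqtlkit import gwas, simulate
from mqtlkit.containers import GeneModelSet, GenotypeMatrix


def make_geno(dosages, chroms=None, positions=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = [f"s{j}" for j in range(m)]
    chroms = chroms or ["chr1"] * m
    positions = positions if positions is not None else np.arange(1, m + 1) * 100
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2
    var = pd.DataFrame({"chrom": chroms, "pos": positions,
                        "ref": ["A"] * m, "alt": ["T"] * m,
                        "maf": np.minimum(p, 1 - p)}, index=snps)
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=[f"L{i}" for i in range(n)], columns=snps),
        var)


class TestKinship:
    def test_identical_lines_share_kinship(self):
        geno = make_geno([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 0, 1]])
        K = gwas.kinship(geno)
        assert np.isclose(K.iloc[0, 1], K.iloc[0, 0])

    def test_hand_computed_toy(self):
        """3 lines x 2 SNPs against the VanRaden formula by hand."""
        dos = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        geno = make_geno(dos)
        p = dos.mean(axis=0) / 2  # (0.5, 0.5)
        W = dos - 2 * p
        expect = W @ W.T / (2 * np.sum(p * (1 - p)))
        K = gwas.kinship(geno)
        assert np.allclose(K.to_numpy(), expect, atol=1e-12)

    def test_gram_matrix_psd(self, rng):
        dos = rng.integers(0, 3, size=(50, 200)).astype(float)
        K = gwas.kinship(make_geno(dos))
        assert np.linalg.eigvalsh(K.to_numpy()).min() > -1e-8

    def test_monomorphic_only_error(self):
        geno = make_geno([[2.0, 0.0], [2.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="monomorphic"):
            gwas.kinship(geno)


class TestMlmScan:
    def test_identity_kinship_equals_ols(self, geno_small):
        """K = I, no PCs: p equals the OLS t-test p for every SNP."""
        rng = np.random.default_rng(5)
        n = len(geno_small.line_ids)
        y = pd.Series(rng.normal(size=n), index=geno_small.line_ids)
        res = gwas.mlm_scan(geno_small, y, np.eye(n), n_pc=0)
        G = geno_small.dosages.to_numpy()
        for j in range(0, G.shape[1], 13):
            ols = stats.linregress(G[:, j], y.to_numpy())
            assert abs(np.log10(res["p"].iloc[j]) - np.log10(ols.pvalue)) < 1e-6

    def test_zero_genetic_variance_equals_ols_with_pcs(self, geno_small):
        """K = 0 forces V = I: the scan is exact OLS with PC covariates."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = len(geno_small.line_ids)
        y = pd.Series(rng.normal(size=n), index=geno_small.line_ids)
        res = gwas.mlm_scan(geno_small, y, np.zeros((n, n)), n_pc=3)
        pcs = gwas.genotype_pcs(geno_small, 3).to_numpy()
        G = geno_small.dosages.to_numpy()
        for j in range(0, G.shape[1], 29):
            X = sm.add_constant(np.column_stack([pcs, G[:, j]]))
            fit = sm.OLS(y.to_numpy(), X).fit()
            assert abs(np.log10(res["p"].iloc[j])
                       - np.log10(fit.pvalues[-1])) < 1e-6

    def test_null_inflation_controlled(self, geno_small, kinship_small):
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=len(geno_small.line_ids)),
                      index=geno_small.line_ids)
        res = gwas.mlm_scan(geno_small, y, kinship_small, n_pc=5)
        chi2 = stats.chi2.isf(res["p"].dropna(), 1)
        lam = np.median(chi2) / stats.chi2.ppf(0.5, 1)
        assert 0.8 <= lam <= 1.2

    def test_line_reordering_invariance(self, geno_small, kinship_small):
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(size=len(geno_small.line_ids)),
                      index=geno_small.line_ids)
        res1 = gwas.mlm_scan(geno_small, y, kinship_small, n_pc=2)
        order = list(rng.permutation(geno_small.line_ids))
        geno_p = GenotypeMatrix(geno_small.dosages.loc[order],
                                geno_small.variants)
        K_p = kinship_small.loc[order, order]
        res2 = gwas.mlm_scan(geno_p, y.loc[order], K_p, n_pc=2)
        assert np.allclose(res1["p"].dropna(), res2["p"].dropna(), rtol=1e-6)

    def test_causal_snp_detected(self, geno_small, kinship_small):
        rng = np.random.default_rng(9)
        snp = geno_small.snp_ids[37]
        g = geno_small.dosages[snp]
        y = g * 0.8 + pd.Series(rng.normal(size=len(g)), index=g.index)
        res = gwas.mlm_scan(geno_small, y, kinship_small, n_pc=5)
        assert res.loc[snp, "p"] < 1e-6
        assert res.loc[snp, "pve"] > 0.05

    def test_constant_trait_error(self, geno_small, kinship_small):
        y = pd.Series(1.0, index=geno_small.line_ids)
        with pytest.raises(ValueError, match="constant"):
            gwas.mlm_scan(geno_small, y, kinship_small)

    def test_monomorphic_snp_skipped(self, kinship_small, geno_small):
        dosages = geno_small.dosages.copy()
        dosages.iloc[:, 0] = 2.0
        geno = GenotypeMatrix(dosages, geno_small.variants)
        rng = np.random.default_rng(10)
        y = pd.Series(rng.normal(size=len(geno.line_ids)),
                      index=geno.line_ids)
        res = gwas.mlm_scan(geno, y, kinship_small)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p"].iloc[0])


class TestThresholds:
    def test_published_meff_gives_published_threshold(self):
        thr = gwas.suggestive_threshold(474_242)
        assert f"{thr:.2e}" == "2.11e-06"

    def test_simple_reciprocal(self):
        assert gwas.suggestive_threshold(100) == 0.01

    def test_full_precision(self):
        assert np.isclose(gwas.suggestive_threshold(474_242),
                          2.1086337645019214e-06, rtol=1e-12)

    def test_meff_below_one_error(self):
        with pytest.raises(ValueError):
            gwas.suggestive_threshold(0)

    def test_meff_orthogonal_snps(self):
        """Exactly uncorrelated SNPs: Meff equals the SNP count."""
        # 4 orthogonal +-1 patterns over 8 lines, mapped to dosages {0,2}
        H = np.array([[1, 1, 1, 1], [1, -1, 1, -1],
                      [1, 1, -1, -1], [1, -1, -1, 1]])
        pattern = np.vstack([H, -H])
        dos = (pattern + 1.0)  # 0/2 dosages, mutually orthogonal after centering
        geno = make_geno(dos)
        assert gwas.effective_marker_count(geno) == 4

    def test_meff_duplicated_blocks(self):
        """Two duplicated SNPs per block, two blocks -> Meff = 2."""
        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, size=40).astype(float)
        b = rng.integers(0, 3, size=40).astype(float)
        dos = np.column_stack([a, a, b, b])
        geno = make_geno(dos, chroms=["chr1", "chr1", "chr2", "chr2"],
                         positions=[100, 200, 100, 200])
        assert gwas.effective_marker_count(geno) == 2

    def test_meff_bounded_by_snp_count(self, geno_small):
        meff = gwas.effective_marker_count(geno_small)
        assert 10 <= meff <= len(geno_small.snp_ids)


class TestClusterMqtl:
    def _sig(self, positions, chroms=None, pvals=None, traits=None):
        m = len(positions)
        return pd.DataFrame({
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chroms or ["chr1"] * m,
            "pos": positions,
            "p": pvals if pvals is not None else [1e-8] * m,
            "trait": traits or ["t1"] * m,
        })

    def test_gap_rule(self):
        """(100; 5,000; 30,000): 4,900 < 10 kb joins, 25,000 splits."""
        mqtls = gwas.cluster_mqtl(self._sig([100, 5_000, 30_000]))
        spans = sorted((q.start, q.end) for q in mqtls)
        assert spans == [(100, 5_000), (30_000, 30_000)]

    def test_chromosomes_never_merge(self):
        mqtls = gwas.cluster_mqtl(self._sig([500, 500],
                                            chroms=["chr1", "chr2"]))
        assert len(mqtls) == 2

    def test_exact_gap_splits(self):
        mqtls = gwas.cluster_mqtl(self._sig([100, 10_100]))  # gap == 10 kb
        assert len(mqtls) == 2
        mqtls = gwas.cluster_mqtl(self._sig([100, 10_099]))  # gap 9,999
        assert len(mqtls) == 1

    def test_peak_snp_min_p_tie_smaller_position(self):
        sig = self._sig([100, 200, 300], pvals=[1e-8, 1e-9, 1e-9])
        q = gwas.cluster_mqtl(sig)[0]
        assert q.peak_snp == "s1"  # p tie between s1 and s2 -> smaller pos

    def test_empty_input(self):
        assert gwas.cluster_mqtl(pd.DataFrame(
            columns=["snp", "chrom", "pos", "p", "trait"])) == []

    def test_matches_transitive_closure_oracle(self, rng):
        """200 random SNPs: clusters equal the O(n^2) closure of < 10 kb."""
        pos = np.sort(rng.choice(np.arange(1, 500_000), size=200,
                                 replace=False))
        chroms = rng.choice(["chr1", "chr2"], size=200)
        sig = self._sig(list(pos), chroms=list(chroms),
                        pvals=list(rng.uniform(1e-12, 1e-6, 200)))
        mqtls = gwas.cluster_mqtl(sig)
        got = {tuple(sorted(q.member_snps)) for q in mqtls}

        parent = dict(zip(sig["snp"], sig["snp"]))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        rows = list(sig.itertuples())
        for i, a in enumerate(rows):
            for b in rows[i + 1:]:
                if a.chrom == b.chrom and abs(a.pos - b.pos) < 10_000:
                    parent[find(a.snp)] = find(b.snp)
        oracle: dict[str, list] = {}
        for s in sig["snp"]:
            oracle.setdefault(find(s), []).append(s)
        assert got == {tuple(sorted(v)) for v in oracle.values()}

    def test_idempotent_on_own_output(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 200_000), size=80,
                                 replace=False))
        sig = self._sig(list(pos), pvals=list(rng.uniform(1e-10, 1e-6, 80)))
        first = gwas.cluster_mqtl(sig)
        members = {tuple(sorted(q.member_snps)) for q in first}
        again = gwas.cluster_mqtl(sig[sig["snp"].isin(
            [s for q in first for s in q.member_snps])])
        assert {tuple(sorted(q.member_snps)) for q in again} == members

    def test_unions_traits_and_conditions(self):
        sig = pd.DataFrame({
            "snp": ["s0", "s0", "s1"], "chrom": ["chr1"] * 3,
            "pos": [100, 100, 900], "p": [1e-8, 1e-9, 1e-7],
            "trait": ["m1", "m2", "m1"],
            "condition": ["WW", "DS", "DS"]})
        q = gwas.cluster_mqtl(sig)[0]
        assert q.traits == ["m1", "m2"]
        assert q.conditions == ["DS", "WW"]


class TestCandidateGenes:
    def _genes(self):
        return GeneModelSet(genes=pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1_000, 5_000],
             "end": [2_000, 6_000], "strand": ["+", "-"]},
            index=["gA", "gB"]))

    def _mqtl_for(self, sig):
        return gwas.cluster_mqtl(sig)

    def test_snp_inside_gene(self):
        sig = pd.DataFrame({"snp": ["s0"], "chrom": ["chr1"], "pos": [1_500],
                            "p": [1e-9], "trait": ["m"]})
        mqtls = gwas.assign_candidate_genes(self._mqtl_for(sig),
                                            self._genes(), sig)
        assert mqtls[0].candidate_genes == ["gA"]

    def test_boundary_inclusive(self):
        sig = pd.DataFrame({"snp": ["s0", "s1"], "chrom": ["chr1"] * 2,
                            "pos": [1_000, 2_000], "p": [1e-9, 1e-9],
                            "trait": ["m"] * 2})
        mqtls = gwas.assign_candidate_genes(self._mqtl_for(sig),
                                            self._genes(), sig)
        assert mqtls[0].candidate_genes == ["gA"]

    def test_outside_gene_excluded(self):
        sig = pd.DataFrame({"snp": ["s0"], "chrom": ["chr1"], "pos": [999],
                            "p": [1e-9], "trait": ["m"]})
        mqtls = gwas.assign_candidate_genes(self._mqtl_for(sig),
                                            self._genes(), sig)
        assert mqtls[0].candidate_genes == []

    def test_matches_brute_force_membership(self, rng):
        """50 random SNPs x 20 random genes vs direct interval checks."""
        pos = np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))
        sig = pd.DataFrame({"snp": [f"s{j}" for j in range(50)],
                            "chrom": ["chr1"] * 50, "pos": pos,
                            "p": rng.uniform(1e-12, 1e-6, 50),
                            "trait": ["m"] * 50})
        starts = rng.integers(1, 90_000, size=20)
        genes = GeneModelSet(genes=pd.DataFrame({
            "chrom": ["chr1"] * 20, "start": starts,
            "end": starts + rng.integers(500, 5_000, size=20),
            "strand": ["+"] * 20}, index=[f"g{j}" for j in range(20)]))
        mqtls = gwas.assign_candidate_genes(gwas.cluster_mqtl(sig), genes, sig)
        for q in mqtls:
            expect = set()
            for s in q.member_snps:
                p = int(sig.set_index("snp").loc[s, "pos"])
                for gid, row in genes.genes.iterrows():
                    if row["start"] <= p <= row["end"]:
                        expect.add(gid)
            assert set(q.candidate_genes) == expect


class TestQtlOverlap:
    def _mqtl(self, chrom, start, end):
        return gwas.MQTL(chrom=chrom, start=start, end=end, peak_snp="s",
                         peak_p=1e-9, member_snps=["s"], traits=[],
                         conditions=[])

    def test_one_bp_overlap_counts(self):
        known = pd.DataFrame({"chrom": ["chr1"], "start": [150],
                              "end": [300]})
        flags, frac = gwas.qtl_overlap([self._mqtl("chr1", 100, 200)], known)
        assert flags.iloc[0] and frac == 1.0

    def test_adjacent_intervals_do_not_overlap(self):
        known = pd.DataFrame({"chrom": ["chr1"], "start": [201],
                              "end": [300]})
        flags, frac = gwas.qtl_overlap([self._mqtl("chr1", 100, 200)], known)
        assert not flags.iloc[0] and frac == 0.0

    def test_matches_brute_force_pairwise(self, rng):
        mqtls = [self._mqtl(rng.choice(["chr1", "chr2"]),
                            int(s), int(s) + int(rng.integers(1, 5_000)))
                 for s in rng.integers(1, 100_000, size=30)]
        ks = rng.integers(1, 100_000, size=15)
        known = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=15),
            "start": ks, "end": ks + rng.integers(1, 8_000, size=15)})
        flags, _ = gwas.qtl_overlap(mqtls, known)
        for q, got in zip(mqtls, flags):
            expect = any(
                k.chrom == q.chrom and k.start <= q.end and k.end >= q.start
                for k in known.itertuples())
            assert got == expect


class TestScanTraits:
    def test_multi_trait_scan_matches_single(self, geno_small, kinship_small):
        rng = np.random.default_rng(12)
        traits = pd.DataFrame(
            rng.normal(size=(len(geno_small.line_ids), 3)),
            index=geno_small.line_ids, columns=["a", "b", "c"])
        multi = gwas.scan_traits(geno_small, traits, kinship_small, n_pc=2)
        single = gwas.mlm_scan(geno_small, traits["b"], kinship_small, n_pc=2)
        got = multi[multi["trait"] == "b"].set_index("snp")["p"]
        assert np.allclose(got.dropna(), single["p"].dropna(), rtol=1e-9)

    def test_null_exceedance_rate_bounded(self, geno_small, kinship_small):
        """Suggestive threshold 1/Meff: null SNPs pass at ~1/Meff rate."""
        rng = np.random.default_rng(13)
        meff = gwas.effective_marker_count(geno_small)
        thr = gwas.suggestive_threshold(meff)
        n_snps = len(geno_small.snp_ids)
        exceed = 0
        n_rep = 10
        for rep in range(n_rep):
            y = pd.Series(rng.normal(size=len(geno_small.line_ids)),
                          index=geno_small.line_ids)
            res = gwas.mlm_scan(geno_small, y, kinship_small, n_pc=5)
            exceed += int((res["p"].dropna() < thr).sum())
        # expected about n_snps/meff false hits per scan
        assert exceed / n_rep <= 1.5 * n_snps / meff + 1.0
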
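import numpy as np
import pandas as pd
import pytest

from plastisel.errors import ValidationError
from plastisel.popgen import (MISSING, VariantTable, annotation_class_enrichment,
                              filter_variants, fst_outlier_enrichment,
                              gaussian_smooth, hwe_scan, ld_set_comparison,
                              mean_fst_contrast, pairwise_ld,
                              weir_cockerham_fst, weir_cockerham_theta)
from plastisel.stats import hwe_chisquare, two_proportion_test, welch_t_test


def brute_force_theta(geno_a, geno_b):
    """Independent Weir-Cockerham 1984 two-population theta, computed
    scalar-by-scalar from the variance-component definitions."""
    # cast to Python ints: int8 inputs would overflow the allele sums
    ga = [int(g) for g in geno_a if g != MISSING]
    gb = [int(g) for g in geno_b if g != MISSING]
    n1, n2 = len(ga), len(gb)
    if n1 < 2 or n2 < 2:
        return np.nan
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for g in ga if g == 1) / n1
    h2 = sum(1 for g in gb if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if s2 == 0 and (pbar == 0 or pbar == 1):
        return np.nan
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    if a + b + c == 0:
        return np.nan
    return a / (a + b + c)


def make_variants(genotypes, pos=None, qual=None, gene=None, fclass=None,
                  set_label=None, scaffold="scaffold_1"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    snps = pd.DataFrame({
        "scaffold": scaffold,
        "pos": pos if pos is not None else np.arange(1, n + 1) * 100,
        "qual": qual if qual is not None else np.full(n, 40.0),
        "gene_id": gene if gene is not None else ["gX"] * n,
        "functional_class": fclass if fclass is not None else ["noncoding"] * n,
        "set_label": set_label if set_label is not None else ["background"] * n,
    }, index=pd.Index([f"s{i}" for i in range(n)], name="snp_id"))
    return VariantTable(snps=snps, genotypes=genotypes,
                        sample_ids=[f"ind{j}" for j in range(m)])


class TestWeirCockerham:
    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n1, n2 = rng.integers(2, 6, size=2)
            ga = rng.integers(0, 3, size=n1)
            gb = rng.integers(0, 3, size=n2)
            geno = np.concatenate([ga, gb])[None, :].astype(np.int8)
            theta = weir_cockerham_theta(geno, np.arange(n1),
                                         np.arange(n1, n1 + n2))[0]
            expected = brute_force_theta(ga, gb)
            if np.isnan(expected):
                assert np.isnan(theta)
            else:
                assert theta == pytest.approx(expected, abs=1e-10)

    def test_fixed_difference_is_one(self):
        geno = np.array([[0, 0, 0, 2, 2, 2]], dtype=np.int8)
        theta = weir_cockerham_theta(geno, np.array([0, 1, 2]),
                                     np.array([3, 4, 5]))
        assert theta[0] == pytest.approx(1.0)

    def test_missing_genotypes_dropped(self):
        ga = np.array([0, 1, MISSING, 2], dtype=np.int8)
        gb = np.array([1, 1, 2, MISSING], dtype=np.int8)
        geno = np.concatenate([ga, gb])[None, :]
        theta = weir_cockerham_theta(geno, np.arange(4), np.arange(4, 8))
        expected = brute_force_theta(list(ga), list(gb))
        assert theta[0] == pytest.approx(expected, abs=1e-10)

    def test_matched_frequencies_near_zero(self):
        """HWE genotypes with identical frequencies in both populations
        give |theta| < 0.02 at n=40/40."""
        rng = np.random.default_rng(1)
        p = 0.4
        n_snps = 200
        geno = rng.binomial(2, p, size=(n_snps, 80)).astype(np.int8)
        theta = weir_cockerham_theta(geno, np.arange(40), np.arange(40, 80))
        assert abs(np.nanmean(theta)) < 0.02

    def test_undersized_population_flagged_nan(self):
        geno = np.array([[0, 2, 2, 2]], dtype=np.int8)
        theta = weir_cockerham_theta(geno, np.array([0]), np.array([1, 2, 3]))
        assert np.isnan(theta[0])


class TestSmoothing:
    def test_sigma_zero_returns_raw(self):
        pos = np.array([100, 200, 5000])
        vals = np.array([0.1, np.nan, 0.5])
        out = gaussian_smooth(pos, vals, sigma_bp=0)
        assert out[0] == 0.1 and np.isnan(out[1]) and out[2] == 0.5

    def test_sigma_infinite_returns_scaffold_mean(self):
        pos = np.array([100, 200, 300, 1000])
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        out = gaussian_smooth(pos, vals, sigma_bp=1e12)
        np.testing.assert_allclose(out, vals.mean(), atol=1e-9)

    def test_weighted_mean_hand_case(self):
        pos = np.array([0.0, 1000.0])
        vals = np.array([1.0, 0.0])
        sigma = 1000.0
        w = np.exp(-0.5)
        expected0 = (1.0 + w * 0.0) / (1.0 + w)
        out = gaussian_smooth(pos, vals, sigma)
        assert out[0] == pytest.approx(expected0, abs=1e-12)


class TestFilter:
    def test_boundaries(self):
        # SNP0: qual 19.9 (fails); SNP1: MAF 0.04 (fails);
        # SNP2: MAF exactly 0.05 (passes); SNP3: 25% missing (fails)
        n = 20  # 40 alleles
        g_ok = np.ones(n, dtype=np.int8)  # MAF 0.5
        g_maf_low = np.zeros(n, dtype=np.int8)
        g_maf_low[0] = 1  # 1/40 = 0.025 < 0.05
        g_maf_edge = np.zeros(n, dtype=np.int8)
        g_maf_edge[0] = 2  # 2/40 = 0.05 exactly
        g_miss = np.ones(n, dtype=np.int8)
        g_miss[:5] = MISSING  # 25% missing
        geno = np.vstack([g_ok, g_maf_low, g_maf_edge, g_miss])
        vt = make_variants(geno, qual=[19.9, 40.0, 40.0, 40.0])
        out, report = filter_variants(vt)
        assert list(out.snps.index) == ["s2"]
        assert report["removed_quality"] == 1
        assert report["n_retained"] == 1

    def test_toy_table_counts(self):
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.5, size=(10, 30)).astype(np.int8)
        qual = np.full(10, 50.0)
        qual[[1, 4]] = 10.0                      # 2 quality violations
        geno[7] = 0
        geno[7, 0] = 1                           # 1 MAF violation (1/60)
        vt = make_variants(geno, qual=qual)
        out, report = filter_variants(vt)
        assert report["n_retained"] == 7
        assert {"s1", "s4", "s7"}.isdisjoint(out.snps.index)

    def test_empty_output_warns_not_raises(self, caplog):
        geno = np.zeros((2, 10), dtype=np.int8)
        vt = make_variants(geno)
        out, report = filter_variants(vt)
        assert report["n_retained"] == 0


class TestOutlierEnrichment:
    def _theta(self, rng, n_bg=500, n_set=100, shift=0.0):
        bg = pd.Series(rng.normal(0.02, 0.02, size=n_bg),
                       index=[f"b{i}" for i in range(n_bg)])
        focal = pd.Series(rng.normal(0.02 + shift, 0.02, size=n_set),
                          index=[f"f{i}" for i in range(n_set)])
        return pd.concat([bg, focal]), bg.index, focal.index

    def test_null_set_near_alpha(self):
        rng = np.random.default_rng(3)
        theta, bg_idx, focal_idx = self._theta(rng, n_set=500)
        rep = fst_outlier_enrichment(theta, focal_idx, bg_idx, alpha=0.05)
        assert abs(rep["outlier_proportion"] - 0.05) < 0.03
        assert rep["p"] > 0.01

    def test_extreme_set_proportion_one(self):
        rng = np.random.default_rng(4)
        theta, bg_idx, focal_idx = self._theta(rng, shift=1.0)
        rep = fst_outlier_enrichment(theta, focal_idx, bg_idx)
        assert rep["outlier_proportion"] == 1.0
        assert rep["p"] < 1e-10

    def test_background_minimum(self):
        theta = pd.Series(np.linspace(0, 1, 60))
        with pytest.raises(ValidationError):
            fst_outlier_enrichment(theta, theta.index[:10], theta.index[10:])


class TestMeanContrast:
    def test_identical_sets(self):
        theta = pd.Series(np.linspace(0, 0.2, 40))
        rep = mean_fst_contrast(theta, theta.index, theta.index)
        assert rep["t"] == pytest.approx(0.0)
        assert rep["p"] == pytest.approx(1.0)

    def test_welch_closed_form(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.05, 0.05, 0.2])
        rep = welch_t_test(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / 3 + vb / 3)
        t_expected = (a.mean() - b.mean()) / se
        df_expected = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert rep["t"] == pytest.approx(t_expected, abs=1e-12)
        assert rep["df"] == pytest.approx(df_expected, abs=1e-9)


class TestPairwiseLD:
    def test_duplicated_snp_r2_one(self):
        rng = np.random.default_rng(5)
        col = rng.binomial(2, 0.5, size=12).astype(np.int8)
        geno = np.vstack([col, col])
        vt = make_variants(geno, pos=[100, 200])
        pairs = pairwise_ld(vt)
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)
        assert pairs["distance_bp"].iloc[0] == 100

    def test_window_boundary_excludes_pair(self):
        rng = np.random.default_rng(6)
        geno = rng.binomial(2, 0.5, size=(2, 12)).astype(np.int8)
        vt = make_variants(geno, pos=[4999, 15001])
        pairs = pairwise_ld(vt, window_bp=10_000)
        assert pairs.empty

    def test_hand_computed_r2(self):
        gi = np.array([0, 0, 1, 1, 2, 2, 0, 1], dtype=np.int8)
        gj = np.array([0, 1, 1, 2, 2, 2, 0, 0], dtype=np.int8)
        vt = make_variants(np.vstack([gi, gj]), pos=[10, 20])
        pairs = pairwise_ld(vt)
        expected = np.corrcoef(gi.astype(float), gj.astype(float))[0, 1] ** 2
        assert pairs["r2"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_ref_alt_swap_invariance(self):
        rng = np.random.default_rng(7)
        geno = rng.binomial(2, 0.4, size=(2, 15)).astype(np.int8)
        vt = make_variants(geno, pos=[10, 20])
        swapped = geno.copy()
        swapped[0] = 2 - swapped[0]
        vt2 = make_variants(swapped, pos=[10, 20])
        r2a = pairwise_ld(vt)["r2"].iloc[0]
        r2b = pairwise_ld(vt2)["r2"].iloc[0]
        assert r2a == pytest.approx(r2b, abs=1e-12)

    def test_bin_convention(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.5, size=12).astype(np.int8)
        flip = rng.binomial(2, 0.5, size=12).astype(np.int8)
        vt = make_variants(np.vstack([base, flip, base]), pos=[1, 1000, 1001])
        pairs = pairwise_ld(vt).set_index(["snp_i", "snp_j"])
        assert pairs.loc[("s0", "s1"), "distance_bin"] == 0   # 999 bp
        assert pairs.loc[("s0", "s2"), "distance_bin"] == 1   # 1000 bp

    def test_monomorphic_pair_skipped(self):
        mono = np.ones(10, dtype=np.int8)
        poly = np.array([0, 1] * 5, dtype=np.int8)
        vt = make_variants(np.vstack([mono, poly]), pos=[10, 20])
        assert pairwise_ld(vt).empty


class TestLDComparison:
    def _pairs(self, rng, n_genes=30, elevate=0.0):
        rows = []
        for g in range(n_genes):
            label = ("candidate_maladaptive" if g < n_genes // 2
                     else "background")
            mean = 0.2 + (elevate if label != "background" else 0.0)
            for k in range(6):
                rows.append({"gene_id": f"g{g}", "set_label": label,
                             "distance_bin": k % 3,
                             "r2": float(np.clip(rng.normal(mean, 0.05), 0, 1))})
        return pd.DataFrame(rows)

    def test_relabeled_identical_distribution_not_significant(self):
        rng = np.random.default_rng(9)
        pairs = self._pairs(rng, elevate=0.0)
        rep = ld_set_comparison(pairs, n_perm=200, seed=1)
        assert rep["empirical_p"] > 0.05

    def test_planted_elevation_detected(self):
        rng = np.random.default_rng(10)
        pairs = self._pairs(rng, elevate=0.3)
        rep = ld_set_comparison(pairs, n_perm=200, seed=2)
        assert rep["empirical_p"] <= 0.05
        assert rep["mean_r2_candidate"] > rep["mean_r2_background"]

    def test_bin_profiles_present(self):
        rng = np.random.default_rng(11)
        rep = ld_set_comparison(self._pairs(rng), n_perm=20, seed=3)
        assert set(rep["bins_candidate"]) == {0, 1, 2}


class TestHWE:
    def test_exact_hwe_chi2_zero(self):
        res = hwe_chisquare(25, 50, 25)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # counts (30, 40, 30): p=0.5, expected (25, 50, 25) -> chi2 = 4
        res = hwe_chisquare(30, 40, 30)
        assert res["chi2"] == pytest.approx(4.0, abs=1e-12)

    def test_monomorphic_site(self):
        res = hwe_chisquare(20, 0, 0)
        assert res["chi2"] == 0.0 and res["p"] == 1.0

    def test_scan_and_identical_proportion_comparison(self):
        rng = np.random.default_rng(12)
        geno = rng.binomial(2, 0.5, size=(40, 30)).astype(np.int8)
        labels = ["candidate_maladaptive"] * 20 + ["background"] * 20
        vt = make_variants(geno, pos=np.arange(1, 41) * 10, set_label=labels)
        pops = {"popA": vt.sample_ids[:15], "popB": vt.sample_ids[15:]}
        table, comparison = hwe_scan(vt, pops)
        assert len(table) == 80
        counts = table[["n_hom_ref", "n_het", "n_hom_alt"]].sum(axis=1)
        assert (counts == 15).all()
        for rep in comparison.values():
            assert 0 <= rep["p"] <= 1


class TestTwoProportion:
    def test_matches_textbook_continuity_corrected_formula(self):
        count_a, n_a, count_b, n_b = 40, 100, 20, 100
        rep = two_proportion_test(count_a, n_a, count_b, n_b)
        p_pool = (count_a + count_b) / (n_a + n_b)
        num = (abs(count_a / n_a - count_b / n_b) - 0.5 * (1 / n_a + 1 / n_b)) ** 2
        den = p_pool * (1 - p_pool) * (1 / n_a + 1 / n_b)
        assert rep["chi2"] == pytest.approx(num / den, abs=1e-12)

    def test_equal_proportions_null(self):
        rep = two_proportion_test(30, 100, 30, 100)
        assert rep["chi2"] == pytest.approx(0.0)
        assert rep["p"] == pytest.approx(1.0)

    def test_matches_r_prop_test_values(self):
        # R: prop.test(c(40, 20), c(100, 100)) -> X-squared = 8.595238,
        #    p = 0.00337043; prop.test(c(30, 40), ...) -> 1.780220
        rep = two_proportion_test(40, 100, 20, 100)
        assert rep["chi2"] == pytest.approx(8.595238, abs=1e-6)
        assert rep["p"] == pytest.approx(0.00337043, rel=1e-4)
        rep2 = two_proportion_test(30, 100, 40, 100)
        assert rep2["chi2"] == pytest.approx(1.780220, abs=1e-6)


class TestAnnotationEnrichment:
    def test_equal_proportions_null(self):
        # both sets 40% noncoding exactly
        fclass = (["noncoding"] * 10 + ["synonymous"] * 15) * 2
        labels = ["candidate_adaptive"] * 25 + ["background"] * 25
        geno = np.ones((50, 10), dtype=np.int8)
        vt = make_variants(geno, pos=np.arange(1, 51), fclass=fclass,
                           set_label=labels)
        rep = annotation_class_enrichment(vt, "candidate_adaptive", "noncoding")
        assert rep["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert rep["p"] > 0.99

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(13)
        n = 400
        fclass = (list(rng.choice(["noncoding", "synonymous"], p=[0.7, 0.3], size=n))
                  + list(rng.choice(["noncoding", "synonymous"], p=[0.5, 0.5], size=n)))
        labels = ["candidate_maladaptive"] * n + ["background"] * n
        geno = np.ones((2 * n, 4), dtype=np.int8)
        vt = make_variants(geno, pos=np.arange(1, 2 * n + 1), fclass=fclass,
                           set_label=labels)
        rep = annotation_class_enrichment(vt, "candidate_maladaptive", "noncoding")
        assert rep["p"] < 0.001
        lo, hi = rep["ci95_focal"]
        assert lo <= rep["prop_focal"] <= hi
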
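"""Mixed-model association scan, kinship, thresholds, haplotypes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sita.assoc import (bonferroni_threshold, compare_haplotypes,
                        fit_null_lmm, haplotype_groups, impute_missing,
                        kinship, maf, maf_filter, pca_structure, scan_snps,
                        significant_hits)
from sita.simgen import GenotypePanel, PanelSimConfig, simulate_panel


def make_panel(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1),
        "id": [f"s{j}" for j in range(m)],
        "ref": ["A"] * m, "alt": ["T"] * m,
    })
    return GenotypePanel(dosages, [f"acc{i}" for i in range(n)], markers)


class TestMaf:
    def test_manual_allele_count(self):
        assert maf(np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 2.0])) == pytest.approx(0.15)

    def test_all_homozygous_alt_folds_to_zero(self):
        assert maf(np.full(10, 2.0)) == pytest.approx(0.0)

    def test_balanced_is_half(self):
        assert maf(np.array([0.0, 0, 2, 2])) == pytest.approx(0.5)

    def test_fold_invariance_under_allele_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.integers(0, 3, size=30).astype(float)
            assert maf(d) == pytest.approx(maf(2.0 - d), abs=1e-12)

    def test_missing_ignored(self):
        assert maf(np.array([0.0, np.nan, 1.0])) == pytest.approx(0.25)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            maf(np.array([np.nan, np.nan]))


class TestMafFilter:
    def test_exact_threshold_excluded(self):
        # 1 alt allele among 10 -> maf exactly 0.05: strict > excludes it
        col = np.zeros((10, 1))
        col[0, 0] = 1.0
        panel = make_panel(col)
        filtered, m = maf_filter(panel, 0.05)
        assert m == 0

    def test_zero_threshold_keeps_polymorphic(self):
        d = np.zeros((10, 3))
        d[0, 0] = 1.0          # polymorphic
        d[:, 2] = 2.0          # monomorphic alt
        filtered, m = maf_filter(make_panel(d), 0.0)
        assert list(filtered.markers["id"]) == ["s0"]

    def test_matches_per_snp_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(40, 50)).astype(float)
        d[rng.random(d.shape) < 0.05] = np.nan
        panel = make_panel(d)
        filtered, m = maf_filter(panel, 0.2)
        expected = [j for j in range(50)
                    if np.any(np.isfinite(d[:, j]))
                    and maf(d[:, j]) > 0.2]
        assert list(filtered.markers["id"]) == [f"s{j}" for j in expected]
        assert m == len(expected)


class TestImputeMissing:
    def test_complete_input_unchanged(self):
        d = np.array([[0.0, 2], [1, 1]])
        assert np.array_equal(impute_missing(make_panel(d)), d)

    def test_single_missing_gets_mean(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        assert impute_missing(make_panel(d))[2, 0] == pytest.approx(1.0)

    def test_column_means_preserved(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(30, 10)).astype(float)
        means = d.mean(axis=0)
        d2 = d.copy()
        d2[rng.random(d.shape) < 0.2] = np.nan
        # imputation restores each column's observed mean
        filled = impute_missing(make_panel(d2))
        obs_means = np.nanmean(d2, axis=0)
        assert np.allclose(filled.mean(axis=0), obs_means, atol=1e-12)


class TestKinship:
    def test_identical_accessions_equal_rows(self):
        rng = np.random.default_rng(3)
        row = rng.integers(0, 3, size=50).astype(float)
        d = np.vstack([row, row, rng.integers(0, 3, 50)])
        K = kinship(make_panel(d))
        assert np.allclose(K[0], K[1], atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(12, 60)).astype(float)
        perm = rng.permutation(12)
        K = kinship(make_panel(d))
        Kp = kinship(make_panel(d[perm]))
        assert np.allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)

    def test_psd_and_unit_diagonal(self):
        panel, _, _ = simulate_panel(PanelSimConfig(n_acc=100, n_snp=1000,
                                                    seed=5))
        K = kinship(panel)
        assert np.allclose(K, K.T)
        assert np.min(np.linalg.eigvalsh(K)) >= -1e-8
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.15)

    def test_within_subpop_exceeds_between(self):
        panel, _, truth = simulate_panel(
            PanelSimConfig(n_acc=100, n_snp=1000, fst=0.1, n_subpop=2,
                           seed=6))
        K = kinship(panel)
        sub = np.array(truth["subpop"])
        same = np.equal.outer(sub, sub) & ~np.eye(len(sub), dtype=bool)
        diff = ~np.equal.outer(sub, sub)
        assert K[same].mean() > K[diff].mean()

    def test_ibs_option(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(10, 40)).astype(float)
        K = kinship(make_panel(d), method="ibs")
        assert np.allclose(np.diag(K), 1.0)
        assert np.all((K >= 0.0) & (K <= 1.0))

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            kinship(make_panel(np.full((5, 3), 2.0)))


class TestPcaStructure:
    def test_orthonormal_scores(self):
        panel, _, _ = simulate_panel(PanelSimConfig(n_acc=60, n_snp=400,
                                                    seed=8))
        S = pca_structure(kinship(panel), 3)
        assert np.allclose(S.T @ S, np.eye(3), atol=1e-8)

    def test_pc1_separates_subpops(self):
        panel, _, truth = simulate_panel(
            PanelSimConfig(n_acc=200, n_snp=2000, fst=0.1, n_subpop=2,
                           seed=9))
        S = pca_structure(kinship(panel), 1)
        sub = np.array(truth["subpop"], dtype=float)
        r = np.corrcoef(S[:, 0], sub)[0, 1]
        assert abs(r) > 0.9

    def test_rank_limit(self):
        with pytest.raises(ValueError, match="rank"):
            pca_structure(np.ones((4, 4)), 3)  # rank-1 matrix


class TestNullLMM:
    def test_identity_kinship_pure_noise(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1.3, 200)
        fit = fit_null_lmm(y, np.eye(200))
        total = fit.sigma2_g + fit.sigma2_e
        assert total == pytest.approx(y.var(ddof=1), rel=0.10)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_null_lmm(np.full(50, 3.0), np.eye(50))

    def test_non_finite_phenotype_rejected(self):
        y = np.zeros(10)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_null_lmm(y, np.eye(10))

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=30)
        cov = np.ones((30, 2))  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            fit_null_lmm(y, np.eye(30), cov)

    def test_polygenic_recovery_median(self):
        """Median REML heritability over replicates near the truth 0.5."""
        h2s = []
        master = np.random.default_rng(12)
        for _ in range(9):
            panel, y, _ = simulate_panel(
                PanelSimConfig(n_acc=500, n_snp=2000, h2_snp=0.0,
                               h2_poly=0.5, seed=int(master.integers(2**31))))
            K = kinship(panel)
            fit = fit_null_lmm(y, K)
            h2s.append(fit.heritability)
        assert 0.35 <= float(np.median(h2s)) <= 0.65


class TestScan:
    def test_identity_kinship_matches_ols(self):
        """GLS with identity kinship reduces to ordinary regression."""
        panel, y, _ = simulate_panel(
            PanelSimConfig(n_acc=100, n_snp=200, h2_snp=0.1, h2_poly=0.0,
                           fst=0.0, n_subpop=1, seed=13))
        filtered, _ = maf_filter(panel, 0.0)
        null = fit_null_lmm(y, np.eye(100))
        res = scan_snps(filtered, y, null)
        G = filtered.dosages
        for j in range(G.shape[1]):
            sl = stats.linregress(G[:, j], y)
            assert res.table["beta"][j] == pytest.approx(sl.slope, abs=1e-8)
            assert res.table["se"][j] == pytest.approx(sl.stderr, abs=1e-8)
            assert res.table["p"][j] == pytest.approx(sl.pvalue, abs=1e-8)

    def test_permuted_phenotype_p_uniform(self):
        """Scan on a permuted phenotype yields ~Uniform(0,1) p-values."""
        panel, y, _ = simulate_panel(
            PanelSimConfig(n_acc=200, n_snp=2000, h2_snp=0.1, h2_poly=0.3,
                           seed=14))
        rng = np.random.default_rng(99)
        y_perm = rng.permutation(y)
        filtered, m = maf_filter(panel)
        K = kinship(filtered)
        null = fit_null_lmm(y_perm, K)
        res = scan_snps(filtered, y_perm, null)
        ks = stats.kstest(res.table["p"], "uniform").statistic
        # 1% critical value of the KS statistic ~ 1.63 / sqrt(m)
        assert ks < 1.63 / math.sqrt(m)

    def test_scan_determinism(self):
        panel, y, _ = simulate_panel(PanelSimConfig(n_acc=80, n_snp=300,
                                                    seed=15))
        filtered, _ = maf_filter(panel)
        K = kinship(filtered)
        a = scan_snps(filtered, y, fit_null_lmm(y, K))
        b = scan_snps(filtered, y, fit_null_lmm(y, K))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_dimension_mismatch(self):
        panel, y, _ = simulate_panel(PanelSimConfig(n_acc=30, n_snp=50,
                                                    seed=16))
        filtered, _ = maf_filter(panel)
        null = fit_null_lmm(y, np.eye(30))
        with pytest.raises(ValueError, match="mismatch"):
            scan_snps(filtered, y[:-1], null)


class TestBonferroni:
    def test_printed_panel_size(self):
        assert bonferroni_threshold(0.05, 1_753_576) == pytest.approx(
            7.5449, abs=1e-3)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == pytest.approx(1.3010, abs=1e-4)

    def test_alternative_alpha(self):
        assert bonferroni_threshold(0.1, 204_741) == pytest.approx(6.31, abs=0.005)

    def test_monotonicity(self):
        assert (bonferroni_threshold(0.05, 1000)
                > bonferroni_threshold(0.05, 100))
        assert (bonferroni_threshold(0.01, 100)
                > bonferroni_threshold(0.05, 100))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSignificantHits:
    def _result(self):
        panel, y, truth = simulate_panel(
            PanelSimConfig(n_acc=200, n_snp=500, h2_snp=0.3, h2_poly=0.1,
                           seed=17))
        filtered, _ = maf_filter(panel)
        K = kinship(filtered)
        return scan_snps(filtered, y, fit_null_lmm(y, K)), truth

    def test_empty_when_no_signal(self):
        panel, y, _ = simulate_panel(
            PanelSimConfig(n_acc=50, n_snp=100, h2_snp=0.0, h2_poly=0.0,
                           seed=18))
        filtered, _ = maf_filter(panel)
        res = scan_snps(filtered, y, fit_null_lmm(y, np.eye(50)))
        hits = significant_hits(res, threshold=300.0)
        assert len(hits) == 0

    def test_flag_invariant_and_order(self):
        res, _ = self._result()
        hits = significant_hits(res)
        assert (hits["neglog10p"] >= res.threshold).all()
        assert hits["p"].is_monotonic_increasing
        flagged = res.table[res.table["significant"]]
        assert set(hits["id"]) == set(flagged["id"])

    def test_planted_snp_in_hits(self):
        res, truth = self._result()
        hits = significant_hits(res)
        assert truth["causal_id"] in set(hits["id"])


class TestHaplotypes:
    def test_single_snp_two_groups(self):
        d = np.array([[0.0], [0], [2], [2], [2]])
        g = haplotype_groups(make_panel(d), ["s0"], min_size=1)
        assert len(g.group_sizes) == 2
        assert g.group_sizes == {"H1": 3, "H2": 2}

    def test_perfect_linkage_redundant(self):
        col = np.array([0.0, 0, 2, 2, 0, 2])
        d = np.column_stack([col, col, col])
        g3 = haplotype_groups(make_panel(d), ["s0", "s1", "s2"], min_size=1)
        g1 = haplotype_groups(make_panel(d[:, :1]), ["s0"], min_size=1)
        assert (g3.assignments == g1.assignments).all()

    def test_missing_calls_excluded(self):
        d = np.array([[0.0], [np.nan], [2], [0]])
        g = haplotype_groups(make_panel(d), ["s0"], min_size=1)
        assert "acc1" not in g.assignments.index

    def test_unknown_snp_id(self):
        with pytest.raises(KeyError):
            haplotype_groups(make_panel(np.zeros((3, 2))), ["nope"])

    def test_planted_blocks_recovered(self):
        """Two planted haplotype blocks come back with Rand index 1."""
        rng = np.random.default_rng(19)
        labels = rng.integers(0, 2, size=80)
        block = np.column_stack([labels * 2.0] * 3)  # 3 SNPs in perfect LD
        noise = rng.integers(0, 3, size=(80, 20)).astype(float)
        panel = make_panel(np.column_stack([block, noise]))
        g = haplotype_groups(panel, ["s0", "s1", "s2"], min_size=1)
        got = (g.assignments.loc[[f"acc{i}" for i in range(80)]] == "H1")
        agree = (got.to_numpy() == (labels == labels[got.argmax()]))
        assert agree.all() or (~agree).all()

    def test_identical_groups_zero_statistic(self):
        d = np.array([[0.0], [0], [2], [2]])
        g = haplotype_groups(make_panel(d), ["s0"], min_size=1)
        trait = pd.Series([1.0, 1.0, 1.0, 1.0],
                          index=[f"acc{i}" for i in range(4)])
        g = compare_haplotypes(trait, g)
        assert g.statistic == 0.0

    def test_null_calibration(self):
        """Same-distribution groups reject at ~nominal 5% rate."""
        rng = np.random.default_rng(20)
        d = np.repeat([[0.0], [2.0]], 25, axis=0)
        g = haplotype_groups(make_panel(d), ["s0"], min_size=2)
        n_sig = 0
        reps = 500
        for _ in range(reps):
            trait = pd.Series(rng.normal(size=50),
                              index=[f"acc{i}" for i in range(50)])
            n_sig += compare_haplotypes(trait, g).p_value < 0.05
        assert 0.03 <= n_sig / reps <= 0.07

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(21)
        d = np.repeat([[0.0], [2.0]], 50, axis=0)
        g = haplotype_groups(make_panel(d), ["s0"], min_size=2)
        trait = pd.Series(np.concatenate([rng.normal(0, 1, 50),
                                          rng.normal(2, 1, 50)]),
                          index=[f"acc{i}" for i in range(100)])
        assert compare_haplotypes(trait, g).p_value < 0.001

    def test_three_group_rank_test(self):
        d = np.array([[0.0], [0], [1], [1], [2], [2]])
        g = haplotype_groups(make_panel(d), ["s0"], min_size=1)
        trait = pd.Series([0.0, 0.1, 5.0, 5.1, 10.0, 10.1],
                          index=[f"acc{i}" for i in range(6)])
        g = compare_haplotypes(trait, g)
        assert len(g.group_means) == 3
        assert math.isfinite(g.p_value)
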
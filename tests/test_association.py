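"""Kinship, mixed-model scan correctness, thresholding, haplotype contrasts."""

import numpy as np
import pytest
from scipy import stats as sps

import germscan as gs
from germscan.association import SIGNIFICANCE_THRESHOLD


def _polygenic_trait(K, rng, sigma_g2=1.0, sigma_e2=1.0):
    n = K.shape[0]
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    return np.sqrt(sigma_g2) * (L @ rng.normal(size=n)) + np.sqrt(
        sigma_e2
    ) * rng.normal(size=n)


class TestKinship:
    def test_identical_rows_share_diagonal_value(self):
        dos = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 0, 1]])
        K = gs.kinship(dos)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert np.allclose(K, K.T)

    def test_psd_and_offdiag_mean_near_zero(self):
        cfg = gs.SimulationConfig(n_genotypes=2000, n_snps=400, n_causal=0, rng_seed=8)
        gm, _ = gs.simulate_genotypes(cfg)
        K = gs.kinship(gm)
        off = K[~np.eye(2000, dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert np.linalg.eigvalsh(K).min() > -1e-8
        assert K.diagonal().mean() > off.mean()

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            gs.kinship(np.ones((5, 3), dtype=int))


class TestScanEquivalence:
    def test_identity_kinship_reduces_to_ols(self, rng):
        import statsmodels.api as sm

        cfg = gs.SimulationConfig(n_genotypes=30, n_snps=20, n_causal=0, rng_seed=12)
        gm, _ = gs.simulate_genotypes(cfg)
        y = rng.normal(size=30)
        scan = gs.mlm_scan(y, gm, K=np.eye(30))
        for j in range(20):
            fit = sm.OLS(y, sm.add_constant(gm.dosage[:, j].astype(float))).fit()
            assert scan.loc[j, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)
            assert scan.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-8)

    def test_matches_dense_gls_oracle(self, rng):
        """Spectral P3D scan ≡ brute-force GLS refit per SNP at the null delta."""
        cfg = gs.SimulationConfig(n_genotypes=30, n_snps=20, n_causal=0, rng_seed=13)
        gm, _ = gs.simulate_genotypes(cfg)
        K = gs.kinship(gm)
        y = _polygenic_trait(K, rng)
        null = gs.fit_null(y, K)
        scan = gs.mlm_scan(y, gm, K=K, null=null)
        Vi = np.linalg.inv(K + null.delta * np.eye(30))
        for j in range(20):
            X = np.column_stack([np.ones(30), gm.dosage[:, j].astype(float)])
            A = X.T @ Vi @ X
            b = np.linalg.solve(A, X.T @ Vi @ y)
            res = y - X @ b
            s2 = (res @ Vi @ res) / (30 - 2)
            se = np.sqrt(s2 * np.linalg.inv(A)[1, 1])
            p = 2 * sps.t.sf(abs(b[1] / se), 28)
            assert scan.loc[j, "beta"] == pytest.approx(b[1], abs=1e-6)
            assert scan.loc[j, "p"] == pytest.approx(p, abs=1e-6)

    def test_per_snp_reml_consistent_with_p3d(self, rng):
        """With K=I the refit changes nothing; with real kinship the two
        variance strategies must agree on the ranking of SNPs."""
        cfg = gs.SimulationConfig(n_genotypes=40, n_snps=10, n_causal=0, rng_seed=14)
        gm, _ = gs.simulate_genotypes(cfg)
        y = rng.normal(size=40)
        fast_i = gs.mlm_scan(y, gm, K=np.eye(40))
        exact_i = gs.mlm_scan(y, gm, K=np.eye(40), per_snp_reml=True)
        np.testing.assert_allclose(fast_i["p"], exact_i["p"], atol=1e-8)

        K = gs.kinship(gm)
        yk = _polygenic_trait(K, rng)
        fast = gs.mlm_scan(yk, gm, K=K)
        exact = gs.mlm_scan(yk, gm, K=K, per_snp_reml=True)
        rho = sps.spearmanr(fast["p"], exact["p"]).statistic
        assert rho > 0.9

    def test_length_mismatch_rejected(self, rng, small_panel):
        gm, _ = small_panel
        with pytest.raises(ValueError):
            gs.mlm_scan(rng.normal(size=10), gm)


class TestSignificance:
    def test_threshold_is_inclusive(self):
        import pandas as pd

        scan = pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "chrom": [1, 1, 2], "pos": [30, 10, 5],
             "p": [1e-6, 1e-4, 1e-5],
             "neglog10p": [6.0, 4.0, 5.0]}
        )
        hits = gs.significant_snps(scan, threshold=SIGNIFICANCE_THRESHOLD)
        assert set(hits["snp_id"]) == {"a", "c"}  # 1e-5 exactly is kept
        # sorted by chromosome then position
        assert list(hits["snp_id"]) == ["a", "c"]
        # idempotent
        assert gs.significant_snps(hits).equals(hits)


class TestPVE:
    def test_null_effect_near_zero_and_monotone_in_beta(self, rng):
        n = 264
        g = rng.binomial(2, 0.3, size=n).astype(float)
        noise = rng.normal(size=n)
        pves = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            y = beta * g + noise
            scan = gs.mlm_scan(y, g[:, None], K=np.eye(n))
            pves.append(scan.loc[0, "pve"])
        assert pves[0] < 2.0
        assert pves == sorted(pves)

    def test_planted_ten_percent_snp_recovered(self, rng):
        """A SNP built to explain 10% of variance is estimated within ±4 points."""
        n = 264
        ests = []
        for _ in range(10):
            g = rng.binomial(2, 0.3, size=n).astype(float)
            vg = g.var()
            beta = np.sqrt(0.10 / 0.90 / vg)  # 10% of total variance
            y = beta * g + rng.normal(size=n)
            scan = gs.mlm_scan(y, g[:, None], K=np.eye(n))
            ests.append(scan.loc[0, "pve"])
        assert abs(np.mean(ests) - 10.0) < 4.0


class TestHaplotype:
    def test_separated_groups_get_three_stars(self, rng):
        dos = np.array([0] * 50 + [2] * 50)
        y = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(1, 0.1, 50)])
        eff = gs.haplotype_compare(dos, y, "A", "T", "S14_0000001")
        assert eff.p_value < 0.001 and eff.stars == "***"
        assert eff.group_sizes == (50, 50)
        assert eff.higher_allele == "T"

    def test_identical_groups_f_zero(self):
        dos = np.array([0, 0, 2, 2])
        y = np.array([1.0, 1.0, 1.0, 1.0])
        eff = gs.haplotype_compare(dos, y, "A", "C")
        assert eff.f_stat == pytest.approx(0.0) or np.isnan(eff.f_stat)
        assert eff.stars == ""

    def test_label_permutation_symmetry(self, rng):
        dos = np.array([0] * 30 + [2] * 30)
        y = rng.normal(size=60)
        a = gs.haplotype_compare(dos, y, "A", "T")
        b = gs.haplotype_compare(2 - dos, y, "T", "A")
        assert a.p_value == pytest.approx(b.p_value)

    def test_heterozygotes_excluded_and_small_groups_rejected(self, rng):
        dos = np.array([0, 0, 1, 1, 1, 2, 2])
        y = rng.normal(size=7)
        eff = gs.haplotype_compare(dos, y, "G", "T")
        assert sum(eff.group_sizes) == 4
        with pytest.raises(ValueError):
            gs.haplotype_compare(np.array([0, 2, 2]), np.zeros(3), "A", "T")
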
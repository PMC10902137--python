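"""Descriptive moments, balanced ANOVA vs an independent oracle, heritability."""

import numpy as np
import pandas as pd
import pytest

import germscan as gs


class TestDescribe:
    def test_constant_vector(self):
        s = gs.describe([5.0, 5.0, 5.0])
        assert s["sd"] == 0 and s["cv"] == 0 and s["range"] == 0

    def test_two_point_sample(self):
        s = gs.describe([0.0, 1.0])
        assert s["mean"] == 0.5
        assert s["sd"] == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert s["cv"] == pytest.approx(141.4214, abs=1e-3)

    def test_symmetric_sample_has_zero_skew(self):
        s = gs.describe([-2, -1, 0, 1, 2])
        assert s["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_spss_style_bias_adjustment(self):
        # adjusted Fisher–Pearson g1·sqrt(n(n-1))/(n-2), worked by hand for n=4
        x = np.array([1.0, 2.0, 3.0, 7.0])
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        g1 = m3 / m2**1.5
        expected = g1 * np.sqrt(4 * 3) / 2
        assert gs.describe(x)["skewness"] == pytest.approx(expected, abs=1e-12)

    def test_zero_mean_cv_missing(self):
        assert np.isnan(gs.describe([-1.0, 1.0])["cv"])


def _oracle_anova(df):
    """Independent route: statsmodels OLS + anova_lm."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    m = ols("value ~ C(genotype_id) * C(environment)", data=df).fit()
    return sm.stats.anova_lm(m, typ=1)


class TestAnova:
    @pytest.mark.parametrize("n_g,n_e,r", [(2, 2, 2), (3, 2, 3), (4, 3, 2)])
    def test_matches_statsmodels_oracle(self, n_g, n_e, r):
        df = gs.simulate_trait_layout(1.0, 0.5, 1.0, n_g, n_e, r, seed=n_g * 10 + r)
        ours = gs.anova_two_way(df)
        oracle = _oracle_anova(df)
        assert ours.loc["Genotype", "SS"] == pytest.approx(
            oracle.loc["C(genotype_id)", "sum_sq"], abs=1e-10
        )
        assert ours.loc["Environment", "SS"] == pytest.approx(
            oracle.loc["C(environment)", "sum_sq"], abs=1e-10
        )
        assert ours.loc["GxE", "SS"] == pytest.approx(
            oracle.loc["C(genotype_id):C(environment)", "sum_sq"], abs=1e-10
        )
        assert ours.loc["Residual", "SS"] == pytest.approx(
            oracle.loc["Residual", "sum_sq"], abs=1e-10
        )
        assert ours.loc["GxE", "P"] == pytest.approx(
            oracle.loc["C(genotype_id):C(environment)", "PR(>F)"], abs=1e-10
        )

    def test_all_equal_gives_zero_ss(self):
        df = gs.simulate_trait_layout(0, 0, 0, 3, 2, 2, seed=0, grand_mean=4.0)
        ours = gs.anova_two_way(df)
        assert ours.loc[["Genotype", "Environment", "GxE", "Residual"], "SS"].sum() \
            == pytest.approx(0.0, abs=1e-18)

    def test_pure_environment_shift(self):
        df = gs.simulate_trait_layout(0, 0, 0, 4, 2, 3, seed=0)
        df["value"] += (df["environment"] == "E2") * 2.0
        ours = gs.anova_two_way(df)
        assert ours.loc["Environment", "SS"] > 0
        assert ours.loc["Genotype", "SS"] == pytest.approx(0.0, abs=1e-18)
        assert ours.loc["GxE", "SS"] == pytest.approx(0.0, abs=1e-18)

    def test_ss_decomposition_is_exact(self):
        df = gs.simulate_trait_layout(1, 1, 1, 6, 3, 4, seed=2)
        ours = gs.anova_two_way(df)
        parts = ours.loc[["Genotype", "Environment", "GxE", "Residual"], "SS"].sum()
        assert parts == pytest.approx(ours.loc["Total", "SS"], rel=1e-12)

    def test_unbalanced_rejected(self):
        df = gs.simulate_trait_layout(1, 1, 1, 3, 2, 3, seed=1).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            gs.anova_two_way(df)

    def test_too_few_levels_rejected(self):
        df = gs.simulate_trait_layout(1, 1, 1, 3, 1, 3, seed=1)
        with pytest.raises(ValueError):
            gs.anova_two_way(df)


class TestVarianceComponents:
    def test_equal_mean_squares_give_zero_components(self):
        df = gs.simulate_trait_layout(0, 0, 1, 4, 2, 3, seed=3)
        an = gs.anova_two_way(df)
        # force equal MS to exercise the algebra exactly
        an.loc[["Genotype", "GxE", "Residual"], "MS"] = 1.0
        vc = gs.variance_components(an)
        assert vc.sigma_g2 == 0 and vc.sigma_ge2 == 0 and vc.sigma_e2 == 1.0

    def test_negative_estimates_clipped_with_warning(self):
        df = gs.simulate_trait_layout(0, 0, 1, 4, 2, 3, seed=4)
        an = gs.anova_two_way(df)
        an.loc["GxE", "MS"] = 0.1
        an.loc["Residual", "MS"] = 1.0
        an.loc["Genotype", "MS"] = 0.05
        with pytest.warns(UserWarning, match="clipped"):
            vc = gs.variance_components(an)
        assert vc.sigma_ge2 == 0.0 and vc.sigma_g2 == 0.0
        assert set(vc.clipped) == {"sigma_g2", "sigma_ge2"}

    def test_moment_estimator_inverts_expected_mean_squares(self):
        # EMS: MS_G = nr·σg² + r·σge² + σ²; MS_GxE = r·σge² + σ²; MS_res = σ²
        df = gs.simulate_trait_layout(1, 1, 1, 3, 2, 3, seed=5)
        an = gs.anova_two_way(df)
        sg, sge, se = 2.0, 0.5, 1.0
        n, r = 2, 3
        an.loc["Residual", "MS"] = se
        an.loc["GxE", "MS"] = r * sge + se
        an.loc["Genotype", "MS"] = n * r * sg + r * sge + se
        vc = gs.variance_components(an)
        assert (vc.sigma_g2, vc.sigma_ge2, vc.sigma_e2) == (sg, sge, se)


class TestHeritability:
    @pytest.mark.parametrize(
        "args,expected",
        [((1, 0, 0, 2, 3), 1.0), ((1, 1, 1, 2, 3), 0.6), ((0, 1, 1, 2, 3), 0.0)],
    )
    def test_worked_values(self, args, expected):
        assert gs.heritability(*args) == pytest.approx(expected)

    def test_monotonicity(self):
        base = gs.heritability(1, 1, 1, 2, 3)
        assert gs.heritability(2, 1, 1, 2, 3) > base
        assert gs.heritability(1, 2, 1, 2, 3) < base
        assert gs.heritability(1, 1, 2, 2, 3) < base

    def test_all_zero_is_nan(self):
        assert np.isnan(gs.heritability(0, 0, 0, 2, 3))

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            gs.heritability(-1, 0, 0, 2, 3)


class TestCorrelate:
    def test_identity_and_sign(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": -x, "c": x + rng.normal(0, 0.1, 50)})
        r, p = gs.correlate(df, ["a", "b", "c"])
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert r.loc["a", "c"] > 0.9
        assert p.loc["a", "c"] < 1e-10

    def test_construction_implied_correlation_recovered(self, rng):
        """Traits built with correlation 0.9 estimate within 0.05 at n=264."""
        rho = 0.9
        z = rng.normal(size=(264, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        r, _ = gs.correlate(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert abs(r.loc["x", "y"] - rho) < 0.05

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            gs.correlate(df, ["a", "b"])
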
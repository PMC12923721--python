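"""Shared statistical machinery: AICc protocol, classical tests, REML, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clutchkit import stats


class TestAicc:
    def test_hand_evaluation(self):
        # -2*(-5) + 2*2 + 2*2*3/(10-3) = 10 + 4 + 12/7
        assert stats.aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7, abs=1e-12)

    def test_exceeds_aic_and_converges_to_it(self):
        aic = -2 * (-5.0) + 2 * 2
        assert stats.aicc(-5.0, 2, 10) > aic
        assert stats.aicc(-5.0, 2, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError, match="n > k"):
            stats.aicc(-5.0, 3, 4)


class TestSelectionProtocol:
    def _score(self, label, k, aicc_val):
        return stats.ModelScore(label=label, k=k, loglik=0.0, aicc=aicc_val, n=50)

    def test_identical_models_tie_break_to_simpler_label(self):
        scores = [self._score("b", 2, 100.0), self._score("a", 2, 100.0)]
        best = stats.selection_protocol(scores)
        assert best.label == "a"
        assert all(s.competitive for s in scores)

    def test_simpler_model_wins_within_delta_two(self):
        scores = [self._score("full", 5, 100.0), self._score("base", 2, 101.5)]
        assert stats.selection_protocol(scores).label == "base"

    def test_uninformative_parameter_discards_competitive_model(self):
        scores = [self._score("extra", 3, 100.0), self._score("base", 2, 101.0)]
        best = stats.selection_protocol(
            scores, uninformative={"extra": ["frill"], "base": []}
        )
        assert best.label == "base"

    def test_protected_group_term_never_flagged(self):
        scores = [self._score("with_group", 3, 100.0)]
        best = stats.selection_protocol(
            scores, uninformative={"with_group": ["group"]}
        )
        assert best.label == "with_group"
        assert best.uninformative_params == []


class TestClassicalTests:
    def test_welch_equal_groups_is_null(self):
        res = stats.welch_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_scipy_on_raw_samples(self, rng):
        x = rng.normal(0, 1, 14)
        y = rng.normal(0.8, 1.6, 19)
        ours = stats.welch_t(x.mean(), x.std(ddof=1), len(x),
                             y.mean(), y.std(ddof=1), len(y))
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert ours.df == pytest.approx(ref.df, rel=1e-10)

    def test_chi2_identical_rows_zero(self):
        res = stats.chi2_2x2([[5, 15], [5, 15]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_chi2_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="zero margin"):
            stats.chi2_2x2([[0, 5], [0, 7]])

    def test_mann_whitney_symmetric_null(self, rng):
        x = rng.normal(0, 1, 30)
        res = stats.mann_whitney_u(x, x)
        assert res.p_value == pytest.approx(1.0, abs=0.02)

    def test_fisher_matches_enumeration_small_tables(self):
        # independent oracle: full hypergeometric enumeration at fixed margins
        def enumerate_p(a, b, c, d):
            r1, c1, n = a + b, a + c, a + b + c + d
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            ks = np.arange(lo, hi + 1)
            pmf = sps.hypergeom.pmf(ks, n, r1, c1)
            p_obs = sps.hypergeom.pmf(a, n, r1, c1)
            return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())

        for table in [(10, 0, 0, 10), (3, 7, 6, 4), (1, 12, 9, 2),
                      (0, 0, 5, 5), (8, 8, 8, 6), (2, 2, 2, 2)]:
            a, b, c, d = table
            ours = stats.fisher_exact([[a, b], [c, d]]).p_value
            assert ours == pytest.approx(enumerate_p(a, b, c, d), abs=1e-10)


class TestLmm:
    def test_zero_variance_truth_equals_ols(self, rng):
        n = 120
        df = pd.DataFrame({
            "x": rng.normal(0, 1, n),
            "g": np.repeat(np.arange(12), 10).astype(str),
        })
        eps = pd.Series(rng.normal(0, 0.5, n))
        # remove all between-group variation from the noise so the REML
        # estimate is pinned at the zero boundary and GLS collapses to OLS
        eps -= eps.groupby(df["g"].values).transform("mean")
        df["y"] = 1.0 + 2.0 * df["x"] + eps.values
        fit = stats.lmm_fit(df, "y ~ x", group="g")
        import statsmodels.formula.api as smf

        ols = smf.ols("y ~ x", df).fit()
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=1e-6)
        assert fit.boundary  # group variance pinned at ~0

    def test_balanced_anova_method_of_moments(self, rng):
        # balanced one-way layout: REML variance components equal the
        # classical ANOVA estimators sigma_e^2 = MSW, sigma_b^2 = (MSB-MSW)/n
        g, n = 30, 8
        b = rng.normal(0, 2.0, g)
        y = (b[:, None] + rng.normal(0, 1.0, (g, n))).ravel()
        df = pd.DataFrame({"y": y, "g": np.repeat(np.arange(g), n).astype(str)})
        gm = df.groupby("g")["y"].mean()
        msw = float(df.groupby("g")["y"].var(ddof=1).mean())
        msb = float(n * gm.var(ddof=1))
        fit = stats.lmm_fit(df, "y ~ 1", group="g")
        assert fit.resid_var == pytest.approx(msw, rel=1e-3)
        assert fit.vc["g"] == pytest.approx((msb - msw) / n, rel=1e-3)

    def test_wald_coverage_near_nominal(self):
        # 95% CI for a fixed effect should cover the truth ~95% of the time
        hits = 0
        reps = 120
        for r in range(reps):
            rg = np.random.default_rng(1000 + r)
            groups = np.repeat(np.arange(15), 6)
            x = rg.normal(0, 1, groups.size)
            y = 0.5 * x + rg.normal(0, 1.0, 15)[groups] + rg.normal(0, 1, groups.size)
            df = pd.DataFrame({"y": y, "x": x, "g": groups.astype(str)})
            fit = stats.lmm_fit(df, "y ~ x", group="g")
            lo, hi = fit.ci95.loc["x"]
            hits += lo <= 0.5 <= hi
        assert 0.88 <= hits / reps <= 1.0


class TestMonteCarloPower:
    def test_size_under_null(self):
        pw = stats.monte_carlo_power(0.2, 0.2, 80, 80, alpha=0.05, reps=8000,
                                     seed=3, correction=False)
        assert pw == pytest.approx(0.05, abs=0.02)

    def test_monotone_in_effect_size(self):
        powers = [
            stats.monte_carlo_power(0.05, p2, 80, 80, reps=4000, seed=5)
            for p2 in (0.10, 0.20, 0.35)
        ]
        assert powers == sorted(powers)

    def test_probability_validation(self):
        with pytest.raises(ValueError, match="probability"):
            stats.monte_carlo_power(1.2, 0.1, 50, 50, reps=2000, seed=1)
        with pytest.raises(ValueError, match="reps"):
            stats.monte_carlo_power(0.1, 0.2, 50, 50, reps=10, seed=1)

    def test_clustered_variant_reduces_to_egg_level_at_zero_icc(self):
        free = stats.monte_carlo_power(0.031, 0.103, 64, 66, reps=4000, seed=9)
        clustered = stats.monte_carlo_power(0.031, 0.103, 64, 66, reps=4000,
                                            seed=9, cluster_sizes=(4,), icc=0.0)
        assert clustered == pytest.approx(free, abs=0.035)

    def test_clustering_makes_chi2_anticonservative_under_null(self):
        # shared clutch outcomes violate the independence assumption, so
        # the egg-level chi-squared rejects the true null too often
        null = stats.monte_carlo_power(0.10, 0.10, 64, 66, reps=4000, seed=13,
                                       correction=False,
                                       cluster_sizes=(4,), icc=0.6)
        assert null > 0.08
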
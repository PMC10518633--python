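import numpy as np
import pandas as pd
import pytest
import scipy.stats

import gliaquant.stats as gstats
from gliaquant.stats import (
    correlate,
    fit_group_model,
    fold_change,
    pairwise_contrasts,
    tukey_transform,
)


def _nested_table(rng, groups, n_cases=6, n_obs=4, sigma_case=0.5,
                  sigma_obs=0.5, lognormal=True):
    rows = []
    for g, mu in groups.items():
        for c in range(n_cases):
            u = rng.normal(0.0, sigma_case)
            for _ in range(n_obs):
                v = mu + u + rng.normal(0.0, sigma_obs)
                rows.append({"y": np.exp(v) if lognormal else v,
                             "group": g, "case": f"{g}{c}"})
    return pd.DataFrame(rows)


class TestTukeyTransform:
    def test_preserves_observation_order(self, rng):
        x = rng.lognormal(0, 1, 50)
        tt = tukey_transform(x)
        assert np.array_equal(np.argsort(x), np.argsort(tt.values))

    def test_lognormal_sample_selects_low_lambda(self):
        x = np.random.default_rng(0).lognormal(0, 0.8, 500)
        assert tukey_transform(x).lambda_ <= 0.5

    def test_normal_positive_sample_keeps_lambda_near_one(self):
        x = np.random.default_rng(0).normal(50, 5, 500)
        assert 0.5 <= tukey_transform(x).lambda_ <= 2.0

    def test_nonpositive_values_shifted_into_domain(self, rng):
        x = rng.normal(0, 1, 100)  # contains negatives
        tt = tukey_transform(x)
        assert tt.shift == pytest.approx(1e-6 + abs(x.min()))
        assert np.isfinite(tt.values).all()

    def test_too_few_or_constant_values_rejected(self):
        with pytest.raises(ValueError, match="3 values"):
            tukey_transform([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            tukey_transform([2.0, 2.0, 2.0, 2.0])

    def test_transform_method_matches_fitted_values(self, rng):
        x = rng.lognormal(0, 1, 40)
        tt = tukey_transform(x)
        np.testing.assert_allclose(tt.transform(x), tt.values)


class TestFitGroupModel:
    def test_f_matches_one_way_anova_with_zero_case_variance(self):
        # case effects removed exactly: between-case variance is literally 0
        rng = np.random.default_rng(1)
        rows = []
        for g, mu in (("a", 0.0), ("b", 0.4)):
            for c in range(6):
                e = rng.normal(0, 1, 4)
                e -= e.mean()
                rows += [{"y": mu + v, "group": g, "case": f"{g}{c}"} for v in e]
        df = pd.DataFrame(rows)
        fit = fit_group_model(df, "y", ["group"], "case", transform=False)
        f_ref = scipy.stats.f_oneway(df.loc[df.group == "a", "y"],
                                     df.loc[df.group == "b", "y"]).statistic
        assert fit.anova.F.iloc[0] == pytest.approx(f_ref, rel=0.05)

    def test_ci_coverage_of_planted_effect(self):
        delta = 0.8
        covered = 0
        n_rep = 200
        for i in range(n_rep):
            rng = np.random.default_rng(3000 + i)
            df = _nested_table(rng, {"a": 0.0, "b": delta}, lognormal=False)
            fit = fit_group_model(df, "y", ["group"], "case", transform=False)
            con = pairwise_contrasts(fit, "group").iloc[0]
            tcrit = scipy.stats.t.ppf(0.975, con.df)
            lo, hi = con.estimate - tcrit * con.se, con.estimate + tcrit * con.se
            covered += lo <= (delta if con.level_a == "b" else -delta) <= hi
        assert 0.90 <= covered / n_rep <= 0.985

    def test_covariates_can_enter_as_fixed_effects(self, rng):
        df = _nested_table(rng, {"a": 0.0, "b": 0.5})
        df["age"] = rng.normal(70, 5, len(df))
        df["apoe4"] = rng.random(len(df)) < 0.4
        fit = fit_group_model(df, "y", ["group", "age", "apoe4"], "case")
        assert set(fit.anova.term) == {"group", "age", "apoe4"}
        assert ((fit.anova.p >= 0) & (fit.anova.p <= 1)).all()
        assert fit.transform is not None

    def test_missing_outcome_rejected(self, rng):
        df = _nested_table(rng, {"a": 0.0, "b": 0.5})
        df.loc[0, "y"] = np.nan
        with pytest.raises(ValueError, match="missing outcome"):
            fit_group_model(df, "y", ["group"], "case")

    def test_transform_recorded_in_result(self, rng):
        df = _nested_table(rng, {"a": 0.0, "b": 0.5})
        fit = fit_group_model(df, "y", ["group"], "case")
        assert fit.transform.lambda_ in gstats.LAMBDA_LADDER

    def test_log_selection_makes_fit_scale_invariant(self, rng):
        df = _nested_table(rng, {"a": 0.0, "b": 0.7}, sigma_case=0.3,
                           sigma_obs=0.8)
        fit1 = fit_group_model(df, "y", ["group"], "case")
        df2 = df.assign(y=df.y * 137.0)
        fit2 = fit_group_model(df2, "y", ["group"], "case")
        assert fit1.transform.lambda_ == fit2.transform.lambda_ == 0.0
        assert fit1.anova.F.iloc[0] == pytest.approx(fit2.anova.F.iloc[0],
                                                     rel=1e-6)


class TestPairwiseContrasts:
    def test_two_level_family_equals_unadjusted_p(self, rng):
        df = _nested_table(rng, {"a": 0.0, "b": 0.5})
        fit = fit_group_model(df, "y", ["group"], "case")
        con = pairwise_contrasts(fit, "group").iloc[0]
        p_t = 2 * scipy.stats.t.sf(abs(con.t), con.df)
        assert con.p_adj == pytest.approx(p_t, rel=1e-6)

    def test_exactly_equal_groups_give_large_adjusted_p(self, rng):
        # identical residuals in every group -> estimated differences exactly 0
        e = rng.normal(0, 1, 24)
        rows = []
        for g in ("a", "b", "c"):
            for c in range(6):
                for s in range(4):
                    rows.append({"y": 5.0 + e[c * 4 + s], "group": g,
                                 "case": f"{g}{c}"})
        fit = fit_group_model(pd.DataFrame(rows), "y", ["group"], "case",
                              transform=False)
        con = pairwise_contrasts(fit, "group")
        assert len(con) == 3
        assert (con.p_adj > 0.5).all()

    def test_unknown_factor_rejected(self, rng):
        df = _nested_table(rng, {"a": 0.0, "b": 0.5})
        fit = fit_group_model(df, "y", ["group"], "case")
        with pytest.raises(ValueError, match="unknown factor"):
            pairwise_contrasts(fit, "region")

    def test_single_level_factor_rejected(self, rng):
        df = _nested_table(rng, {"a": 0.0})
        df["region"] = "BA17"
        fit = fit_group_model(df, "y", ["group"], "case")
        with pytest.raises(ValueError, match=">= 2 levels"):
            pairwise_contrasts(fit, "region")


class TestFoldChange:
    def _table(self):
        rows = []
        for g, means in (("AD", [4.0, 4.2, 4.4]), ("ctrl", [1.9, 2.0, 2.1])):
            for c, m in enumerate(means):
                for obs in (m - 0.1, m, m + 0.1):
                    rows.append({"value": obs, "group": g, "case_id": f"{g}{c}"})
        return pd.DataFrame(rows)

    def test_worked_ratio(self):
        ratio, (lo, hi) = fold_change(self._table(), "AD", "ctrl", seed=1)
        assert ratio == pytest.approx(4.2 / 2.0)
        assert lo <= ratio <= hi

    def test_identical_groups_give_unity(self):
        df = self._table()
        df.loc[df.group == "AD", "value"] = df.loc[df.group == "ctrl",
                                                   "value"].to_numpy()
        assert fold_change(df, "AD", "ctrl", seed=1)[0] == pytest.approx(1.0)

    def test_bootstrap_reproducible_with_seed(self):
        r1 = fold_change(self._table(), "AD", "ctrl", seed=7)
        r2 = fold_change(self._table(), "AD", "ctrl", seed=7)
        assert r1 == r2

    def test_pseudoreplication_invariance(self):
        df = self._table()
        dup = pd.concat([df, df, df], ignore_index=True)
        assert fold_change(dup, "AD", "ctrl", seed=1)[0] == pytest.approx(
            fold_change(df, "AD", "ctrl", seed=1)[0])

    def test_zero_denominator_rejected(self):
        df = self._table()
        df.loc[df.group == "ctrl", "value"] = 0.0
        with pytest.raises(ValueError, match="reference group"):
            fold_change(df, "AD", "ctrl", seed=1)


class TestCorrelate:
    def test_perfect_decreasing_monotone_is_minus_one(self):
        x = np.arange(10.0)
        y = -np.exp(x)  # monotone decreasing, nonlinear
        r, _ = correlate(x, y, method="rank")
        assert r == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(4)
        r, _ = correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_linear_method_is_pearson(self, rng):
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        r, _ = correlate(x, y, method="linear")
        assert r == pytest.approx(scipy.stats.pearsonr(x, y)[0])

    def test_constant_or_short_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="at least 3"):
            correlate([1, 2], [3, 4])
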
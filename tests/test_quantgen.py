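"""RCBD ANOVA, Tukey letters, variance components and genetic parameters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saltspec import quantgen, simulate
from saltspec.exceptions import BalanceError, ConfigurationError, SaltspecError


def toy_table(g, y, r, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, j, k in itertools.product(range(g), range(y), range(r)):
        rows.append({"genotype": f"G{i}", "season": f"S{j}", "replicate": k + 1,
                     "y": rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestAnovaSingleSeason:
    def test_trial_layout_degrees_of_freedom(self, trait_panel):
        table, _ = trait_panel
        anova = quantgen.anova_single_season(table, "PDW", season="S1")
        assert anova["df"].tolist() == [2, 23, 46]

    def test_constant_response_has_zero_ss_and_missing_f(self):
        table = toy_table(4, 1, 3)
        table["y"] = 7.0
        anova = quantgen.anova_single_season(table, "y")
        assert anova["sum_sq"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(anova["F"]).all()

    def test_matches_brute_force_cell_mean_decomposition(self):
        table = toy_table(3, 1, 2, seed=5)
        anova = quantgen.anova_single_season(table, "y")
        y = table["y"].to_numpy()
        grand = y.mean()
        gm = table.groupby("genotype")["y"].mean()
        rm = table.groupby("replicate")["y"].mean()
        assert anova.loc["genotype", "sum_sq"] == pytest.approx(
            2 * ((gm - grand) ** 2).sum())
        assert anova.loc["replication", "sum_sq"] == pytest.approx(
            3 * ((rm - grand) ** 2).sum())
        assert anova["sum_sq"].sum() == pytest.approx(((y - grand) ** 2).sum())

    def test_missing_cell_raises_balance_error(self):
        table = toy_table(3, 1, 2).iloc[1:]
        with pytest.raises(BalanceError):
            quantgen.anova_single_season(table, "y")


class TestAnovaCombined:
    def test_trial_layout_degrees_of_freedom(self, trait_panel):
        table, _ = trait_panel
        anova = quantgen.anova_combined(table, "PDW")
        assert anova["df"].tolist() == [1, 4, 23, 23, 92]

    def test_matches_brute_force_partition(self):
        table = toy_table(3, 2, 3, seed=8)
        anova = quantgen.anova_combined(table, "y")
        y = table["y"].to_numpy()
        grand = y.mean()
        sm = table.groupby("season")["y"].mean()
        gm = table.groupby("genotype")["y"].mean()
        sgm = table.groupby(["season", "genotype"])["y"].mean()
        srm = table.groupby(["season", "replicate"])["y"].mean()
        ss_s = 9 * ((sm - grand) ** 2).sum()
        ss_g = 6 * ((gm - grand) ** 2).sum()
        ss_sg = 3 * sum(
            (sgm[s, g] - sm[s] - gm[g] + grand) ** 2
            for s, g in sgm.index)
        ss_rs = 3 * sum((srm[s, r] - sm[s]) ** 2 for s, r in srm.index)
        assert anova.loc["season", "sum_sq"] == pytest.approx(ss_s)
        assert anova.loc["genotype", "sum_sq"] == pytest.approx(ss_g)
        assert anova.loc["season_x_genotype", "sum_sq"] == pytest.approx(ss_sg)
        assert anova.loc["rep_within_season", "sum_sq"] == pytest.approx(ss_rs)
        assert anova["sum_sq"].sum() == pytest.approx(((y - grand) ** 2).sum())

    def test_matches_statsmodels_anova_lm(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm
        table = toy_table(5, 2, 3, seed=13)
        ours = quantgen.anova_combined(table, "y")
        fit = ols("y ~ C(season) + C(season):C(replicate) + C(genotype)"
                  " + C(season):C(genotype)", data=table).fit()
        ref = anova_lm(fit, typ=1)
        mapping = {
            "season": "C(season)", "rep_within_season": "C(season):C(replicate)",
            "genotype": "C(genotype)", "season_x_genotype": "C(season):C(genotype)",
            "error": "Residual",
        }
        for term, ref_term in mapping.items():
            assert ours.loc[term, "sum_sq"] == pytest.approx(
                ref.loc[ref_term, "sum_sq"], rel=1e-9)
            assert ours.loc[term, "df"] == ref.loc[ref_term, "df"]

    def test_duplicated_season_zeroes_season_strata(self):
        one = toy_table(4, 1, 3, seed=2)
        two = one.copy()
        two["season"] = "S2"
        table = pd.concat([one, two], ignore_index=True)
        anova = quantgen.anova_combined(table, "y")
        assert anova.loc["season", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert anova.loc["season_x_genotype", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_single_season_redirects(self):
        table = toy_table(3, 1, 3)
        with pytest.raises(SaltspecError, match="single_season"):
            quantgen.anova_combined(table, "y")

    def test_ss_and_df_additivity_on_random_trials(self):
        for seed in range(10):
            table = toy_table(6, 2, 3, seed=seed)
            anova = quantgen.anova_combined(table, "y")
            y = table["y"].to_numpy()
            total = ((y - y.mean()) ** 2).sum()
            assert anova["sum_sq"].sum() == pytest.approx(total, rel=1e-9)
            assert anova["df"].sum() == len(table) - 1


class TestTukeyLetters:
    def test_all_equal_means_share_one_letter(self):
        means = pd.Series([5.0, 5.0, 5.0], index=list("ABC"))
        letters = quantgen.tukey_letters(means, 1.0, 10, 3)
        assert set(letters) == {"a"}

    def test_two_distant_means_get_distinct_letters(self):
        means = pd.Series([10.0, 0.0], index=list("AB"))
        letters = quantgen.tukey_letters(means, 0.01, 10, 3)
        assert letters["A"] == "a" and letters["B"] == "b"

    def test_letters_agree_with_pairwise_hsd_oracle(self):
        means = pd.Series([10.0, 9.2, 8.6, 5.0, 4.8], index=list("ABCDE"))
        ms_error, df_error, n, alpha = 1.0, 20, 4, 0.05
        letters = quantgen.tukey_letters(means, ms_error, df_error, n, alpha)
        hsd = stats.studentized_range.ppf(1 - alpha, len(means), df_error) \
            * np.sqrt(ms_error / n)
        for a, b in itertools.combinations(means.index, 2):
            share = bool(set(letters[a]) & set(letters[b]))
            not_significant = abs(means[a] - means[b]) <= hsd
            assert share == not_significant, (a, b)

    def test_zero_group_size_rejected(self):
        with pytest.raises(ConfigurationError):
            quantgen.tukey_letters(pd.Series([1.0, 2.0]), 1.0, 5, 0)


class TestVarianceComponents:
    def _frame(self, ms_g, ms_gs, ms_e, g=24, r=3, y=2):
        dfs = [y - 1, y * (r - 1), g - 1, (y - 1) * (g - 1),
               g * y * r - 1 - (y - 1) - y * (r - 1) - (g - 1) - (y - 1) * (g - 1)]
        frame = pd.DataFrame(
            {"df": dfs,
             "mean_sq": [1.0, 1.0, ms_g, ms_gs, ms_e]},
            index=["season", "rep_within_season", "genotype",
                   "season_x_genotype", "error"])
        frame["sum_sq"] = frame["df"] * frame["mean_sq"]
        frame.attrs.update(n_genotypes=g, n_reps=r, n_seasons=y)
        return frame

    def test_no_genetic_signal(self):
        vc = quantgen.variance_components(self._frame(0.5, 0.5, 0.5))
        assert vc.var_g == 0.0 and vc.var_gy == 0.0
        assert vc.var_p == pytest.approx(0.5 / 6)

    def test_published_trial_mean_squares_hand_arithmetic(self):
        # combined-season mean squares of the dry-weight trait
        vc = quantgen.variance_components(self._frame(1.9068, 0.0426, 0.0963))
        assert vc.var_g == pytest.approx(0.31070, abs=5e-6)
        assert vc.var_gy == 0.0 and "var_gy" in vc.truncated
        assert vc.var_e == pytest.approx(0.0963)

    def test_estimates_unbiased_over_simulated_trials(self, design):
        specs = {"PDW": simulate.TraitSpec(5.0, 0.30, 0.10, 0.25)}
        est_g, est_gy, est_e = [], [], []
        for seed in range(120):
            table, _ = simulate.simulate_trait_panel(design, specs, seed=seed)
            anova = quantgen.anova_combined(table, "PDW")
            vc = quantgen.variance_components(anova)
            est_g.append(vc.var_g)
            est_gy.append(vc.var_gy)
            est_e.append(vc.var_e)
        assert np.mean(est_g) == pytest.approx(0.30, abs=0.04)
        assert np.mean(est_gy) == pytest.approx(0.10, abs=0.03)
        assert np.mean(est_e) == pytest.approx(0.25, abs=0.02)

    def test_heritability_limits_and_hand_value(self):
        vc = quantgen.VarianceComponents(0.4, 0.0, 0.0, 3, 2)
        assert quantgen.heritability(vc) == 1.0
        vc = quantgen.VarianceComponents(0.0, 0.1, 0.2, 3, 2)
        assert quantgen.heritability(vc) == 0.0
        vc = quantgen.VarianceComponents(0.3107, 0.0, 0.0963, 3, 2)
        assert quantgen.heritability(vc) == pytest.approx(0.9509, abs=5e-5)


class TestGeneticParameters:
    def test_coefficient_of_variation(self):
        assert quantgen.coefficient_of_variation(25.0, 100.0) == 5.0
        assert quantgen.coefficient_of_variation(0.0, 10.0) == 0.0
        # negative-mean variables inherit the sign of the mean
        assert quantgen.coefficient_of_variation(25.0, -100.0) == -5.0
        with pytest.raises(SaltspecError):
            quantgen.coefficient_of_variation(1.0, 0.0)

    def test_selection_intensity_values(self):
        assert round(quantgen.selection_intensity(0.05), 2) == 2.06
        assert quantgen.selection_intensity(0.5) == pytest.approx(0.7979, abs=5e-5)
        assert quantgen.selection_intensity(0.999) == pytest.approx(0.0, abs=5e-3)
        with pytest.raises(ConfigurationError):
            quantgen.selection_intensity(1.5)

    def test_genetic_gain_zero_heritability(self):
        ga, gg = quantgen.genetic_gain(0.0, sigma_p=2.0, mean=10.0, k=2.06)
        assert ga == 0.0 and gg == 0.0

    def test_gcv_bounded_by_pcv(self, trait_panel):
        table, _ = trait_panel
        params = quantgen.genetic_parameter_table(table, list(simulate.TRAITS))
        assert (params["GCV"].abs() <= params["PCV"].abs() + 1e-12).all()

    def test_h2_equals_cv_ratio_squared(self, trait_panel):
        table, _ = trait_panel
        params = quantgen.genetic_parameter_table(table, list(simulate.TRAITS))
        ratio_sq = (params["GCV"] / params["PCV"]) ** 2
        np.testing.assert_allclose(params["h2_pct"] / 100.0, ratio_sq, atol=1e-9)

    def test_constant_variable_gives_zero_parameters(self, trait_panel):
        table, _ = trait_panel
        table = table.copy()
        table["flat"] = 3.0
        params = quantgen.genetic_parameter_table(table, ["flat"])
        row = params.loc["flat"]
        assert row[["h2_pct", "GCV", "PCV", "GA", "GG"]].to_numpy() \
            == pytest.approx(0.0)

    def test_results_object_summary(self, trait_panel):
        table, _ = trait_panel
        res = quantgen.RCBDModel(table, "GY").fit()
        text = res.summary()
        assert "h2=" in text and "genotype" in text
        assert 0.0 <= res.h2 <= 1.0
        assert set(res.tukey.index) == set(table["genotype"].unique())
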
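"""Regression suite: the OLS ladder against a normal-equations oracle,
VIF closed forms, Spearman rho, and the descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

import ranknorms as rn


def normal_equations_ols(y, X):
    """Independent OLS oracle: solve (X'X) b = X'y directly."""
    exog = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(exog.T @ exog, exog.T @ y)


@pytest.fixture()
def random_frame():
    rng = np.random.default_rng(10)
    n = 300
    df = pd.DataFrame(
        {
            "brac": rng.normal(50, 30, n),
            "rank": rng.uniform(0, 1, n),
            "group_mean_distance": rng.normal(0, 25, n),
            "duration": rng.gamma(2, 2.5, n),
            "after_11pm": rng.integers(0, 2, n).astype(float),
            "male": rng.integers(0, 2, n).astype(float),
            "fast": rng.integers(0, 17, n).astype(float),
            "age": rng.normal(26, 9, n),
        }
    )
    df["judge_drunk"] = (
        1.0 + 3.0 * df["rank"] + 0.02 * df["brac"] + rng.normal(0, 1.5, n)
    )
    return df


class TestFitModel:
    def test_matches_normal_equations_oracle(self, random_frame):
        for mid in (1, 2, 3, 4):
            spec = rn.ModelSpec(mid, "judge_drunk")
            fit = rn.fit_model(random_frame, spec)
            expect = normal_equations_ols(
                random_frame["judge_drunk"].to_numpy(),
                random_frame[list(spec.predictors)].to_numpy(),
            )
            np.testing.assert_allclose(fit.coef.to_numpy(), expect, atol=1e-8)

    def test_exact_affine_outcome_model2(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"rank": rng.uniform(0, 1, 100)})
        df["judge_drunk"] = 2.5 + 4.0 * df["rank"]
        fit = rn.fit_model(df, rn.ModelSpec(2, "judge_drunk"))
        assert fit.coef["rank"] == pytest.approx(4.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_outcome_zero_slopes(self, random_frame):
        df = random_frame.assign(judge_drunk=3.0)
        fit = rn.fit_model(df, rn.ModelSpec(3, "judge_drunk"))
        assert (fit.coef.drop("const") == 0).all()
        assert fit.r_squared == 0.0
        assert fit.coef["const"] == 3.0

    def test_beta_of_simple_regression_is_pearson_r(self, random_frame):
        fit = rn.fit_model(random_frame, rn.ModelSpec(2, "judge_drunk"))
        r = np.corrcoef(random_frame["rank"], random_frame["judge_drunk"])[0, 1]
        assert fit.params.loc["rank", "beta"] == pytest.approx(r, abs=1e-10)
        # and the simple-regression R2 is r^2
        assert fit.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_r2_never_decreases_along_ladder_nesting(self, random_frame):
        """Model 3 nests Model 1, Model 4 nests Model 3: R2 is monotone."""
        r2 = {m: rn.fit_model(random_frame, rn.ModelSpec(m, "judge_drunk")).r_squared
              for m in (1, 3, 4)}
        assert r2[1] <= r2[3] + 1e-12
        assert r2[3] <= r2[4] + 1e-12

    def test_ci_brackets_coefficient(self, random_frame):
        fit = rn.fit_model(random_frame, rn.ModelSpec(4, "judge_drunk"))
        assert (fit.params["ci_low"] <= fit.params["b"] + 1e-12).all()
        assert (fit.params["b"] <= fit.params["ci_high"] + 1e-12).all()
        assert (fit.vif >= 1 - 1e-12).all()

    def test_listwise_deletion(self, random_frame):
        df = random_frame.copy()
        df.loc[df.index[:25], "fast"] = np.nan
        fit = rn.fit_model(df, rn.ModelSpec(4, "judge_drunk"))
        assert fit.n_used == len(df) - 25
        # Model 2 does not use fast, so it keeps every row
        assert rn.fit_model(df, rn.ModelSpec(2, "judge_drunk")).n_used == len(df)

    def test_singular_design_raises_naming_columns(self, random_frame):
        df = random_frame.copy()
        df["group_mean_distance"] = 2.0 * df["brac"]  # exact collinearity
        with pytest.raises(rn.SingularDesignError, match="brac|group_mean_distance"):
            rn.fit_model(df, rn.ModelSpec(3, "judge_drunk"))

    def test_too_few_rows_rejected(self, random_frame):
        with pytest.raises(ValueError, match="complete rows"):
            rn.fit_model(random_frame.head(8), rn.ModelSpec(4, "judge_drunk"))


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)})
        vif = rn.compute_vif(X)
        assert vif["a"] == pytest.approx(1.0, abs=1e-10)
        assert vif["b"] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("r", [0.3, 0.9, -0.7])
    def test_bivariate_closed_form(self, r):
        """Two predictors with correlation r: VIF = 1/(1 - r^2) for both
        (r = 0.9 -> 5.263...)."""
        rng = np.random.default_rng(5)
        z1, z2 = rng.normal(size=(2, 200_000))
        x = z1
        y = r * z1 + np.sqrt(1 - r**2) * z2
        vif = rn.compute_vif(pd.DataFrame({"x": x, "y": y}))
        emp_r = np.corrcoef(x, y)[0, 1]
        expect = 1.0 / (1.0 - emp_r**2)
        assert vif["x"] == pytest.approx(expect, rel=1e-9)
        assert vif["y"] == pytest.approx(expect, rel=1e-9)

    def test_near_collinear_triple_matches_statsmodels(self):
        """One predictor is the sum of the others plus small noise: all VIFs
        large and equal to statsmodels' auxiliary-regression diagnostics."""
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        c = a + b + rng.normal(0, 0.05, 500)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        vif = rn.compute_vif(X)
        assert (vif > 50).all()
        exog = sm.add_constant(X.to_numpy())
        for j, col in enumerate(X.columns):
            assert vif[col] == pytest.approx(
                variance_inflation_factor(exog, j + 1), rel=1e-6
            )

    def test_perfect_collinearity_reports_inf(self):
        x = np.arange(100, dtype=float)
        vif = rn.compute_vif(pd.DataFrame({"x": x, "y": 3 * x + 1}))
        assert np.isinf(vif["x"]) and np.isinf(vif["y"])

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            rn.compute_vif(pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)}))


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(20.0)
        assert rn.spearman_rho(x, np.exp(x / 5)) == pytest.approx(1.0)
        assert rn.spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_single_adjacent_swap(self):
        # d^2 sums to 2: rho = 1 - 6*2/(5*24) = 0.9
        assert rn.spearman_rho([1, 2, 3, 4, 5], [1, 2, 3, 5, 4]) == pytest.approx(0.9)

    def test_constant_input_undefined(self):
        assert np.isnan(rn.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rn.spearman_rho([1, 2], [1, 2])
        with pytest.raises(ValueError):
            rn.spearman_rho([1, 2, 3], [1, 2])


class TestDescriptives:
    def test_pooled_t_from_summary_gender_contrast(self):
        """The study-scale gender contrast: means 52.3/43.0, SDs 30.0/27.8,
        n 1177/685 give t close to 6.64."""
        t, df = rn.pooled_t_from_summary(52.3, 30.0, 1177, 43.0, 27.8, 685)
        assert df == 1860
        assert t == pytest.approx(6.64, abs=0.1)

    def test_identical_groups_t_zero(self):
        # both genders carry the identical BrAC multiset 1..10 twice over
        pool = pd.DataFrame(
            {
                "id": [str(i) for i in range(40)],
                "brac_ug_per_100ml": np.tile(np.arange(1.0, 11.0), 4),
                "gender": ["M"] * 20 + ["F"] * 20,
                "location": [1, 2] * 20,
            }
        )
        for col in rn.RATING_COLUMNS:
            pool[col] = 5.0
        pool["session_duration_h"] = 5.0
        pool["survey_after_23h"] = 1
        pool["fast_score"] = 6
        pool["age_years"] = 25.0
        desc = rn.descriptives(pool, pool)
        assert desc["gender_t"]["t"] == pytest.approx(0.0, abs=1e-12)

    def test_null_location_anova_f_near_one(self):
        """With equal location means/variances the ANOVA F statistic averages
        ~1 across simulations (null F distribution has mean df2/(df2-2))."""
        rng = np.random.default_rng(11)
        fs = []
        for _ in range(200):
            groups = [rng.normal(50, 30, 100) for _ in range(4)]
            from scipy.stats import f_oneway

            fs.append(f_oneway(*groups)[0])
        assert 0.8 < np.mean(fs) < 1.25

    def test_subsample_table_layout(self, pool, judgements):
        desc = rn.descriptives(pool, judgements)
        t1 = desc["table1"]
        assert list(t1["variable"])[:4] == [
            "Perceived drunkenness", "Extreme drinking",
            "Long-term health", "Liver cirrhosis",
        ]
        assert len(t1) == 10
        # proportions carry no SD
        prop_rows = t1[t1["variable"].str.startswith("Proportion")]
        assert prop_rows["sd"].isna().all()
        assert desc["location_anova"]["df_between"] == 3
        assert desc["location_anova"]["p"] < 0.001  # location offsets are real
        assert desc["gender_t"]["t"] > 0  # men drink more in this cohort
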
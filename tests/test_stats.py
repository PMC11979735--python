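import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from arcticphen import stats


def grouped_data(rng, n_groups=12, per_group=8, slope=0.0, group_sd=0.0, resid_sd=1.0):
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, group_sd)
        x = rng.normal(0, 1, per_group)
        y = 10 + slope * x + u + rng.normal(0, resid_sd, per_group)
        for xi, yi in zip(x, y):
            rows.append({"individual_id": f"g{g}", "year": 2000 + g % 4, "x": xi, "y": yi})
    return pd.DataFrame(rows)


class TestAicc:
    def test_hand_computed_example(self):
        # -2(-10) + 2*2 + 2*2*3/7 = 24 + 12/7
        assert stats.aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert stats.aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_penalty_monotone_in_k(self):
        assert stats.aicc(-10.0, 3, 50) > stats.aicc(-10.0, 2, 50)

    def test_small_n_rejected(self):
        with pytest.raises(stats.StatsError):
            stats.aicc(-10.0, 9, 10)

    @settings(deadline=None, max_examples=1000)
    @given(
        llf=st.floats(-1e4, 1e4),
        k=st.integers(1, 20),
        n=st.integers(2, 10000),
    )
    def test_matches_textbook_formula(self, llf, k, n):
        if n <= k + 1:
            return
        textbook = -2 * llf + 2 * k * n / (n - k - 1)  # algebraically identical form
        assert stats.aicc(llf, k, n) == pytest.approx(textbook, abs=1e-9, rel=1e-12)


class TestFitLmm:
    def test_zero_group_variance_matches_ols(self, rng):
        df = grouped_data(rng, slope=2.0, group_sd=0.0)
        # balance the design: demeaning x and the residual within groups puts
        # the group variance on its zero boundary and makes the GLS and OLS
        # estimators coincide exactly
        df["x"] = df["x"] - df.groupby("individual_id")["x"].transform("mean")
        resid = df["y"] - 10 - 2.0 * df["x"]
        df["y"] = 10 + 2.0 * df["x"] + resid - resid.groupby(df["individual_id"]).transform("mean")
        lmm = stats.fit_lmm(df, "y", ("x",), random=("individual_id",))
        import statsmodels.formula.api as smf

        ols = smf.ols("y ~ x", data=df).fit()
        assert lmm.params["x"] == pytest.approx(ols.params["x"], abs=1e-6)
        assert lmm.params["Intercept"] == pytest.approx(ols.params["Intercept"], abs=1e-6)

    def test_intercept_only_balanced_gives_grand_mean(self, rng):
        df = grouped_data(rng, n_groups=2, per_group=20)
        lmm = stats.fit_lmm(df, "y", (), random=("individual_id",))
        assert lmm.params["Intercept"] == pytest.approx(df["y"].mean(), abs=1e-4)

    def test_crossed_random_intercepts_recover_variances(self, rng):
        rows = []
        u = {f"i{i}": rng.normal(0, 3.0) for i in range(25)}
        v = {y: rng.normal(0, 2.0) for y in range(2008, 2020)}
        for i in u:
            for y in v:
                rows.append(
                    {"individual_id": i, "year": y, "y": u[i] + v[y] + rng.normal(0, 1.0)}
                )
        df = pd.DataFrame(rows)
        fit = stats.fit_lmm(df, "y", (), random=("individual_id", "year"))
        vc = stats._variance_components(fit.result)
        est = sorted(vc.values(), reverse=True)
        assert est[0] == pytest.approx(9.0, rel=0.6)
        assert est[1] == pytest.approx(4.0, rel=0.6)

    def test_k_counts_fixed_plus_variances_plus_residual(self, rng):
        df = grouped_data(rng)
        fit = stats.fit_lmm(df, "y", ("x",), random=("individual_id", "year"))
        assert fit.k == 2 + 2 + 1

    def test_single_level_random_factor_rejected(self, rng):
        df = grouped_data(rng, n_groups=1)
        with pytest.raises(stats.StatsError):
            stats.fit_lmm(df, "y", ("x",), random=("individual_id",))


class TestModelSelect:
    def test_single_candidate_selected(self, rng):
        df = grouped_data(rng)
        cmp_ = stats.model_select([stats.fit_lmm(df, "y", (), random=("individual_id",))])
        assert cmp_.table["selected"].sum() == 1

    def test_identical_likelihood_prefers_fewer_parameters(self):
        f1 = stats.LMMFit("small", "y ~ 1", (), None, 100, 2, -50.0, True, False, (1,))
        f2 = stats.LMMFit("big", "y ~ x", (), None, 100, 4, -50.0, True, False, (1,))
        cmp_ = stats.model_select([f2, f1])
        assert cmp_.table.loc[cmp_.table["selected"], "label"].iloc[0] == "small"
        # the bigger model sits within 2 dAICc but only adds parameters
        big = cmp_.table.set_index("label").loc["big"]
        assert big["delta_aicc"] <= 4.3 and not big["informative"]

    def test_differing_row_sets_rejected(self, rng):
        df = grouped_data(rng)
        f1 = stats.fit_lmm(df, "y", (), random=("individual_id",))
        f2 = stats.fit_lmm(df.iloc[:-5], "y", (), random=("individual_id",))
        with pytest.raises(stats.StatsError, match="row set"):
            stats.model_select([f1, f2])

    def test_strong_slope_beats_intercept_only(self, rng):
        df = grouped_data(rng, slope=5.0)  # 5 SD effect
        f0 = stats.fit_lmm(df, "y", (), random=("individual_id",), label="null")
        f1 = stats.fit_lmm(df, "y", ("x",), random=("individual_id",), label="slope")
        cmp_ = stats.model_select([f0, f1])
        assert cmp_.best.label == "slope"


class TestPopulationSlopes:
    def _fit(self, rng, slopes={"a": 0.5, "b": 0.0}):
        rows = []
        for pop, beta in slopes.items():
            for i in range(15):
                for y in range(2010, 2020):
                    x = rng.normal(0, 5)
                    rows.append(
                        {
                            "population": pop,
                            "individual_id": f"{pop}{i}",
                            "year": y,
                            "x": x,
                            "y": 100 + beta * x + rng.normal(0, 2),
                        }
                    )
        df = pd.DataFrame(rows)
        return stats.fit_lmm(
            df, "y", ("x", "C(population)", "x:C(population)"), random=("individual_id",)
        )

    def test_reference_population_slope_is_main_effect(self, rng):
        fit = self._fit(rng)
        slopes = stats.population_slopes(fit, "x")
        ref = [s for s in slopes if s.population == "a"][0]
        assert ref.slope == pytest.approx(float(fit.params["x"]), abs=1e-12)

    def test_true_slopes_inside_wald_cis(self):
        hits = total = 0
        for rep in range(20):
            fit = self._fit(np.random.default_rng(100 + rep))
            for s in stats.population_slopes(fit, "x"):
                truth = {"a": 0.5, "b": 0.0}[s.population]
                hits += s.ci_low <= truth <= s.ci_high
                total += 1
        assert hits / total >= 0.85  # nominal 95% Wald coverage

    def test_ci_excludes_zero_iff_wald(self, rng):
        for s in stats.population_slopes(self._fit(rng), "x"):
            z = sps.norm.ppf(0.975)
            assert s.excludes_zero == (abs(s.slope) > z * s.se)


class TestCentringAndStandardising:
    def test_centring_leaves_slopes_unchanged(self, rng):
        df = grouped_data(rng, slope=1.5)
        df["population"] = "p1"
        fit1 = stats.fit_lmm(df, "y", ("x",), random=("individual_id",))
        shifted = df.assign(x=df["x"] + 57.0)
        centred = stats.centre_by_population(shifted, ("x",))
        fit2 = stats.fit_lmm(centred, "y", ("x",), random=("individual_id",))
        assert fit1.params["x"] == pytest.approx(fit2.params["x"], abs=1e-8)

    def test_standardisation_roundtrip(self, rng):
        df = grouped_data(rng, slope=1.5)
        raw = stats.fit_lmm(df, "y", ("x",), random=("individual_id",))
        std = stats.standardise(df, ("y", "x"))
        fit = stats.fit_lmm(std, "y", ("x",), random=("individual_id",))
        back = fit.params["x"] * df["y"].std(ddof=1) / df["x"].std(ddof=1)
        assert back == pytest.approx(raw.params["x"], abs=1e-6)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(stats.ZeroVarianceError):
            stats.standardise(df, ("x",))


class TestSlopeOfSlopes:
    def test_arrival_equals_speed_slopes_selects_speed_with_unit_coefficient(self, rng):
        n = 10
        speed = rng.normal(0, 0.5, n)
        df = pd.DataFrame(
            {
                "population": [f"p{i}" for i in range(n)],
                "slope_arrival": speed,
                "slope_departure": rng.normal(0, 0.5, n),
                "slope_distance": rng.normal(0, 0.5, n),
                "slope_speed": speed,
            }
        )
        cmp_ = stats.slope_of_slopes(df)
        assert cmp_.best.label == "slope_speed"
        assert cmp_.best.params["slope_speed"] == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_slopes_select_intercept_only(self, rng):
        n = 10
        df = pd.DataFrame(
            {
                "population": [f"p{i}" for i in range(n)],
                "slope_arrival": rng.normal(0, 0.05, n),
                "slope_departure": rng.normal(0, 0.5, n),
                "slope_distance": rng.normal(0, 0.5, n),
                "slope_speed": rng.normal(0, 0.5, n),
            }
        )
        assert stats.slope_of_slopes(df).best.label == "intercept_only"

    def test_too_few_populations_drops_big_candidates(self, rng):
        df = pd.DataFrame(
            {
                "population": list("abcdef"),
                "slope_arrival": rng.normal(0, 1, 6),
                "slope_departure": rng.normal(0, 1, 6),
                "slope_distance": rng.normal(0, 1, 6),
                "slope_speed": rng.normal(0, 1, 6),
            }
        )
        cmp_ = stats.slope_of_slopes(df)
        assert cmp_.table["k"].max() <= 4  # the 3-predictor model is inestimable


class TestLayingModel:
    def test_collinear_regressors_flagged(self, rng, caplog):
        df = pd.DataFrame(
            {
                "population": "p1",
                "individual_id": [f"i{i}" for i in range(60)],
                "year": list(range(2010, 2020)) * 6,
                "snowmelt_doy": rng.normal(160, 8, 60),
            }
        )
        df["arrival_doy"] = df["snowmelt_doy"] * 1.0  # r = 1
        df["laying_doy"] = 150 + 0.2 * df["snowmelt_doy"] + rng.normal(0, 2, 60)
        import logging

        with caplog.at_level(logging.WARNING, logger="arcticphen.stats"):
            cmp_ = stats.laying_model(df)
        assert abs(cmp_.collinearity_r) > 0.99
        assert any("collinear" in r.message for r in caplog.records)


class TestLiteratureMeta:
    def test_hand_computed_t(self):
        rep = stats.one_sample_t([0.5, 0.7, 0.6])
        assert rep.mean == pytest.approx(0.6)
        assert rep.t == pytest.approx(0.6 / (0.1 / np.sqrt(3)), rel=1e-9)
        assert rep.df == 2

    def test_zero_variance_is_an_error(self):
        with pytest.raises(stats.ZeroVarianceError):
            stats.one_sample_t([0.0, 0.0, 0.0])

    def test_meta_report_structure(self, rng):
        from arcticphen.synthetic import generate_literature_table

        tbl = generate_literature_table(rng=rng)
        rep = stats.literature_meta(tbl)
        assert rep["ttest_slope_laying_snowmelt"].p < 0.001
        assert rep["ttest_slope_arrival_snowmelt"].p < 0.001
        # laying-date time trends are built on snowmelt trends; the LM sees it
        assert rep["lm_slope_laying_time"].best.label == "snowmelt_trend"
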
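"""Composites, mixed models, likelihood-ratio tests, R², stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from convo_timing.stats import (
    LmmFit,
    ModelSpec,
    bonferroni_alpha,
    compute_composites,
    describe_cohort,
    fit_lmm,
    lrt_interaction,
    r2_nakagawa,
    report_alpha,
    stepwise_select,
)
from convo_timing.synthetic_data import simulate_cohort


class TestComposites:
    def test_mean_of_constituents(self):
        df = pd.DataFrame({
            "rbans_immediate_recall": [40.0], "rbans_delayed_recall": [60.0],
            "moca_immediate_recall": [40.0], "moca_delayed_recall": [60.0],
            "moca_orientation": [50.0],
        })
        out = compute_composites(df)
        assert out.loc[0, "memory"] == pytest.approx(50.0)
        assert out.loc[0, "orientation"] == pytest.approx(50.0)

    def test_equal_constituents_passthrough(self):
        df = pd.DataFrame({c: [50.0] for c in
                           ("rbans_language", "moca_language", "moca_naming")})
        assert compute_composites(df).loc[0, "language"] == pytest.approx(50.0)

    def test_missing_constituent_flagged_not_fatal(self):
        df = pd.DataFrame({"rbans_immediate_recall": [30.0, np.nan],
                           "rbans_delayed_recall": [50.0, np.nan]})
        out = compute_composites(df)
        assert out.loc[0, "memory"] == pytest.approx(40.0)
        assert bool(out.loc[0, "memory_partial"])
        assert np.isnan(out.loc[1, "memory"])


class TestBonferroni:
    @pytest.mark.parametrize("n,raw,reported", [(8, 0.00625, 0.006),
                                                (16, 0.003125, 0.003),
                                                (1, 0.05, 0.05)])
    def test_thresholds(self, n, raw, reported):
        thr = bonferroni_alpha(0.05, n)
        assert thr == pytest.approx(raw, rel=1e-12)
        assert report_alpha(thr) == reported

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.0, 4)


def _fit_stub(var_f, var_r, var_e):
    return LmmFit(spec=None, params=pd.Series(dtype=float),
                  conf_int=pd.DataFrame(), pvalues=pd.Series(dtype=float),
                  var_fixed=var_f, var_random=var_r, var_residual=var_e,
                  llf=0.0, n_obs=0, n_groups=0, method="reml",
                  log_transformed=False, converged=True, boundary=False, formula="")


class TestR2Nakagawa:
    def test_direct_formula(self):
        r2m, r2c = r2_nakagawa(_fit_stub(2.0, 1.0, 1.0))
        assert (r2m, r2c) == (pytest.approx(0.5), pytest.approx(0.75))

    def test_no_fixed_variance(self):
        r2m, r2c = r2_nakagawa(_fit_stub(0.0, 1.0, 1.0))
        assert r2m == 0.0 and r2c == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            r2_nakagawa(_fit_stub(0.0, 0.0, 0.0))

    def test_ordering_invariant_on_fits(self):
        tabs = simulate_cohort((6, 6, 6), 31)
        fit = fit_lmm(tabs["features"], ModelSpec(dv="speech_rate", log_dv=True))
        r2m, r2c = r2_nakagawa(fit)
        assert 0.0 <= r2m <= r2c <= 1.0


@pytest.fixture(scope="module")
def planted_tables():
    return simulate_cohort({"HC": 11, "MCI": 11, "AD": 10}, 314,
                           planted_effects={("turn_dur", "wm_attention", None): 0.40})


class TestFitLmm:
    def test_reduces_to_ols_when_one_obs_per_speaker(self):
        """With one observation per speaker the random intercept is
        unidentifiable and coefficients match ordinary least squares."""
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(0)
        n = 120
        df = pd.DataFrame({
            "speaker": [f"s{i}" for i in range(n)],
            "trial": ["describe", "match", "describe_and_match"] * (n // 3),
            "x": rng.normal(size=n),
            "age": rng.normal(70, 5, n), "sex": rng.integers(0, 2, n),
            "education": rng.normal(13, 2, n),
        })
        df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(0, 0.3, n)
        spec = ModelSpec(dv="y", predictors=("x",), trial_interaction=False, log_dv=False)
        fit = fit_lmm(df, spec)
        ols = smf.ols("y ~ x + C(trial, Treatment('describe_and_match')) + age + sex + education",
                      df).fit()
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=1e-6)

    def test_planted_slope_recovered(self, planted_tables):
        spec = ModelSpec(dv="turn_dur", predictors=("wm_attention",),
                         scale={"wm_attention": "zscore"}, log_dv=True)
        fit = fit_lmm(planted_tables["features"], spec)
        est = fit.params["wm_attention_z"]
        se = (fit.conf_int.loc["wm_attention_z"].iloc[1] - est) / 1.96
        assert abs(est - 0.40) < 3 * se
        assert fit.log_transformed and fit.method == "reml"

    def test_ci_brackets_estimate(self, planted_tables):
        fit = fit_lmm(planted_tables["features"], ModelSpec(dv="ipu_dur", log_dv=True))
        lo, hi = fit.conf_int.iloc[:, 0], fit.conf_int.iloc[:, 1]
        assert ((lo <= fit.params) & (fit.params <= hi)).all()

    def test_slopes_invariant_to_centering(self, planted_tables):
        df = planted_tables["features"]
        base = fit_lmm(df, ModelSpec(dv="turn_dur", predictors=("wm_attention",), log_dv=True))
        centered = fit_lmm(df, ModelSpec(dv="turn_dur", predictors=("wm_attention",),
                                         scale={"wm_attention": "center"}, log_dv=True))
        assert base.params["wm_attention"] == pytest.approx(
            centered.params["wm_attention_c"], abs=1e-6)

    def test_missing_column_rejected(self, planted_tables):
        with pytest.raises(ValueError, match="missing columns"):
            fit_lmm(planted_tables["features"], ModelSpec(dv="not_a_feature"))


class TestLrt:
    def _fits(self, df, dv="turn_dur", pred="wm_attention"):
        common = dict(dv=dv, predictors=(pred,), scale={pred: "zscore"},
                      log_dv=True, method="ml")
        add = fit_lmm(df, ModelSpec(trial_interaction=False, **common))
        full = fit_lmm(df, ModelSpec(trial_interaction=True, **common))
        return add, full

    def test_identical_models_chi2_zero_p_one(self, planted_tables):
        add, _ = self._fits(planted_tables["features"])
        chi2, df_, p = lrt_interaction(add, add)
        assert chi2 == 0.0 and df_ == 0 and p == 1.0

    def test_df_counts_interaction_parameters(self, planted_tables):
        add, full = self._fits(planted_tables["features"])
        _, df_, _ = lrt_interaction(add, full)
        assert df_ == 2  # one continuous predictor x (3-1) trials

    def test_group_by_trial_df_is_four(self):
        tabs = simulate_cohort((6, 6, 6), 77)
        common = dict(dv="speech_rate", predictors=("group",), log_dv=True, method="ml")
        add = fit_lmm(tabs["features"], ModelSpec(trial_interaction=False, **common))
        full = fit_lmm(tabs["features"], ModelSpec(trial_interaction=True, **common))
        assert lrt_interaction(add, full)[1] == 4

    def test_reml_fits_rejected(self, planted_tables):
        spec = ModelSpec(dv="turn_dur", log_dv=True)
        fit = fit_lmm(planted_tables["features"], spec)
        with pytest.raises(ValueError, match="ML"):
            lrt_interaction(fit, fit)

    def test_statistic_invariant_to_dv_rescaling(self, planted_tables):
        df = planted_tables["features"].copy()
        add, full = self._fits(df)
        chi2, _, _ = lrt_interaction(add, full)
        df["turn_dur"] = df["turn_dur"] * 7.3   # log-dv: scale is an intercept shift
        add2, full2 = self._fits(df)
        chi2b, _, _ = lrt_interaction(add2, full2)
        assert chi2 == pytest.approx(chi2b, abs=1e-4)

    def test_type_one_error_calibrated(self):
        """Null simulations reject at about the nominal 5% level."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            tabs = simulate_cohort((11, 11, 10), rng)  # no planted interaction
            add, full = self._fits(tabs["features"], dv="ipu_dur", pred="memory")
            _, _, p = lrt_interaction(add, full)
            rejections += (p < 0.05)
        rate = rejections / n_rep
        assert abs(rate - 0.05) <= 0.05  # wide band at 120 replicates


class TestStepwise:
    def test_deterministic(self, planted_tables):
        spec = ModelSpec(dv="turn_dur", predictors=("wm_attention", "memory"),
                         scale={"wm_attention": "zscore", "memory": "zscore"}, log_dv=True)
        r1 = stepwise_select(planted_tables["features"], spec)
        r2 = stepwise_select(planted_tables["features"], spec)
        assert r1.kept == r2.kept

    def test_strong_predictor_retained_noise_dropped(self):
        rng = np.random.default_rng(7)
        kept_strong = kept_noise = 0
        n_rep = 12
        for _ in range(n_rep):
            tabs = simulate_cohort((11, 11, 10), rng,
                                   planted_effects={("turn_dur", "wm_attention", None): 0.6})
            tabs["features"]["noise_pred"] = rng.normal(size=len(tabs["features"]))
            spec = ModelSpec(dv="turn_dur", predictors=("wm_attention", "noise_pred"),
                             scale={"wm_attention": "zscore"}, log_dv=True,
                             trial_interaction=False)
            res = stepwise_select(tabs["features"], spec)
            kept_strong += "wm_attention" in res.kept
            kept_noise += "noise_pred" in res.kept
        assert kept_strong >= 11
        assert kept_noise <= 4


class TestDescribeCohort:
    def test_identical_groups_no_differences(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "group": ["HC"] * 40 + ["MCI"] * 40,
            "score": np.tile(rng.normal(50, 5, 40), 2),
            "female": np.tile(rng.integers(0, 2, 40), 2),
        })
        out = describe_cohort(df, continuous=("score",), binary=("female",))
        ps = out["p_vs_ref"].dropna()
        assert (ps > 0.99).all()

    def test_group_means_and_percentages(self):
        tabs = simulate_cohort((30, 30, 30), 12)
        out = describe_cohort(tabs["speakers"], continuous=("rbans_total",), binary=("sex",))
        ad = out[(out.group == "AD") & (out.variable == "rbans_total")].iloc[0]
        assert ad["mean"] == pytest.approx(64.3, abs=3 * 11.8 / np.sqrt(30))
        pct = out[out.variable == "sex"]["pct"]
        assert ((0 <= pct) & (pct <= 100)).all()

    def test_missing_reference_group_rejected(self):
        df = pd.DataFrame({"group": ["MCI"] * 4, "x": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            describe_cohort(df, continuous=("x",))
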
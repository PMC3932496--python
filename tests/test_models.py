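"""Cox and Weibull proportional-hazards fits, RRRs, model comparison."""

import numpy as np
import pandas as pd
import pytest

from lexisurv.errors import ConvergenceError, ValidationError
from lexisurv.models import (
    CoxPH,
    FitResult,
    ModelSpec,
    WeibullPH,
    compare_models,
    extract_rrr,
    fit_cox,
    fit_weibull,
    survival_array,
)

from _oracles import cox_brute_force_1d


def records_frame(event, z):
    z = np.asarray(z, float)
    return pd.DataFrame({"z": z, "y": 1 - np.exp(-z), "event": np.asarray(event, int)})


def sim_records(rng, n=500, beta=(0.7, -0.3), censor=0.8):
    X = pd.DataFrame({
        "a": rng.random(n),
        "b": (rng.random(n) < 0.5).astype(float),
    })
    z = rng.exponential(1 / np.exp(X.to_numpy() @ np.asarray(beta)))
    c = rng.exponential(censor * z.mean() * 4, n)
    e = z <= c
    return records_frame(e, np.minimum(z, c)), X


class TestCoxPH:
    def test_symmetric_groups_give_zero_coefficient(self):
        # identical event-time patterns in both groups (with cross-group ties)
        times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        group = np.repeat([0.0, 1.0], 4)
        rec = records_frame(np.ones(8), times)
        X = pd.DataFrame({"g": group})
        for ties in ("efron", "breslow"):
            fit = fit_cox(rec, X, ModelSpec(ties=ties))
            assert abs(fit.coef["g"]) < 1e-10

    def test_matches_brute_force_partial_likelihood(self):
        # 6 subjects, one binary covariate, untied times
        times = np.array([1.0, 2.5, 3.1, 4.7, 5.2, 6.9])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        fit = fit_cox(records_frame(event, times), pd.DataFrame({"x": x}))
        oracle = cox_brute_force_1d(x, times, event.astype(bool))
        assert fit.coef["x"] == pytest.approx(oracle, abs=1e-6)

    def test_rank_invariance_of_time_scale(self):
        rng = np.random.default_rng(8)
        rec, X = sim_records(rng)
        fit_z = fit_cox(rec, X, ModelSpec(scale="z"))
        fit_y = fit_cox(rec, X, ModelSpec(scale="y"))
        np.testing.assert_allclose(fit_z.coef, fit_y.coef, atol=1e-8)
        # any strictly increasing transform leaves the fit unchanged
        rec_sq = rec.assign(z=rec["y"] ** 2)
        fit_sq = fit_cox(rec_sq, X, ModelSpec(scale="z"))
        np.testing.assert_allclose(fit_z.coef, fit_sq.coef, atol=1e-8)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(9)
        rec, X = sim_records(rng, n=300)
        fit = fit_cox(rec, X)
        df = X.assign(T=rec["z"], E=rec["event"])
        cf = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cf.params_.values, atol=1e-6)
        np.testing.assert_allclose(
            fit.cov.to_numpy(), cf.variance_matrix_.values, atol=1e-8
        )
        assert fit.loglik == pytest.approx(cf.log_likelihood_)

    def test_score_is_zero_at_optimum(self):
        from lexisurv.models import _cox_groups, _cox_ll_grad_hess

        rng = np.random.default_rng(10)
        rec, X = sim_records(rng, n=200)
        fit = fit_cox(rec, X)
        order, groups = _cox_groups(rec["z"].to_numpy(), rec["event"].to_numpy(bool))
        _, grad, _ = _cox_ll_grad_hess(
            fit.coef.to_numpy(), X.to_numpy()[order], groups=groups, ties="efron"
        )
        assert np.max(np.abs(grad)) < 1e-8

    def test_monotone_likelihood_names_covariate(self):
        # the covariate perfectly orders events before censorings
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(ConvergenceError, match="sep"):
            fit_cox(records_frame(event, times), pd.DataFrame({"sep": x}))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(11)
        rec, X = sim_records(rng, n=100)
        X = X.assign(dup=X["a"] * 2.0)
        with pytest.raises(ValidationError, match="dup"):
            fit_cox(rec, X)

    def test_requires_events(self):
        rec = records_frame([0, 0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            fit_cox(rec, pd.DataFrame({"x": [0.0, 1.0]}))

    def test_sklearn_estimator_api(self):
        rng = np.random.default_rng(12)
        rec, X = sim_records(rng, n=150)
        y = survival_array(rec["event"].astype(bool), rec["z"])
        est = CoxPH(ties="breslow").fit(X, y)
        assert est.get_params()["ties"] == "breslow"
        lp = est.predict(X)
        np.testing.assert_allclose(lp, X.to_numpy() @ est.coef_)


class TestWeibullPH:
    def test_shape_recovery_on_unit_exponential(self):
        rng = np.random.default_rng(13)
        z = rng.exponential(size=2000)
        rec = records_frame(np.ones(2000), z)
        fit = fit_weibull(rec, pd.DataFrame(index=rec.index))
        assert 0.93 <= fit.shape <= 1.07
        assert fit.rate == pytest.approx(1.0, abs=0.1)

    def test_exponential_closed_form(self):
        # shape fixed at 1, one binary covariate: beta-hat is the log of the
        # event/exposure rate ratio
        z = np.array([0.5, 1.2, 0.3, 2.0, 0.9, 1.5, 0.2, 0.8])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        rec = records_frame(e, z)
        fit = fit_weibull(rec, pd.DataFrame({"x": x}), fix_shape=1.0)
        d1, e1 = e[x == 1].sum(), z[x == 1].sum()
        d0, e0 = e[x == 0].sum(), z[x == 0].sum()
        assert fit.coef["x"] == pytest.approx(np.log((d1 / e1) / (d0 / e0)), abs=1e-6)
        assert fit.rate == pytest.approx(d0 / e0, rel=1e-5)

    def test_agrees_with_cox_under_exponential_truth(self):
        rng = np.random.default_rng(14)
        rec, X = sim_records(rng, n=1500)
        cox = fit_cox(rec, X)
        weib = fit_weibull(rec, X)
        # within 2 joint standard errors, coefficient by coefficient
        se = np.sqrt(cox.se.to_numpy() ** 2 + weib.se.to_numpy() ** 2)
        assert np.all(np.abs(cox.coef.to_numpy() - weib.coef.to_numpy()) < 2 * se)

    def test_refuses_y_scale(self):
        rng = np.random.default_rng(15)
        rec, X = sim_records(rng, n=50)
        with pytest.raises(ValidationError):
            fit_weibull(rec, X, ModelSpec(family="weibull", scale="y"))

    def test_matches_lifelines_weibull(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(16)
        rec, X = sim_records(rng, n=400)
        fit = fit_weibull(rec, X)
        df = X.assign(T=rec["z"], E=rec["event"])
        wf = lifelines.WeibullAFTFitter().fit(df, "T", "E")
        rho = np.exp(wf.params_["rho_"]["Intercept"])
        aft_beta = wf.params_["lambda_"].drop("Intercept")
        # AFT coefficients map to PH coefficients via beta_PH = -k * beta_AFT
        np.testing.assert_allclose(
            fit.coef.to_numpy(), (-rho * aft_beta[X.columns]).to_numpy(), atol=2e-3
        )
        assert fit.shape == pytest.approx(rho, rel=1e-3)


class TestRRR:
    def make_fit(self, names, beta, var):
        idx = pd.Index(names)
        return FitResult(
            family="cox",
            params=pd.Series(beta, index=idx),
            cov=pd.DataFrame(np.diag(var), index=idx, columns=idx),
            loglik=-1.0,
            n=10,
            n_events=5,
            scale_axis="z",
            covariate_names=list(names),
        )

    def test_zero_interaction_gives_unit_rrr(self):
        fit = self.make_fit(["female", "fem_x_light"], [0.3, 0.0], [0.01, 0.04])
        rrr = extract_rrr(fit)
        assert rrr.loc["light", "rrr"] == 1.0
        assert rrr.loc["light", "ci_low"] < 1.0 < rrr.loc["light", "ci_high"]

    def test_hand_computed_wald_interval(self):
        beta, se = 0.30010459245033816, 0.118  # log(1.35), chosen SE
        fit = self.make_fit(["fem_x_light"], [beta], [se ** 2])
        rrr = extract_rrr(fit)
        assert rrr.loc["light", "rrr"] == pytest.approx(np.exp(beta))
        assert rrr.loc["light", "ci_low"] == pytest.approx(np.exp(beta - 1.959963984540054 * se))
        assert rrr.loc["light", "ci_high"] == pytest.approx(np.exp(beta + 1.959963984540054 * se))

    def test_rrr_equals_ratio_of_sex_specific_hazard_ratios(self):
        rng = np.random.default_rng(17)
        n = 2000
        female = (rng.random(n) < 0.5).astype(float)
        light = (rng.random(n) < 0.5).astype(float)
        X = pd.DataFrame({
            "grade_light": light, "female": female, "fem_x_light": female * light,
        })
        beta = np.array([0.2, 0.1, np.log(1.5)])
        z = rng.exponential(1 / np.exp(X.to_numpy() @ beta))
        fit = fit_cox(records_frame(np.ones(n), z), X)
        rrr = extract_rrr(fit)
        hr_f = np.exp(fit.coef["grade_light"] + fit.coef["fem_x_light"])
        hr_m = np.exp(fit.coef["grade_light"])
        assert rrr.loc["light", "rrr"] == pytest.approx(hr_f / hr_m)

    def test_simulation_recovery_of_true_rrr(self):
        # true female x light interaction log(1.5): the mean estimated RRR
        # over replicates recovers it
        rng = np.random.default_rng(18)
        vals = []
        for _ in range(200):
            n = 800
            female = (rng.random(n) < 0.5).astype(float)
            light = (rng.random(n) < 0.5).astype(float)
            X = pd.DataFrame({
                "grade_light": light, "female": female,
                "fem_x_light": female * light,
            })
            beta = np.array([0.2, 0.1, np.log(1.5)])
            z = rng.exponential(1 / np.exp(X.to_numpy() @ beta))
            fit = fit_cox(records_frame(np.ones(n), z), X)
            vals.append(extract_rrr(fit).loc["light", "rrr"])
        assert 1.4 <= np.mean(vals) <= 1.6

    def test_missing_interaction_column_rejected(self):
        fit = self.make_fit(["female"], [0.1], [0.01])
        with pytest.raises(ValidationError):
            extract_rrr(fit)


class TestCompareModels:
    def test_weibull_beats_exponential_on_weibull_data(self):
        rng = np.random.default_rng(19)
        z = rng.weibull(2.0, size=1000)
        rec = records_frame(np.ones(1000), z)
        X = pd.DataFrame(index=rec.index)
        expo = fit_weibull(rec, X, fix_shape=1.0)
        weib = fit_weibull(rec, X)
        table = compare_models([expo, weib])
        assert table.loc[1, "family"] == "weibull"
        # nesting: the LR statistic is non-negative
        assert weib.loglik >= expo.loglik

    def test_self_tie_keeps_input_order(self):
        rng = np.random.default_rng(20)
        rec, X = sim_records(rng, n=100)
        fit = fit_cox(rec, X)
        table = compare_models([fit, fit])
        assert list(table["input_index"]) == [0, 1]

    def test_mismatched_data_rejected(self):
        rng = np.random.default_rng(21)
        rec1, X1 = sim_records(rng, n=60)
        rec2, X2 = sim_records(rng, n=60)
        with pytest.raises(ValidationError):
            compare_models([fit_cox(rec1, X1), fit_cox(rec2, X2)])
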
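import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from efferotype.datatypes import ClinicalTable
from efferotype.survival import (
    build_nomogram,
    calibration_curve,
    classify_icb_response,
    compare_response_proportions,
    cox_fit,
    design_matrix,
    km_logrank,
    point_biserial,
    time_dependent_auc,
)
from efferotype.synthetic import CohortConfig, generate_cohort


def _clin(times, events, **covars):
    n = len(times)
    return ClinicalTable(pd.DataFrame(
        {"os_time": times, "os_event": events, **covars},
        index=[f"s{i}" for i in range(n)]))


@pytest.fixture(scope="module")
def survival_cohort():
    coh = generate_cohort(CohortConfig(n_samples=600, seed=1))
    tbl = coh.clinical.table.copy()
    tbl["is_c1"] = (tbl["subtype_true"] == "C1").astype(float)
    return ClinicalTable(tbl.drop(columns="subtype_true"))


@pytest.fixture(scope="module")
def multi_fit(survival_cohort):
    return cox_fit(survival_cohort, ["is_c1", "age"], mode="multivariate")


class TestKmLogrank:
    def test_single_group_step_function_is_empirical(self):
        clin = _clin([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], group=["a"] * 4)
        # add a second group so the log-rank runs; inspect group a's curve
        clin2 = _clin([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1] * 6,
                      group=["a"] * 4 + ["b"] * 2)
        curves, _, _ = km_logrank(clin2, clin2.table["group"])
        s = curves["a"]
        # no censoring: S(t) after k-th of 4 deaths is (4-k)/4
        assert s.loc[1.0] == pytest.approx(0.75)
        assert s.loc[2.0] == pytest.approx(0.50)
        assert s.loc[4.0] == pytest.approx(0.0)

    def test_identical_groups_give_large_p(self):
        times = list(range(1, 21)) * 2
        groups = ["a"] * 20 + ["b"] * 20
        clin = _clin([float(t) for t in times], [1] * 40, group=groups)
        _, _, p = km_logrank(clin, clin.table["group"])
        assert p > 0.9

    def test_planted_hazard_separation_is_detected(self, survival_cohort):
        labels = survival_cohort.table["is_c1"].map({1.0: "C1", 0.0: "C2"})
        _, _, p = km_logrank(survival_cohort, labels)
        assert p < 1e-3

    def test_eventless_group_warns(self):
        clin = _clin([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], group=["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="no events"):
            km_logrank(clin, clin.table["group"])


class TestCoxFit:
    def test_planted_hazard_ratios_recovered(self, multi_fit):
        hr_subtype = multi_fit.hazard_ratio("is_c1")
        hr_age = multi_fit.hazard_ratio("age")
        assert abs(hr_subtype - 5.583) / 5.583 < 0.2
        assert abs(hr_age - 1.070) / 1.070 < 0.02

    def test_null_covariate_has_hr_near_one(self):
        rng = np.random.default_rng(4)
        coh = generate_cohort(CohortConfig(n_samples=400, seed=4))
        tbl = coh.clinical.table.copy()
        tbl["noise"] = rng.normal(size=len(tbl))
        fit = cox_fit(ClinicalTable(tbl.drop(columns="subtype_true")), ["noise"],
                      mode="univariate")["noise"]
        coef = float(fit.summary.loc["noise", "coef"])
        se = float(fit.summary.loc["noise", "se"])
        assert abs(coef) < 2.5 * se

    def test_univariate_mode_loops_variables(self, survival_cohort):
        fits = cox_fit(survival_cohort, ["is_c1", "age"], mode="univariate")
        assert set(fits) == {"is_c1", "age"}
        # univariate subtype effect is strongly positive (attenuation aside)
        assert fits["is_c1"].hazard_ratio("is_c1") > 2.0

    def test_categorical_dummy_coding(self, survival_cohort):
        tbl = survival_cohort.table.copy()
        tbl["subtype"] = tbl["is_c1"].map({1.0: "C1", 0.0: "C2"})
        fit = cox_fit(ClinicalTable(tbl), ["subtype"], mode="multivariate")
        assert "subtype[C2]" in fit.summary.index
        # C2 vs C1 is protective: the inverse of the planted C1 hazard ratio
        assert fit.hazard_ratio("subtype[C2]") < 0.5

    def test_constant_covariate_rejected(self):
        clin = _clin([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0], flat=[1.0] * 4)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(clin, ["flat"], mode="multivariate")

    def test_hr_equals_exp_coef_and_ci_contains_hr(self, multi_fit):
        s = multi_fit.summary
        np.testing.assert_allclose(s["hr"], np.exp(s["coef"]))
        assert ((s["hr_lower"] <= s["hr"]) & (s["hr"] <= s["hr_upper"])).all()


class TestNomogram:
    def test_predictions_match_direct_cox_formula(self, multi_fit, survival_cohort):
        """Internal-consistency oracle: S(t|x) = exp(-L0(t) * exp(lp)) computed
        from first principles off the fitted baseline cumulative hazard."""
        nom = build_nomogram(multi_fit, horizons=[365.0, 1095.0])
        design = design_matrix(survival_cohort, ["is_c1", "age"])
        beta = multi_fit.summary["coef"]
        ch = multi_fit.fitter.baseline_cumulative_hazard_.iloc[:, 0]
        for t in (365.0, 1095.0):
            lp = ((design - design.mean()) * beta).sum(axis=1)
            h0 = float(ch.iloc[ch.index.searchsorted(t, side="right") - 1])
            expected = np.exp(-h0 * np.exp(lp))
            got = nom.predict_survival(design, t)
            assert float((got - expected).abs().max()) < 1e-6

    def test_reference_covariates_predict_baseline_survival(self, multi_fit, survival_cohort):
        nom = build_nomogram(multi_fit, horizons=[365.0])
        design = design_matrix(survival_cohort, ["is_c1", "age"])
        ref = design.mean().to_frame().T  # lifelines baseline is at the mean
        ref.index = ["ref"]
        ch = multi_fit.fitter.baseline_cumulative_hazard_.iloc[:, 0]
        h0 = float(ch.iloc[ch.index.searchsorted(365.0, side="right") - 1])
        assert nom.predict_survival(ref, 365.0)["ref"] == pytest.approx(np.exp(-h0), abs=1e-12)

    def test_risk_increase_never_raises_survival(self, multi_fit, survival_cohort):
        nom = build_nomogram(multi_fit, horizons=[365.0])
        design = design_matrix(survival_cohort, ["is_c1", "age"]).iloc[:5].copy()
        base = nom.predict_survival(design, 365.0)
        bumped = design.copy()
        bumped["is_c1"] = bumped["is_c1"] + 1.0  # positive-coefficient covariate
        assert (nom.predict_survival(bumped, 365.0) <= base + 1e-12).all()

    def test_points_are_affine_in_linear_predictor(self, multi_fit, survival_cohort):
        nom = build_nomogram(multi_fit, horizons=[365.0])
        design = design_matrix(survival_cohort, ["is_c1", "age"])
        pts = nom.points(design)["total"]
        lp = nom.linear_predictor(design)
        r = np.corrcoef(pts, lp)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)
        # widest-ranging variable spans exactly 100 points
        per_var = nom.points(design).drop(columns="total")
        assert per_var.max().max() == pytest.approx(100.0)
        assert per_var.min().min() == pytest.approx(0.0)

    def test_horizon_beyond_follow_up_rejected(self, multi_fit):
        with pytest.raises(ValueError, match="beyond"):
            build_nomogram(multi_fit, horizons=[1e9])

    def test_needs_at_least_two_terms(self, survival_cohort):
        fit = cox_fit(survival_cohort, ["age"], mode="multivariate")
        with pytest.raises(ValueError, match="2 terms"):
            build_nomogram(fit, horizons=[365.0])


class TestTimeDependentAuc:
    def test_perfect_marker_without_censoring_scores_one(self):
        times = np.linspace(10, 1000, 50)
        clin = _clin(times.tolist(), [1] * 50)
        risk = pd.Series(-times, index=clin.sample_ids)  # earlier death = higher risk
        assert time_dependent_auc(risk, clin, 500.0) == pytest.approx(1.0)

    def test_reduces_to_plain_roc_auc_without_censoring(self):
        from efferotype.classify import roc_auc

        rng = np.random.default_rng(8)
        times = rng.uniform(10, 2000, 120)
        risk = pd.Series(-np.log(times) + rng.normal(0, 0.3, 120))
        clin = _clin(times.tolist(), [1] * 120)
        risk.index = clin.sample_ids
        t = 700.0
        cases = (times <= t).astype(int)
        assert time_dependent_auc(risk, clin, t) == pytest.approx(
            roc_auc(risk.to_numpy(), cases), abs=1e-10)

    def test_pure_noise_marker_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            coh = generate_cohort(CohortConfig(n_samples=500, seed=seed))
            clin = ClinicalTable(coh.clinical.table.drop(columns="subtype_true"))
            noise = pd.Series(rng.normal(size=500), index=clin.sample_ids)
            aucs.append(time_dependent_auc(noise, clin, 365.0))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_no_events_before_horizon_rejected(self):
        clin = _clin([100.0, 200.0, 300.0], [1, 1, 1])
        risk = pd.Series([1.0, 2.0, 3.0], index=clin.sample_ids)
        with pytest.raises(ValueError, match="comparable"):
            time_dependent_auc(risk, clin, 5.0)


class TestCalibration:
    def test_self_simulated_data_is_calibrated(self, multi_fit, survival_cohort):
        nom = build_nomogram(multi_fit, horizons=[1095.0])
        curve = calibration_curve(nom, survival_cohort, 1095.0, n_bins=4)
        assert (np.abs(curve["predicted"] - curve["observed"]) < 0.12).all()
        # predictions ordered by bin construction
        assert curve["predicted"].is_monotonic_increasing

    def test_single_bin_recovers_overall_km(self, multi_fit, survival_cohort):
        from lifelines import KaplanMeierFitter

        nom = build_nomogram(multi_fit, horizons=[1095.0])
        curve = calibration_curve(nom, survival_cohort, 1095.0, n_bins=1)
        kmf = KaplanMeierFitter().fit(survival_cohort.table["os_time"],
                                      survival_cohort.table["os_event"])
        overall = float(kmf.survival_function_at_times(1095.0).iloc[0])
        assert len(curve) == 1
        assert curve.loc[0, "observed"] == pytest.approx(overall)


class TestPointBiserial:
    def test_equals_pearson_with_binary_coding(self):
        rng = np.random.default_rng(10)
        y = np.array([0, 1] * 5)
        x = rng.normal(size=10) + y
        r, p = point_biserial(y, x)
        rp, pp = sps.pearsonr(y.astype(float), x)
        assert r == pytest.approx(rp, abs=1e-12)
        assert p == pytest.approx(pp, abs=1e-12)

    def test_sign_flips_with_label_inversion(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        x = np.array([1.0, 2.0, 5.0, 6.0, 1.5, 7.0])
        r1, _ = point_biserial(y, x)
        r2, _ = point_biserial(1 - y, x)
        assert r1 == pytest.approx(-r2)

    def test_equal_group_means_give_zero(self):
        y = [0, 0, 1, 1]
        x = [1.0, 3.0, 0.0, 4.0]  # both groups mean 2
        r, _ = point_biserial(y, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            point_biserial([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])


class TestIcbResponse:
    def test_thresholding_policy(self):
        scores = pd.Series({"a": 0.5, "b": -0.3, "c": 0.0})
        with pytest.warns(UserWarning, match="exactly 0"):
            out = classify_icb_response(scores)
        assert out["a"] == "non-responder"
        assert out["b"] == "responder"
        assert out["c"] == "non-responder"

    def test_missing_scores_excluded(self):
        scores = pd.Series({"a": 1.0, "b": np.nan, "c": -1.0})
        out = classify_icb_response(scores)
        assert list(out.index) == ["a", "c"]

    def test_proportions_chi_square(self):
        resp = ["responder"] * 30 + ["non-responder"] * 10 + \
               ["responder"] * 10 + ["non-responder"] * 30
        grp = ["C1"] * 40 + ["C2"] * 40
        chi2, p = compare_response_proportions(resp, grp)
        tab = pd.crosstab(pd.Series(resp), pd.Series(grp))
        chi2_ref, p_ref, _, _ = sps.chi2_contingency(tab)
        assert chi2 == pytest.approx(chi2_ref) and p == pytest.approx(p_ref)
        assert p < 0.001
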
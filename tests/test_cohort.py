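"""Generator calibration, simulation fidelity, missingness, and CSV round trips."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cvprofiles as cv
from cvprofiles.cohort import (
    CLASS_MEANS,
    CLASS_SDS,
    POOLED_CORR,
    CalibrationError,
    marginal_high_risk_probability,
    within_class_correlation,
)


class TestDefaultParams:
    def test_calibrated_defaults(self, params):
        assert np.allclose(params.class_prevalence, [0.62, 0.38])
        assert params.class_indicator_means[1, 0] == pytest.approx(28.97)
        assert params.class_indicator_means[0, 3] == pytest.approx(74.13)
        # factor shifts center at zero under prevalence weighting
        w = params.class_prevalence @ params.cognitive_class_means
        assert np.all(np.abs(w) < 1e-9)
        # and the speeded-language shifts stay near the published class means
        assert abs(0.62 * params.cognitive_class_means[0, 4]
                   + 0.38 * params.cognitive_class_means[1, 4]) < 0.02
        params.validate()

    def test_validation_rejects_bad_prevalence(self, params):
        bad = params.copy()
        bad.class_prevalence = np.array([0.7, 0.4])
        with pytest.raises(ValueError):
            bad.validate()

    def test_validation_rejects_nonpsd_corr(self, params):
        bad = params.copy()
        R = np.eye(7)
        R[0, 1] = R[1, 0] = 0.9
        R[0, 2] = R[2, 0] = 0.9
        R[1, 2] = R[2, 1] = -0.9
        bad.within_class_corr = R
        with pytest.raises(ValueError):
            bad.validate()


class TestCalibrateIntercept:
    def test_closed_form_no_slopes(self):
        p = cv.GeneratorParams()
        p.concomitant_coefs = {k: 0.0 for k in p.concomitant_coefs}
        out = cv.calibrate_intercept(p)
        assert out.concomitant_coefs["intercept"] == pytest.approx(
            np.log(0.38 / 0.62), abs=1e-9
        )

    def test_symmetric_target_half(self):
        p = cv.GeneratorParams()
        p.class_prevalence = np.array([0.5, 0.5])
        p.concomitant_coefs = {k: 0.0 for k in p.concomitant_coefs}
        out = cv.calibrate_intercept(p)
        assert out.concomitant_coefs["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_marginal_matches_monte_carlo(self, params):
        """Numerically integrated marginal agrees with simulation."""
        analytic = marginal_high_risk_probability(params)
        assert analytic == pytest.approx(0.38, abs=1e-6)
        big = params.copy()
        big.n_subjects = 200_000
        c = cv.simulate_cohort(big, seed=11)
        assert c.true_class.mean() == pytest.approx(0.38, abs=0.005)


class TestCalibrateCorrelations:
    def test_hdl_triglycerides_within_corr(self, params):
        """Mixture-moment inversion gives rho_w ~ -0.22 for the -0.486 target."""
        pi = np.array([0.62, 0.38])
        r = within_class_correlation(-0.486, CLASS_MEANS, CLASS_SDS, pi, 3, 4)
        assert r == pytest.approx(-0.221, abs=0.005)
        assert params.within_class_corr[3, 4] == pytest.approx(r, abs=1e-9)

    def test_monte_carlo_recovers_pooled_target(self, params):
        """Large-sample pooled correlation converges to the calibration target."""
        big = cv.default_params(n_subjects=300_000)
        c = cv.simulate_cohort(big, seed=3)
        emp = np.corrcoef(c[cv.INDICATORS].to_numpy(), rowvar=False)
        off = ~np.eye(7, dtype=bool)
        assert np.abs(emp - POOLED_CORR)[off].max() < 0.02

    def test_equal_classes_passthrough(self):
        """With identical class moments the within corr equals the pooled target."""
        means = np.tile(CLASS_MEANS[0], (2, 1))
        sds = np.tile(CLASS_SDS[0], (2, 1))
        r = within_class_correlation(
            -0.486, means, sds, np.array([0.62, 0.38]), 3, 4
        )
        assert r == pytest.approx(-0.486, abs=1e-12)

    def test_identity_target_with_separated_means(self):
        p = cv.GeneratorParams()
        r = within_class_correlation(
            0.0, p.class_indicator_means, p.class_indicator_sds,
            np.array([0.62, 0.38]), 3, 4,
        )
        assert r > 0  # compensates the negative between-class HDL-TG covariance

    def test_infeasible_target_raises(self):
        p = cv.GeneratorParams()
        target = POOLED_CORR.copy()
        target[0, 1] = target[1, 0] = 0.999
        sds = p.class_indicator_sds.copy()
        sds[:, 1] = 0.001  # shrink CIMT spread so the pair becomes infeasible
        p.class_indicator_sds = sds
        with pytest.raises(CalibrationError, match="cimt"):
            cv.calibrate_correlations(p, target)


class TestSimulateCohort:
    def test_deterministic(self, params, cohort):
        again = cv.simulate_cohort(params, seed=1)
        pd.testing.assert_frame_equal(cohort, again)

    def test_class_share_near_prevalence(self, cohort):
        share = (cohort.true_class == 0).mean()
        se = np.sqrt(0.62 * 0.38 / len(cohort))
        assert abs(share - 0.62) < 3 * se

    def test_indicators_positive_and_finite(self, cohort):
        assert np.isfinite(cohort[cv.INDICATORS].to_numpy()).all()
        assert (cohort.hdl > 0).all()
        assert (cohort.triglycerides > 0).all()
        assert (cohort.bmi > 0).all()

    def test_degenerate_n_rejected(self, params):
        small = params.copy()
        small.n_subjects = 3
        with pytest.raises(ValueError):
            cv.simulate_cohort(small, seed=1)

    def test_logistic_recovery_of_age_slope(self):
        """Generator self-consistency: logit of true class recovers the slopes."""
        big = cv.default_params(n_subjects=100_000)
        c = cv.simulate_cohort(big, seed=7)
        from cvprofiles.concomitant import build_design

        D, complete = build_design(c)
        X = sm.add_constant(D)
        fit = sm.Logit(c.true_class.to_numpy(), X).fit(disp=0)
        slope, se = fit.params[1], fit.bse[1]
        assert abs(slope - np.log(1.140)) < 2 * se

    def test_mixture_moments_match_closed_form(self):
        big = cv.default_params(n_subjects=100_000)
        c = cv.simulate_cohort(big, seed=9)
        pi = np.array([0.62, 0.38])
        pooled_mean = pi @ CLASS_MEANS
        dev = CLASS_MEANS - pooled_mean
        pooled_var = pi @ (CLASS_SDS**2 + dev**2)
        emp_mean = c[cv.INDICATORS].mean().to_numpy()
        emp_var = c[cv.INDICATORS].var(ddof=0).to_numpy()
        assert np.all(np.abs(emp_mean - pooled_mean) / np.sqrt(pooled_var) < 0.02)
        assert np.all(np.abs(emp_var / pooled_var - 1) < 0.05)

    def test_factor_scores_center_near_zero(self, cohort):
        cols = [f"true_{f}" for f in cv.FACTORS]
        means = cohort[cols].mean().to_numpy()
        assert np.all(np.abs(means) < 0.12)  # 3 SE at n=727, SD<=0.88

    def test_derived_fps_in_attainable_range(self, params):
        p = params.copy()
        p.fps_mode = "derived"
        p.n_subjects = 300
        c = cv.simulate_cohort(p, seed=4)
        lo, hi = cv.load_point_table().attainable_range()
        assert c.fps.between(lo, hi).all()
        assert c.fps.dtype.kind in "iu"


class TestMissingness:
    def test_zero_rate_identity(self, params, cohort):
        p = params.copy()
        p.missing_rate = 0.0
        out = cv.apply_missingness(cohort, p, seed=3)
        pd.testing.assert_frame_equal(out, cohort)

    def test_incomplete_fraction(self, cohort_missing):
        frac = cohort_missing.isna().any(axis=1).mean()
        se = np.sqrt(0.22 * 0.78 / len(cohort_missing))
        assert abs(frac - 0.22) < 3 * se

    def test_indicators_never_missing(self, cohort_missing):
        assert cohort_missing[cv.INDICATORS].notna().all().all()

    def test_invalid_rate_rejected(self, params, cohort):
        bad = params.copy()
        bad.missing_rate = 1.5
        with pytest.raises(ValueError):
            cv.apply_missingness(cohort, bad, seed=1)


class TestCohortIO:
    def test_round_trip(self, cohort_missing, tmp_path):
        path = tmp_path / "cohort.csv"
        cv.write_cohort(cohort_missing, path)
        back = cv.read_cohort(path)
        num = [c for c in cohort_missing.columns if c != "ethnicity"]
        np.testing.assert_allclose(
            back[num].to_numpy(float), cohort_missing[num].to_numpy(float),
            rtol=0, atol=1e-12,
        )
        assert (back.ethnicity == cohort_missing.ethnicity).all()

    def test_sidecar_written(self, cohort, params, tmp_path):
        path = tmp_path / "c.csv"
        cv.write_cohort(cohort, path, params, seed=1)
        import json

        meta = json.loads((tmp_path / "c.csv.json").read_text())
        assert meta["simulation_seed"] == 1
        assert meta["class_prevalence"] == [0.62, 0.38]

    def test_non_numeric_cell_diagnosed(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,bmi\n1,24.1\n2,oops\n")
        with pytest.raises(ValueError, match="row 1.*'bmi'"):
            cv.read_cohort(path)

    def test_dot_token_rejected(self, tmp_path):
        path = tmp_path / "dot.csv"
        path.write_text("subject_id,bmi\n1,.\n")
        with pytest.raises(ValueError, match="'.'"):
            cv.read_cohort(path)

    def test_empty_string_is_missing(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("subject_id,bmi,apoe4\n1,24.1,\n")
        back = cv.read_cohort(path)
        assert np.isnan(back.apoe4.iloc[0])
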
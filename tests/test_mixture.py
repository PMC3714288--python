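"""EM engine: closed forms, oracles, entropy, ordering, enumeration."""

import numpy as np
import pytest

import cvprofiles as cv
from cvprofiles.mixture import LPAModel, PosteriorMatrix, n_parameters


def _matrix(X):
    X = np.asarray(X, float)
    return cv.RiskMatrix(
        X=X, mask=~np.isnan(X), means=np.zeros(X.shape[1]),
        sds=np.ones(X.shape[1]),
    )


class TestStandardize:
    def test_round_trip(self, cohort_missing):
        X = cv.standardize(cohort_missing)
        raw = cohort_missing[cv.INDICATORS].to_numpy(float)
        np.testing.assert_allclose(X.back_transform(X.X), raw, atol=1e-10)

    def test_unit_moments(self, risk_matrix):
        assert np.allclose(np.nanmean(risk_matrix.X, axis=0), 0, atol=1e-8)
        assert np.allclose(np.nanstd(risk_matrix.X, axis=0), 1, atol=1e-8)

    def test_zero_variance_rejected(self, cohort):
        bad = cohort.copy()
        bad["bmi"] = 25.0
        with pytest.raises(ValueError, match="bmi"):
            cv.standardize(bad)

    def test_class_conditional_z_means_near_published(self, cohort):
        """Standardized BMI means by true class sit near the published
        estimated within-class standardized means (-0.324, 0.630)."""
        X = cv.standardize(cohort)
        z = X.X[:, 0]
        cls = cohort.true_class.to_numpy()
        assert z[cls == 0].mean() == pytest.approx(-0.324, abs=0.1)
        assert z[cls == 1].mean() == pytest.approx(0.630, abs=0.1)


class TestLoglik:
    def test_single_cell_at_mode(self):
        m = LPAModel(K=1, pi=np.ones(1), mu=np.zeros((1, 1)),
                     sigma2=np.ones((1, 1)), loglik=0, q=2)
        X = _matrix([[0.0]])
        assert cv.loglik(m, X) == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)))

    def test_additivity_under_duplication(self, toy_two_cluster):
        m, _ = cv.fit_lpa(toy_two_cluster, 2, n_starts=10, seed=0)
        X2 = _matrix(np.vstack([toy_two_cluster.X, toy_two_cluster.X]))
        assert cv.loglik(m, X2) == pytest.approx(2 * cv.loglik(m, toy_two_cluster))

    def test_matches_naive_summation_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((25, 3))
        X[2, 1] = np.nan
        Xm = _matrix(X)
        m, _ = cv.fit_lpa(Xm, 2, n_starts=5, seed=1, max_iter=50)
        # brute force: per subject, sum_k pi_k * prod_obs N(y; mu, sigma)
        from scipy.stats import norm

        total = 0.0
        s2 = m.class_sigma2()
        for i in range(25):
            acc = 0.0
            for k in range(2):
                prod = m.pi[k]
                for j in range(3):
                    if np.isfinite(X[i, j]):
                        prod *= norm.pdf(X[i, j], m.mu[k, j],
                                         np.sqrt(s2[k, j]))
                acc += prod
            total += np.log(acc)
        assert cv.loglik(m, Xm) == pytest.approx(total, abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        m = LPAModel(K=1, pi=np.ones(1), mu=np.zeros((1, 1)),
                     sigma2=np.zeros((1, 1)), loglik=0, q=2)
        with pytest.raises(ValueError):
            cv.loglik(m, _matrix([[0.0]]))


class TestFitLPA:
    def test_k1_closed_form(self, risk_matrix):
        m, P = cv.fit_lpa(risk_matrix, 1)
        X = risk_matrix.X
        np.testing.assert_allclose(m.mu[0], np.nanmean(X, axis=0), atol=1e-12)
        np.testing.assert_allclose(
            np.asarray(m.sigma2).ravel(), np.nanvar(X, axis=0), atol=1e-12
        )
        # closed-form Gaussian loglik over observed cells
        mask = risk_matrix.mask
        z = (X - m.mu[0]) / np.sqrt(np.asarray(m.sigma2).ravel())
        ll = -0.5 * (
            np.log(2 * np.pi * np.asarray(m.sigma2).ravel()) + z**2
        )
        assert m.loglik == pytest.approx(float(np.where(mask, ll, 0).sum()))
        assert np.all(P.probs == 1.0)

    def test_monotone_loglik_and_posterior_normalization(self, risk_matrix):
        m, P = cv.fit_lpa(risk_matrix, 2, seed=0, check_monotone=True)
        assert m.converged
        np.testing.assert_allclose(P.probs.sum(axis=1), 1.0, atol=1e-10)
        # M-step fixed point: pi equals posterior column means at convergence
        np.testing.assert_allclose(m.pi, P.probs.mean(axis=0), atol=1e-5)

    def test_point_masses_recovered(self):
        X = np.vstack([np.full((8, 1), -4.0), np.full((12, 1), 4.0)])
        X += np.random.default_rng(3).normal(0, 1e-3, X.shape)
        m, P = cv.fit_lpa(_matrix(X), 2, n_starts=10, seed=2)
        # HDL ordering does not apply to 1 indicator; sort by mean
        order = np.argsort(m.mu[:, 0])
        assert m.mu[order, 0] == pytest.approx([-4, 4], abs=0.01)
        assert sorted(m.pi) == pytest.approx([0.4, 0.6], abs=1e-3)
        assert P.max_prob.min() > 0.999

    def test_em_matches_grid_search_oracle(self):
        """On a toy instance EM attains at least the best coarse-grid loglik."""
        rng = np.random.default_rng(8)
        X = np.concatenate(
            [rng.normal(-1.2, 0.6, 12), rng.normal(1.5, 0.9, 13)]
        )[:, None]
        Xm = _matrix(X)
        m, _ = cv.fit_lpa(Xm, 2, n_starts=20, seed=0)
        mus = np.linspace(X.min(), X.max(), 21)
        sds = np.geomspace(0.2, 2.5, 8)
        pis = np.linspace(0.1, 0.9, 9)
        best = -np.inf
        x = X.ravel()
        for m1 in mus:
            for m2 in mus:
                for s1 in sds:
                    for s2 in sds:
                        d1 = np.exp(-0.5 * ((x - m1) / s1) ** 2) / s1
                        d2 = np.exp(-0.5 * ((x - m2) / s2) ** 2) / s2
                        for p1 in pis:
                            ll = np.log(
                                (p1 * d1 + (1 - p1) * d2)
                                / np.sqrt(2 * np.pi)
                            ).sum()
                            if ll > best:
                                best = ll
        assert m.loglik >= best - 1e-3

    def test_fiml_equals_complete_data_on_complete_input(self, cohort):
        X = cv.standardize(cohort)
        m, _ = cv.fit_lpa(X, 2, seed=4)
        assert cv.loglik(m, X) == pytest.approx(m.loglik, abs=1e-8)

    def test_permutation_invariance(self, risk_matrix):
        rng = np.random.default_rng(6)
        perm = rng.permutation(risk_matrix.n)
        Xp = cv.RiskMatrix(
            X=risk_matrix.X[perm], mask=risk_matrix.mask[perm],
            means=risk_matrix.means, sds=risk_matrix.sds,
        )
        m1, P1 = cv.fit_lpa(risk_matrix, 2, seed=0)
        m2, P2 = cv.fit_lpa(Xp, 2, seed=0)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-4)
        np.testing.assert_allclose(m1.mu, m2.mu, atol=1e-3)

    def test_preconditions(self, risk_matrix):
        with pytest.raises(ValueError):
            cv.fit_lpa(risk_matrix, 0)
        small = _matrix(np.random.default_rng(0).standard_normal((15, 7)))
        with pytest.raises(ValueError):
            cv.fit_lpa(small, 2)

    def test_class_mean_recovery_over_seeds(self, params):
        """Estimated standardized class means near truth, averaged over seeds."""
        pi = params.class_prevalence
        mu_raw = params.class_indicator_means
        pooled_mean = pi @ mu_raw
        dev = mu_raw - pooled_mean
        pooled_sd = np.sqrt(pi @ (params.class_indicator_sds**2 + dev**2))
        truth = (mu_raw - pooled_mean) / pooled_sd
        errs = []
        for seed in range(1, 11):
            c = cv.simulate_cohort(params, seed=seed)
            X = cv.standardize(c)
            m, _ = cv.fit_lpa(X, 2, seed=seed)
            errs.append(np.abs(m.mu - truth))
        assert np.mean(errs) < 0.15


class TestRelativeEntropy:
    def test_boundary_cases(self):
        hard = PosteriorMatrix.from_probs(np.eye(2)[[0, 1, 0]])
        assert cv.relative_entropy(hard) == pytest.approx(1.0)
        uniform = PosteriorMatrix.from_probs(np.full((5, 2), 0.5))
        assert cv.relative_entropy(uniform) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        P = PosteriorMatrix.from_probs(np.array([[0.9, 0.1], [0.9, 0.1]]))
        assert cv.relative_entropy(P) == pytest.approx(0.5310, abs=1e-4)

    def test_invalid_rows_rejected(self):
        bad = PosteriorMatrix(
            probs=np.array([[0.6, 0.3]]), labels=np.array([0]),
            max_prob=np.array([0.6]),
        )
        with pytest.raises(ValueError):
            cv.relative_entropy(bad)


class TestBIC:
    def test_zero_model(self):
        m = LPAModel(K=1, pi=np.ones(1), mu=np.zeros((1, 1)),
                     sigma2=np.ones((1, 1)), loglik=0.0, q=0)
        assert cv.bic(m, 100) == 0.0

    def test_k1_closed_form(self, risk_matrix):
        m, _ = cv.fit_lpa(risk_matrix, 1)
        expected = -2 * m.loglik + n_parameters(1) * np.log(risk_matrix.n)
        assert cv.bic(m, risk_matrix.n) == pytest.approx(expected)

    def test_bic_prefers_true_k1_on_null_data(self):
        """On 1-class data BIC favors K=1 in nearly all replicates."""
        wins = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            X = _matrix(rng.standard_normal((150, 7)))
            m1, _ = cv.fit_lpa(X, 1)
            m2, _ = cv.fit_lpa(X, 2, n_starts=5, seed=r, tol=1e-5,
                               max_iter=300)
            wins += cv.bic(m1, 150) < cv.bic(m2, 150)
        assert wins >= 0.9 * reps


class TestOrderClasses:
    def test_hdl_descending(self, lpa_fit):
        m, P = lpa_fit
        hdl = m.mu[:, cv.INDICATORS.index("hdl")]
        assert hdl[0] > hdl[1]
        # published estimated standardized HDL means: 0.498 / -0.779
        assert hdl[0] == pytest.approx(0.498, abs=0.15)
        assert hdl[1] == pytest.approx(-0.779, abs=0.15)

    def test_idempotent(self, lpa_fit):
        m, P = lpa_fit
        m2, P2 = cv.order_classes(m, P)
        np.testing.assert_array_equal(m2.mu, m.mu)
        np.testing.assert_array_equal(P2.probs, P.probs)


class TestEnumeration:
    def test_selects_two_on_default_cohort(self, risk_matrix):
        res = cv.enumerate_classes(
            risk_matrix, K_max=3, B=29, seed=0, n_starts=15
        )
        assert res.selected_K == 2
        assert res.table.loc[res.table.K == 2, "blrt_p"].iloc[0] <= 0.05
        ll = res.table.loglik.to_numpy()
        assert np.all(np.diff(ll) >= -1e-6)  # loglik nondecreasing in K

    def test_selects_one_on_null_data(self):
        rng = np.random.default_rng(1)
        X = _matrix(rng.standard_normal((250, 7)))
        res = cv.enumerate_classes(X, K_max=2, B=29, seed=2, n_starts=5)
        assert res.selected_K == 1

    def test_selects_three_on_three_separated_classes(self):
        rng = np.random.default_rng(4)
        centers = np.array([-3.0, 0.0, 3.0])
        cls = rng.integers(0, 3, 450)
        X = centers[cls][:, None] + rng.standard_normal((450, 7))
        res = cv.enumerate_classes(_matrix(X), K_max=3, B=29, seed=3,
                                   n_starts=10)
        assert res.selected_K == 3


class TestBootstrapLRT:
    def test_rejects_on_two_class_data(self, risk_matrix):
        res = cv.bootstrap_lrt(risk_matrix, 2, B=29, seed=1, n_starts=10,
                               inner_starts=3, tol=1e-6, max_iter=400)
        assert res["p_value"] <= 1 / 30 + 1e-12
        assert res["lr"] >= 0.0

    def test_preconditions(self, risk_matrix):
        with pytest.raises(ValueError):
            cv.bootstrap_lrt(risk_matrix, 1)
        with pytest.raises(ValueError):
            cv.bootstrap_lrt(risk_matrix, 2, B=10)
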
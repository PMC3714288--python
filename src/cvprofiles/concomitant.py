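"""Conditional latent profile model: class membership regressed on covariates.

The mixing weights of the 2-class mixture are replaced by a subject-specific
logistic prior on age, education (college+), ethnicity (non-Hispanic Black and
Hispanic vs non-Hispanic White) and APOE4, estimated jointly with the
measurement model by EM.  Subjects with incomplete covariates stay in the
likelihood: their class prior is a free stratum-level mixing weight, so the
indicator part still uses all rows (FIML) while the logistic sub-model is
complete-case.  Standard errors come from the numerically differentiated
observed information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ETHNICITIES
from .mixture import (
    FitError,
    LPAModel,
    PosteriorMatrix,
    RiskMatrix,
    _log_components,
    _m_step,
    fit_lpa,
    n_parameters,
    order_classes,
)

COVARIATE_ORDER = ["age", "education", "eth_black", "eth_hispanic", "apoe4"]


@dataclass
class ConditionalLPAModel:
    K: int
    gamma: np.ndarray             # intercept + slopes, high-risk logit
    gamma_names: list
    gamma_se: np.ndarray | None
    mu: np.ndarray
    sigma2: np.ndarray
    pi_incomplete: np.ndarray     # stratum prior for incomplete-covariate rows
    loglik: float
    q: int
    n_complete: int
    converged: bool = False
    variance_structure: str = "invariant"
    age_center: float = 0.0       # internal centering; slopes are per raw unit


def build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix [age, education, eth_black, eth_hispanic, apoe4].

    Returns (design, complete_row_mask).  Ethnicity is expanded against the
    non-Hispanic-White reference; education reference is below-college.
    """
    eth = covariates["ethnicity"]
    D = np.column_stack(
        [
            covariates["age"].to_numpy(float),
            covariates["education"].to_numpy(float),
            (eth == ETHNICITIES[1]).to_numpy(float),
            (eth == ETHNICITIES[2]).to_numpy(float),
            covariates["apoe4"].to_numpy(float),
        ]
    )
    complete = ~np.isnan(D).any(axis=1) & eth.notna().to_numpy()
    return D, complete


def _logistic_newton(D1, t, gamma, ridge=1e-8, n_iter=25):
    """Weighted logistic M-step: fractional responses t in [0,1]."""
    g = gamma.copy()
    for _ in range(n_iter):
        eta = D1 @ g
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = D1.T @ (t - p)
        W = p * (1.0 - p)
        H = (D1 * W[:, None]).T @ D1 + ridge * np.eye(D1.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H += 1e-4 * np.eye(D1.shape[1])
            step = np.linalg.solve(H, grad)
        if np.abs(step).max() > 5.0:  # separation guard
            step *= 5.0 / np.abs(step).max()
        g = g + step
        if np.abs(step).max() < 1e-10:
            break
    return g


def _cond_loglik(gamma, mu, sigma2, pi_inc, X, mask, D1, complete):
    K = mu.shape[0]
    s2k = np.broadcast_to(sigma2, (K, X.shape[1])) if np.ndim(sigma2) == 1 else sigma2
    lc = _log_components(X, mask, mu, s2k)
    log_prior = np.empty((X.shape[0], K))
    eta = D1 @ gamma
    # class order: [low (reference), high]
    log_prior[complete, 0] = -np.logaddexp(0.0, eta[complete])
    log_prior[complete, 1] = eta[complete] - np.logaddexp(0.0, eta[complete])
    log_prior[~complete] = np.log(pi_inc)
    tot = lc + log_prior
    m = tot.max(axis=1, keepdims=True)
    ll = float((m.ravel() + np.log(np.exp(tot - m).sum(axis=1))).sum())
    P = np.exp(tot - m)
    P /= P.sum(axis=1, keepdims=True)
    return ll, P


def fit_conditional(
    X: RiskMatrix,
    covariates: pd.DataFrame,
    K: int = 2,
    n_starts: int = 50,
    tol: float = 1e-7,
    max_iter: int = 2000,
    seed: int = 0,
    compute_se: bool = True,
) -> tuple[ConditionalLPAModel, PosteriorMatrix]:
    """Joint EM for the 2-class mixture with a logistic concomitant sub-model.

    Initialized from the unconditional fit; the gamma M-step is a weighted
    logistic regression with the posteriors as fractional responses.  Age is
    centered internally for conditioning (slopes reported per raw year).
    """
    if K != 2:
        raise ValueError("the conditional model is implemented for K = 2")
    base_model, base_P = fit_lpa(X, K, n_starts=n_starts, tol=tol,
                                 max_iter=max_iter, seed=seed)
    D, complete = build_design(covariates)
    if complete.sum() < 25:
        raise FitError("too few complete-covariate rows for the logistic model")
    age_center = float(np.nanmean(D[:, 0]))
    Dc = D.copy()
    Dc[:, 0] = Dc[:, 0] - age_center
    D1 = np.column_stack([np.ones(len(Dc)), np.where(np.isnan(Dc), 0.0, Dc)])

    pi_high = float(base_model.pi[1])
    gamma = np.zeros(D1.shape[1])
    gamma[0] = np.log(pi_high / (1 - pi_high))
    mu, sigma2 = base_model.mu.copy(), base_model.sigma2.copy()
    pi_inc = base_model.pi.copy()

    data, mask = X.X, X.mask
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        ll, P = _cond_loglik(gamma, mu, sigma2, pi_inc, data, mask, D1, complete)
        if ll - prev < tol and it > 0:
            converged = True
            prev = ll
            break
        prev = ll
        # M-step: measurement part over all rows, gamma over complete rows
        _, mu, sigma2 = _m_step(data, mask, P, base_model.variance_structure)
        gamma = _logistic_newton(D1[complete], P[complete, 1], gamma)
        if (~complete).any():
            pi_inc = P[~complete].mean(axis=0)
            pi_inc = np.clip(pi_inc, 1e-9, 1.0)
            pi_inc /= pi_inc.sum()
    ll, P = _cond_loglik(gamma, mu, sigma2, pi_inc, data, mask, D1, complete)

    q = n_parameters(K, data.shape[1], base_model.variance_structure) - (K - 1)
    q += D1.shape[1] + ((K - 1) if (~complete).any() else 0)

    gamma_se = None
    if compute_se:
        gamma_se = _gamma_standard_errors(
            gamma, mu, sigma2, pi_inc, data, mask, D1, complete
        )

    model = ConditionalLPAModel(
        K=K,
        gamma=gamma,
        gamma_names=["intercept"] + COVARIATE_ORDER,
        gamma_se=gamma_se,
        mu=mu,
        sigma2=sigma2,
        pi_incomplete=pi_inc,
        loglik=ll,
        q=q,
        n_complete=int(complete.sum()),
        converged=converged,
        variance_structure=base_model.variance_structure,
        age_center=age_center,
    )
    post = PosteriorMatrix.from_probs(P)
    return _order_conditional(model, post)


def _order_conditional(model, P):
    """Relabel so class 1 = low-risk (high HDL); flip gamma if needed."""
    from .mixture import HDL_IDX

    if model.mu[0, HDL_IDX] >= model.mu[1, HDL_IDX]:
        return model, P
    model.mu = model.mu[::-1].copy()
    if np.ndim(model.sigma2) == 2:
        model.sigma2 = model.sigma2[::-1].copy()
    model.gamma = -model.gamma
    model.pi_incomplete = model.pi_incomplete[::-1].copy()
    return model, PosteriorMatrix.from_probs(P.probs[:, ::-1].copy())


def _pack(gamma, mu, sigma2, pi_inc):
    return np.concatenate(
        [gamma, mu.ravel(), np.log(np.atleast_1d(sigma2).ravel()),
         [np.log(pi_inc[1] / pi_inc[0])]]
    )


def _gamma_standard_errors(gamma, mu, sigma2, pi_inc, X, mask, D1, complete,
                           eps=1e-4):
    """SEs for gamma from the full observed information (central differences)."""
    ng, K, p = len(gamma), mu.shape[0], mu.shape[1]
    theta0 = _pack(gamma, mu, sigma2, pi_inc)

    def unpack(theta):
        g = theta[:ng]
        m = theta[ng:ng + K * p].reshape(K, p)
        s2 = np.exp(theta[ng + K * p:ng + K * p + np.atleast_1d(sigma2).size])
        s2 = s2.reshape(np.shape(sigma2))
        lp = theta[-1]
        pi1 = 1.0 / (1.0 + np.exp(-lp))
        return g, m, s2, np.array([1 - pi1, pi1])

    def f(theta):
        g, m, s2, pin = unpack(theta)
        return _cond_loglik(g, m, s2, pin, X, mask, D1, complete)[0]

    d = len(theta0)
    H = np.empty((d, d))
    f0 = f(theta0)
    # central second differences
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            if i == j:
                val = (f(theta0 + ei) - 2 * f0 + f(theta0 - ei)) / eps**2
            else:
                val = (
                    f(theta0 + ei + ej) - f(theta0 + ei - ej)
                    - f(theta0 - ei + ej) + f(theta0 - ei - ej)
                ) / (4 * eps**2)
            H[i, j] = H[j, i] = val
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    var = np.diag(cov)[:ng]
    return np.sqrt(np.maximum(var, 0.0))


def odds_ratios(model: ConditionalLPAModel) -> pd.DataFrame:
    """Wald odds-ratio table for high-risk class membership.

    Columns: OR, 95% CI, z p-value, confidence-limit ratio.  The education
    row is also reported in the low-risk direction (reciprocal OR).
    """
    if model.gamma_se is None:
        raise ValueError("model was fitted without standard errors")
    rows = []
    for name, g, se in zip(model.gamma_names, model.gamma, model.gamma_se):
        if name == "intercept":
            continue
        lo, hi = np.exp(g - 1.96 * se), np.exp(g + 1.96 * se)
        z = g / se if se > 0 else np.inf
        rows.append(
            {
                "covariate": name,
                "log_odds": g,
                "se": se,
                "odds_ratio": float(np.exp(g)),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "p_value": float(2 * stats.norm.sf(abs(z))),
                "clr": float(hi / lo),
            }
        )
    out = pd.DataFrame(rows)
    edu = out.loc[out.covariate == "education"].iloc[0]
    flip = edu.copy()
    flip["covariate"] = "education (low-risk direction)"
    flip["log_odds"] = -edu["log_odds"]
    flip["odds_ratio"] = 1.0 / edu["odds_ratio"]
    flip["ci_lower"] = 1.0 / edu["ci_upper"]
    flip["ci_upper"] = 1.0 / edu["ci_lower"]
    out = pd.concat([out, flip.to_frame().T], ignore_index=True)
    return out


def report_prevalence(
    model: ConditionalLPAModel,
    P: PosteriorMatrix,
    covariates: pd.DataFrame,
) -> dict:
    """Marginal class prevalences: model-implied prior mean and posterior mean."""
    D, complete = build_design(covariates)
    Dc = D.copy()
    Dc[:, 0] -= model.age_center
    D1 = np.column_stack([np.ones(len(Dc)), np.where(np.isnan(Dc), 0.0, Dc)])
    eta = D1 @ model.gamma
    prior_high = np.where(
        complete, 1.0 / (1.0 + np.exp(-eta)), model.pi_incomplete[1]
    )
    return {
        "model_implied": [float(1 - prior_high.mean()), float(prior_high.mean())],
        "posterior": [float(P.probs[:, 0].mean()), float(P.probs[:, 1].mean())],
    }
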
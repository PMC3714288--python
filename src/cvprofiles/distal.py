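"""Distal-outcome analyses: cognition compared across latent risk classes.

Two complementary analyses per cognitive factor score: (1) class-specific
means with a Wald chi-square (1 df) equality test, using either modal class
assignment (default, mirroring highest-posterior allocation) or
posterior-weighted means; (2) a post-hoc regression of the outcome on the
posterior probability of high-risk membership adjusting for age and education.
No three-step (BCH/ML) correction is applied; modal assignment attenuates
class contrasts, which the posterior-weighted mode quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import FACTORS


@dataclass
class DistalResult:
    outcome: str
    class_means: np.ndarray
    class_ses: np.ndarray
    chi2: float
    p_value: float
    n: int
    mode: str


@dataclass
class PosteriorRegressionResult:
    outcome: str
    slope: float
    slope_se: float
    slope_p: float
    covariate_coefs: dict
    n: int


def class_outcome_means(assignment, y, mode: str = "modal"):
    """Per-class means and SEs of an outcome.

    ``assignment`` is either an integer label vector (mode='modal') or an
    n x K posterior matrix (mode='weighted', linearized SEs).  Rows with a
    missing outcome are dropped.
    """
    y = np.asarray(y, float)
    keep = ~np.isnan(y)
    if mode == "modal":
        labels = np.asarray(assignment)[keep]
        yv = y[keep]
        K = int(labels.max()) + 1
        means, ses = np.empty(K), np.empty(K)
        for k in range(K):
            grp = yv[labels == k]
            if len(grp) < 2:
                raise ValueError(f"class {k} has fewer than 2 observed outcomes")
            means[k] = grp.mean()
            ses[k] = grp.std(ddof=1) / np.sqrt(len(grp))
    elif mode == "weighted":
        P = np.asarray(assignment, float)[keep]
        yv = y[keep]
        K = P.shape[1]
        means, ses = np.empty(K), np.empty(K)
        for k in range(K):
            w = P[:, k]
            sw = w.sum()
            if sw < 2:
                raise ValueError(f"class {k} has effective size < 2")
            means[k] = float(w @ yv / sw)
            ses[k] = float(np.sqrt((w**2 @ (yv - means[k]) ** 2)) / sw)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return means, ses, int(keep.sum())


def wald_equality_test(means, ses) -> tuple[float, float]:
    """Wald chi-square (1 df) for equality of two class means."""
    means = np.asarray(means, float)
    ses = np.asarray(ses, float)
    if means.shape != (2,) or ses.shape != (2,):
        raise ValueError("implemented for K = 2")
    if not np.all(np.isfinite(ses)):
        raise ValueError("non-finite standard errors")
    denom = ses[0] ** 2 + ses[1] ** 2
    diff = means[0] - means[1]
    if denom == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    chi2 = diff**2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def posterior_regression(
    y, p_high, covariates: pd.DataFrame | None = None
) -> PosteriorRegressionResult:
    """OLS of an outcome on P(high-risk), adjusting for age and education."""
    y = np.asarray(y, float)
    cols = {"p_high": np.asarray(p_high, float)}
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = covariates[c].to_numpy(float)
    Xdf = pd.DataFrame(cols)
    keep = ~(np.isnan(y) | Xdf.isna().any(axis=1).to_numpy())
    Xk = Xdf.loc[keep]
    for c in Xk.columns:
        if Xk[c].std(ddof=0) < 1e-12:
            raise ValueError(f"design column {c!r} is constant (collinear)")
    X = sm.add_constant(Xk, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        corr = Xk.corr().abs()
        np.fill_diagonal(corr.values, 0)
        a, b = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"collinear design columns: {corr.index[a]!r} and {corr.columns[b]!r}"
        )
    fit = sm.OLS(y[keep], X).fit()
    return PosteriorRegressionResult(
        outcome="",
        slope=float(fit.params["p_high"]),
        slope_se=float(fit.bse["p_high"]),
        slope_p=float(fit.pvalues["p_high"]),
        covariate_coefs={
            c: float(fit.params[c]) for c in Xk.columns if c != "p_high"
        },
        n=int(keep.sum()),
    )


def run_distal_suite(
    scores: pd.DataFrame,
    posterior,
    covariates: pd.DataFrame | None = None,
    mode: str = "modal",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Both analyses for every factor score; one row per outcome.

    ``scores`` rows must align positionally with the posterior matrix (its
    index gives the subject positions in the full cohort).  A Bonferroni
    column is printed for transparency; flags use unadjusted p-values.
    """
    probs = posterior.probs if hasattr(posterior, "probs") else np.asarray(posterior)
    labels = probs.argmax(axis=1)
    outcomes = [c for c in scores.columns if c in FACTORS] or list(scores.columns)
    n_total = probs.shape[0]
    if scores.index.max() >= n_total:
        raise ValueError("score rows do not align with the posterior matrix")
    rows = []
    m = len(outcomes)
    for out in outcomes:
        y_full = np.full(n_total, np.nan)
        y_full[scores.index.to_numpy()] = scores[out].to_numpy(float)
        assign = labels if mode == "modal" else probs
        means, ses, n_used = class_outcome_means(assign, y_full, mode=mode)
        chi2, p = wald_equality_test(means, ses)
        reg = posterior_regression(
            y_full,
            probs[:, 1],
            covariates,
        )
        rows.append(
            {
                "outcome": out,
                "mean_low_risk": means[0],
                "mean_high_risk": means[1],
                "se_low_risk": ses[0],
                "se_high_risk": ses[1],
                "wald_chi2": chi2,
                "wald_p": p,
                "wald_p_bonferroni": min(1.0, p * m),
                "significant": p < alpha,
                "posterior_slope": reg.slope,
                "posterior_slope_se": reg.slope_se,
                "posterior_slope_p": reg.slope_p,
                "n": n_used,
            }
        )
    return pd.DataFrame(rows)
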
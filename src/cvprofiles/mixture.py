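"""Gaussian latent profile analysis over the seven standardized risk indicators.

EM for a K-class mixture of diagonal Gaussians (local independence), with
full-information maximum likelihood over each subject's observed cells under
MAR.  Provides BIC, relative entropy, parametric bootstrap likelihood-ratio
class-enumeration tests and posterior (modal) class assignment.  Classes are
always reported in a fixed order — descending HDL-C mean — so class 1 is the
"low-risk" (high HDL) profile.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import INDICATORS

_LOG2PI = float(np.log(2.0 * np.pi))
HDL_IDX = INDICATORS.index("hdl")
TG_IDX = INDICATORS.index("triglycerides")


class FitError(RuntimeError):
    pass


@dataclass
class RiskMatrix:
    """Standardized indicator matrix with missingness mask and z-constants."""

    X: np.ndarray          # n x 7, z-scores, NaN where missing
    mask: np.ndarray       # n x 7 boolean, True = observed
    means: np.ndarray      # per-column standardization mean (raw units)
    sds: np.ndarray        # per-column standardization SD (raw units)
    columns: list = field(default_factory=lambda: list(INDICATORS))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def back_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sds + self.means


def standardize(cohort: pd.DataFrame, columns=None) -> RiskMatrix:
    """Column-wise z-scores of the indicator columns (analysis-sample moments)."""
    cols = list(columns) if columns is not None else list(INDICATORS)
    raw = cohort[cols].to_numpy(float)
    mask = ~np.isnan(raw)
    means = np.nanmean(raw, axis=0)
    sds = np.nanstd(raw, axis=0, ddof=0)
    if np.any(sds < 1e-12):
        bad = cols[int(np.argmin(sds))]
        raise ValueError(f"zero-variance indicator column {bad!r}")
    Z = (raw - means) / sds
    return RiskMatrix(X=Z, mask=mask, means=means, sds=sds, columns=cols)


@dataclass
class LPAModel:
    K: int
    pi: np.ndarray           # mixing weights, length K
    mu: np.ndarray           # K x 7 class means (standardized scale)
    sigma2: np.ndarray       # 7 (class-invariant) or K x 7 (class-varying)
    loglik: float
    q: int
    variance_structure: str = "varying"
    n_starts_used: int = 0
    best_start_seed: int = -1
    converged: bool = False

    def class_sigma2(self) -> np.ndarray:
        """Variances broadcast to K x 7."""
        s = np.asarray(self.sigma2, float)
        return np.broadcast_to(s, (self.K, s.shape[-1])) if s.ndim == 1 else s


@dataclass
class PosteriorMatrix:
    probs: np.ndarray        # n x K
    labels: np.ndarray       # modal assignment, ties to the lowest index
    max_prob: np.ndarray

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "PosteriorMatrix":
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("posterior rows must sum to 1")
        return cls(
            probs=probs,
            labels=np.argmax(probs, axis=1),
            max_prob=probs.max(axis=1),
        )


def _log_components(X, mask, mu, sigma2_k):
    """n x K matrix of per-class log densities over observed cells only."""
    n, p = X.shape
    K = mu.shape[0]
    out = np.zeros((n, K))
    Xf = np.where(mask, X, 0.0)
    for k in range(K):
        s2 = sigma2_k[k]
        ll = -0.5 * (_LOG2PI + np.log(s2)) - 0.5 * (Xf - mu[k]) ** 2 / s2
        out[:, k] = np.where(mask, ll, 0.0).sum(axis=1)
    return out


def loglik(model: LPAModel, X: RiskMatrix) -> float:
    """Observed-data log-likelihood via log-sum-exp."""
    s2 = model.class_sigma2()
    if np.any(s2 <= 0):
        raise ValueError("variances must be positive")
    lc = _log_components(X.X, X.mask, model.mu, s2) + np.log(model.pi)
    m = lc.max(axis=1, keepdims=True)
    return float((m.ravel() + np.log(np.exp(lc - m).sum(axis=1))).sum())


def _posterior(pi, mu, sigma2_k, X, mask, log_prior_rows=None):
    lc = _log_components(X, mask, mu, sigma2_k)
    lc = lc + (np.log(pi) if log_prior_rows is None else log_prior_rows)
    m = lc.max(axis=1, keepdims=True)
    w = np.exp(lc - m)
    tot = w.sum(axis=1, keepdims=True)
    ll = float((m.ravel() + np.log(tot.ravel())).sum())
    return w / tot, ll


def _m_step(X, mask, P, variance_structure, var_floor=1e-6):
    n, p = X.shape
    K = P.shape[1]
    Xf = np.where(mask, X, 0.0)
    mu = np.empty((K, p))
    denom = np.empty((K, p))
    for k in range(K):
        w = P[:, k][:, None] * mask
        denom[k] = w.sum(axis=0)
        mu[k] = (P[:, k][:, None] * Xf).sum(axis=0) / np.maximum(denom[k], 1e-12)
    if variance_structure == "invariant":
        ss = np.zeros(p)
        for k in range(K):
            ss += (P[:, k][:, None] * mask * (Xf - mu[k]) ** 2).sum(axis=0)
        sigma2 = np.maximum(ss / mask.sum(axis=0), var_floor)
    else:
        sigma2 = np.empty((K, p))
        for k in range(K):
            ss = (P[:, k][:, None] * mask * (Xf - mu[k]) ** 2).sum(axis=0)
            sigma2[k] = np.maximum(ss / np.maximum(denom[k], 1e-12), var_floor)
    pi = P.mean(axis=0)
    return pi, mu, sigma2


def _random_start(X, mask, K, rng):
    n = X.shape[0]
    pooled_mu = np.nanmean(np.where(mask, X, np.nan), axis=0)
    pooled_s2 = np.nanvar(np.where(mask, X, np.nan), axis=0, ddof=0)
    idx = rng.choice(n, size=K, replace=False)
    mu = np.where(mask[idx], X[idx], pooled_mu)
    return np.full(K, 1.0 / K), mu, pooled_s2.copy()


def _run_em(pi, mu, sigma2, X, mask, variance_structure, tol, max_iter,
            check_monotone=False):
    s2k = np.broadcast_to(sigma2, (len(pi), X.shape[1])) if np.ndim(sigma2) == 1 else sigma2
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        P, ll = _posterior(pi, mu, s2k, X, mask)
        if check_monotone and ll < prev - 1e-8:
            raise FitError(f"EM log-likelihood decreased at iteration {it}")
        if np.any(P.mean(axis=0) < 1e-6):
            return pi, mu, sigma2, P, ll, False, True  # empty class
        pi, mu, sigma2 = _m_step(X, mask, P, variance_structure)
        s2k = (
            np.broadcast_to(sigma2, (len(pi), X.shape[1]))
            if np.ndim(sigma2) == 1
            else sigma2
        )
        if ll - prev < tol and it > 0:
            converged = True
            prev = ll
            break
        prev = ll
    P, ll = _posterior(pi, mu, s2k, X, mask)
    return pi, mu, sigma2, P, ll, converged, False


def n_parameters(K: int, p: int = 7, variance_structure: str = "varying") -> int:
    return (K - 1) + K * p + (p if variance_structure == "invariant" else K * p)


def fit_lpa(
    X: RiskMatrix,
    K: int,
    n_starts: int = 50,
    tol: float = 1e-7,
    max_iter: int = 2000,
    seed: int = 0,
    variance_structure: str = "varying",
    check_monotone: bool = False,
) -> tuple[LPAModel, PosteriorMatrix]:
    """Fit the K-class profile model by multistart EM (FIML over observed cells).

    ``n_starts`` random initializations (means drawn from random subjects,
    pooled variances) run 20 burn-in iterations; the best five continue to
    convergence and the top solution is kept.  Classes are relabeled by
    :func:`order_classes`.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if X.n < 10 * K:
        raise ValueError(f"need n >= 10*K subjects (n={X.n}, K={K})")
    if variance_structure not in ("invariant", "varying"):
        raise ValueError("variance_structure must be 'invariant' or 'varying'")

    data, mask = X.X, X.mask
    rng = np.random.default_rng(seed)

    if K == 1:
        pi = np.ones(1)
        mu = np.nanmean(np.where(mask, data, np.nan), axis=0)[None, :]
        sigma2 = np.nanvar(np.where(mask, data, np.nan), axis=0, ddof=0)
        if variance_structure == "varying":
            sigma2 = sigma2[None, :]
        model = LPAModel(
            K=1, pi=pi, mu=mu, sigma2=sigma2, loglik=0.0,
            q=n_parameters(1, data.shape[1], variance_structure),
            variance_structure=variance_structure,
            n_starts_used=1, best_start_seed=seed, converged=True,
        )
        model.loglik = loglik(model, X)
        P = PosteriorMatrix.from_probs(np.ones((X.n, 1)))
        return model, P

    burn = []
    attempts = 0
    start_idx = 0
    while len(burn) < n_starts and attempts < 4 * n_starts:
        attempts += 1
        start_seed = start_idx
        start_idx += 1
        sub = np.random.default_rng(rng.integers(2**31))
        pi0, mu0, s20 = _random_start(data, mask, K, sub)
        res = _run_em(pi0, mu0, s20, data, mask, variance_structure,
                      tol=1e-4, max_iter=20)
        if res[6]:  # empty class: discard this start
            continue
        burn.append((res[4], start_seed, res[:3]))
    if not burn:
        raise FitError("all EM starts collapsed to an empty class")
    burn.sort(key=lambda t: -t[0])

    best = None
    for ll_burn, start_seed, (pi0, mu0, s20) in burn[:5]:
        pi1, mu1, s21, P1, ll1, conv, empty = _run_em(
            pi0, mu0, s20, data, mask, variance_structure, tol, max_iter,
            check_monotone=check_monotone,
        )
        if empty:
            continue
        if best is None or ll1 > best[0]:
            best = (ll1, start_seed, pi1, mu1, s21, P1, conv)
    if best is None:
        raise FitError("no EM start converged without an empty class")
    ll1, start_seed, pi1, mu1, s21, P1, conv = best

    model = LPAModel(
        K=K, pi=pi1, mu=mu1, sigma2=s21, loglik=ll1,
        q=n_parameters(K, data.shape[1], variance_structure),
        variance_structure=variance_structure,
        n_starts_used=len(burn), best_start_seed=start_seed, converged=conv,
    )
    P = PosteriorMatrix.from_probs(P1)
    return order_classes(model, P)


def order_classes(
    model: LPAModel, P: PosteriorMatrix
) -> tuple[LPAModel, PosteriorMatrix]:
    """Sort classes by HDL-C mean descending (class 1 = low-risk, high HDL).

    Exact HDL ties break by ascending triglycerides mean.  Idempotent.
    """
    p = model.mu.shape[1]
    key_col = HDL_IDX if p > HDL_IDX else 0
    tie_col = TG_IDX if p > TG_IDX else key_col
    keys = list(zip(-model.mu[:, key_col], model.mu[:, tie_col], range(model.K)))
    order = [k for *_, k in sorted(keys)]
    order = np.array(order)
    if np.all(order == np.arange(model.K)):
        return model, P
    sigma2 = model.sigma2[order] if np.ndim(model.sigma2) == 2 else model.sigma2
    new_model = dataclasses.replace(
        model, pi=model.pi[order], mu=model.mu[order], sigma2=sigma2
    )
    new_P = PosteriorMatrix.from_probs(P.probs[:, order])
    return new_model, new_P


def relative_entropy(P: PosteriorMatrix) -> float:
    """E = 1 - sum_i sum_k (-p ln p) / (n ln K); 1 = perfect separation."""
    probs = P.probs
    n, K = probs.shape
    if K < 2:
        raise ValueError("relative entropy needs K >= 2")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


def bic(model: LPAModel, n: int) -> float:
    return float(-2.0 * model.loglik + model.q * np.log(n))


def _simulate_from_model(model: LPAModel, mask: np.ndarray, rng) -> RiskMatrix:
    """Parametric draw with the same n and missingness pattern as ``mask``."""
    n, p = mask.shape
    cls = rng.choice(model.K, size=n, p=model.pi)
    s2 = model.class_sigma2()
    X = model.mu[cls] + np.sqrt(s2[cls]) * rng.standard_normal((n, p))
    X = np.where(mask, X, np.nan)
    return RiskMatrix(X=X, mask=mask.copy(), means=np.zeros(p), sds=np.ones(p))


@dataclass
class EnumerationResult:
    table: pd.DataFrame
    selected_K: int
    rationale: str
    models: dict = field(default_factory=dict)
    posteriors: dict = field(default_factory=dict)


def bootstrap_lrt(
    X: RiskMatrix,
    K: int,
    B: int = 99,
    seed: int = 0,
    n_starts: int = 20,
    inner_starts: int = 5,
    max_failure_rate: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> dict:
    """Parametric bootstrap LRT of K classes against K-1.

    The observed statistic is 2(loglik_K - loglik_{K-1}); the null reference
    distribution is built by refitting both models to B datasets simulated
    from the fitted (K-1)-class model with matching n and missingness pattern.
    p = (1 + #{LR_b >= LR}) / (B + 1).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if B < 19:
        raise ValueError("B must be >= 19")
    rng = np.random.default_rng(seed)
    m0, _ = fit_lpa(X, K - 1, n_starts=n_starts, seed=seed, tol=tol,
                    max_iter=max_iter)
    m1, _ = fit_lpa(X, K, n_starts=n_starts, seed=seed, tol=tol,
                    max_iter=max_iter)
    lr_obs = max(0.0, 2.0 * (m1.loglik - m0.loglik))
    lr_boot = []
    failures = 0
    for b in range(B):
        Xb = _simulate_from_model(m0, X.mask, rng)
        try:
            b0, _ = fit_lpa(Xb, K - 1, n_starts=inner_starts,
                            seed=int(rng.integers(2**31)), tol=tol,
                            max_iter=max_iter)
            b1, _ = fit_lpa(Xb, K, n_starts=inner_starts,
                            seed=int(rng.integers(2**31)), tol=tol,
                            max_iter=max_iter)
            lr_boot.append(max(0.0, 2.0 * (b1.loglik - b0.loglik)))
        except FitError:
            failures += 1
            if failures > max_failure_rate * B:
                raise FitError(
                    f"bootstrap refit failed in {failures}/{b + 1} replicates"
                )
    lr_boot = np.array(lr_boot)
    p = (1.0 + np.sum(lr_boot >= lr_obs)) / (len(lr_boot) + 1.0)
    return {
        "K": K,
        "lr": lr_obs,
        "B": len(lr_boot),
        "p_value": float(p),
        "failures": failures,
    }


def enumerate_classes(
    X: RiskMatrix,
    K_max: int = 3,
    B: int = 99,
    seed: int = 0,
    n_starts: int = 50,
    alpha: float = 0.05,
    min_class_share: float = 0.05,
    entropy_drop: float = 0.05,
    run_blrt: bool = True,
) -> EnumerationResult:
    """Fit K = 1..K_max, tabulate BIC / entropy / BLRT, select K.

    Selection rule: K+1 replaces K only when its BLRT against K is
    significant at ``alpha``, every class holds at least ``min_class_share``
    of the sample, and classification quality does not degrade materially
    (relative entropy may not fall more than ``entropy_drop`` below the
    current solution's).  The full table is returned so the rule can be
    overridden.
    """
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    rows = []
    models, posteriors = {}, {}
    for K in range(1, K_max + 1):
        m, P = fit_lpa(X, K, n_starts=n_starts, seed=seed)
        models[K], posteriors[K] = m, P
        rows.append(
            {
                "K": K,
                "loglik": m.loglik,
                "q": m.q,
                "BIC": bic(m, X.n),
                "entropy": relative_entropy(P) if K > 1 else np.nan,
                "min_class_share": float(m.pi.min()),
                "blrt_lr": np.nan,
                "blrt_p": np.nan,
            }
        )
    if run_blrt:
        for K in range(2, K_max + 1):
            res = bootstrap_lrt(X, K, B=B, seed=seed + K, n_starts=n_starts)
            rows[K - 1]["blrt_lr"] = res["lr"]
            rows[K - 1]["blrt_p"] = res["p_value"]
    table = pd.DataFrame(rows)

    selected = 1
    reason = "1-class baseline"
    for K in range(2, K_max + 1):
        row = table.loc[table.K == K].iloc[0]
        sig = (not run_blrt) or (row.blrt_p <= alpha)
        prev_entropy = (
            table.loc[table.K == selected, "entropy"].iloc[0]
            if selected > 1
            else -np.inf
        )
        entropy_ok = row.entropy >= prev_entropy - entropy_drop
        if sig and row.min_class_share >= min_class_share and entropy_ok:
            selected = K
            reason = (
                f"{K}-class solution supported "
                f"(BLRT p={row.blrt_p if run_blrt else float('nan'):.4g}, "
                f"min class share {row.min_class_share:.3f}, "
                f"entropy {row.entropy:.3f})"
            )
        else:
            break
    return EnumerationResult(
        table=table, selected_K=selected, rationale=reason,
        models=models, posteriors=posteriors,
    )
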
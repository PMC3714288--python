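"""Bi-factor confirmatory factor model for the 18-test cognitive battery.

One general (global cognition) factor loads on all tests; four orthogonal
specific factors (verbal learning & memory, auditory attention & working
memory, visual attention & executive function, speeded language & mental
flexibility) load on disjoint test subsets.  Factors have unit variance
(identification), loadings and residual variances are free, and the model is
fitted by minimizing the ML discrepancy

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

with an analytic gradient.  Fit indices (CFI / TLI / RMSEA / BIC) follow the
conventional T = (n-1) F_ML chi-square scaling; factor scores use the
regression method by default with Bartlett scoring behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import DEFAULT_BATTERY, FACTORS


class CFAError(RuntimeError):
    pass


@dataclass(frozen=True)
class BifactorStructure:
    """Indicator names plus the indicator -> specific-factor mapping."""

    indicators: tuple
    specific_map: dict  # factor name -> tuple of indicator names

    def __post_init__(self):
        seen = []
        for fac, tests in self.specific_map.items():
            if len(tests) < 2:
                raise ValueError(
                    f"specific factor {fac!r} needs >= 2 indicators"
                )
            seen.extend(tests)
        # an empty specific_map is the single-factor comparator
        if self.specific_map and (
            sorted(seen) != sorted(self.indicators) or len(set(seen)) != len(seen)
        ):
            raise ValueError(
                "specific-factor subsets must be disjoint and cover all indicators"
            )

    @property
    def factor_names(self) -> list:
        return ["general"] + list(self.specific_map)

    def pattern(self) -> np.ndarray:
        """Boolean p x m loading-support matrix (column 0 = general)."""
        p = len(self.indicators)
        m = 1 + len(self.specific_map)
        pat = np.zeros((p, m), dtype=bool)
        pat[:, 0] = True
        idx = {name: i for i, name in enumerate(self.indicators)}
        for j, tests in enumerate(self.specific_map.values(), start=1):
            for t in tests:
                pat[idx[t], j] = True
        return pat


def default_structure() -> BifactorStructure:
    return BifactorStructure(
        indicators=tuple(t for ts in DEFAULT_BATTERY.values() for t in ts),
        specific_map={k: tuple(v) for k, v in DEFAULT_BATTERY.items()},
    )


@dataclass
class BifactorModel:
    structure: BifactorStructure
    loadings: np.ndarray       # p x m, zeros fixed by structure
    residuals: np.ndarray      # p
    loglik: float
    q: int
    n: int
    F_ml: float
    S: np.ndarray = field(repr=False, default=None)
    converged: bool = False
    heywood: list = field(default_factory=list)

    def implied_covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.residuals)


def _f_ml_and_grad(x, pattern, S, logdet_S, theta_floor):
    p, m = pattern.shape
    nload = int(pattern.sum())
    lam = np.zeros((p, m))
    lam[pattern] = x[:nload]
    theta = x[nload:]
    sigma = lam @ lam.T + np.diag(theta)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(x)
    inv = np.linalg.inv(sigma)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    f = logdet + float(np.trace(S @ inv)) - logdet_S - p
    G = inv - inv @ S @ inv      # dF/dSigma
    g_lam = 2.0 * (G @ lam)
    grad = np.concatenate([g_lam[pattern], np.diag(G)])
    return f, grad


def _initial_values(pattern, S):
    p, m = pattern.shape
    vals, vecs = np.linalg.eigh(S)
    v1 = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-6))
    if v1.sum() < 0:
        v1 = -v1
    lam0 = np.zeros((p, m))
    lam0[:, 0] = np.where(pattern[:, 0], v1, 0.0)
    for j in range(1, m):
        lam0[pattern[:, j], j] = 0.3
    theta0 = np.maximum(np.diag(S) - (lam0**2).sum(axis=1), 0.3 * np.diag(S))
    return lam0, theta0


def fit_bifactor(
    data,
    structure: BifactorStructure | None = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
    theta_floor: float = 1e-3,
    n_restarts: int = 3,
    seed: int = 0,
) -> BifactorModel:
    """ML fit of the structured factor model to an n x p score matrix.

    ``data`` may be a DataFrame (columns selected by the structure's
    indicator names) or an ndarray in structure order; rows with missing
    cells are dropped.  Heywood cases are floored at ``theta_floor`` with a
    warning naming the indicator.
    """
    if structure is None:
        structure = default_structure()
    if isinstance(data, pd.DataFrame):
        Y = data[list(structure.indicators)].to_numpy(float)
    else:
        Y = np.asarray(data, float)
    Y = Y[~np.isnan(Y).any(axis=1)]
    n, p = Y.shape
    pattern = structure.pattern()
    nload = int(pattern.sum())
    q = nload + p
    if n <= q:
        raise CFAError(f"need n > {q} complete rows, got {n}")
    S = np.cov(Y, rowvar=False, ddof=1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise CFAError("sample covariance is not positive definite")

    lam0, theta0 = _initial_values(pattern, S)
    x0 = np.concatenate([lam0[pattern], theta0])
    bounds = [(None, None)] * nload + [(theta_floor, None)] * p
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts):
        res = optimize.minimize(
            _f_ml_and_grad,
            x0,
            args=(pattern, S, logdet_S, theta_floor),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        x0 = np.concatenate([lam0[pattern], theta0]) * (
            1.0 + 0.1 * rng.standard_normal(nload + p)
        )
    res = best

    lam = np.zeros((p, pattern.shape[1]))
    lam[pattern] = res.x[:nload]
    # sign convention: majority-positive general loadings
    for j in range(lam.shape[1]):
        col = lam[pattern[:, j], j]
        if col.sum() < 0:
            lam[:, j] = -lam[:, j]
    theta = res.x[nload:]
    heywood = [
        structure.indicators[i]
        for i in range(p)
        if theta[i] <= theta_floor * 1.001
    ]
    if heywood:
        warnings.warn(
            f"Heywood case: residual variance floored for {heywood}",
            RuntimeWarning,
        )
    F = float(res.fun)
    # multivariate-normal loglik at the fitted covariance (ML divisor n)
    S_ml = S * (n - 1) / n
    sigma = lam @ lam.T + np.diag(theta)
    inv = np.linalg.inv(sigma)
    _, logdet = np.linalg.slogdet(sigma)
    ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + float(np.trace(S_ml @ inv)))
    model = BifactorModel(
        structure=structure,
        loadings=lam,
        residuals=theta,
        loglik=float(ll),
        q=q,
        n=n,
        F_ml=F,
        S=S,
        converged=bool(res.success),
        heywood=heywood,
    )
    if not res.success:
        warnings.warn("bi-factor optimization did not converge", RuntimeWarning)
    return model


@dataclass
class FitIndices:
    F_ml: float
    T: float
    df: int
    CFI: float
    TLI: float
    RMSEA: float
    BIC: float


def fit_indices(model: BifactorModel, S: np.ndarray | None = None,
                n: int | None = None) -> FitIndices:
    """CFI / TLI / RMSEA / BIC against the independence baseline."""
    S = model.S if S is None else S
    n = model.n if n is None else n
    p = S.shape[0]
    df = p * (p + 1) // 2 - model.q
    if df <= 0:
        raise ValueError("non-positive degrees of freedom; indices undefined")
    T = (n - 1) * model.F_ml
    # independence baseline: Sigma = diag(S)
    _, logdet_S = np.linalg.slogdet(S)
    F_b = float(np.log(np.diag(S)).sum() - logdet_S)
    T_b = (n - 1) * F_b
    df_b = p * (p - 1) // 2
    num = max(T - df, 0.0)
    cfi = 1.0 - num / max(T_b - df_b, num, 1e-12)
    tli = ((T_b / df_b) - (T / df)) / ((T_b / df_b) - 1.0)
    rmsea = float(np.sqrt(num / (df * (n - 1))))
    bic = -2.0 * model.loglik + model.q * np.log(n)
    return FitIndices(
        F_ml=model.F_ml, T=float(T), df=int(df), CFI=float(min(cfi, 1.0)),
        TLI=float(min(tli, 1.0)), RMSEA=rmsea, BIC=float(bic),
    )


def factor_scores(
    model: BifactorModel, data, method: str = "regression"
) -> pd.DataFrame:
    """Factor scores for rows with complete test data.

    Regression method (default): eta = Lambda' Sigma^-1 (y - ybar), shrunken
    toward zero; Bartlett: eta = (L' Th L)^-1 L' Th (y - ybar).
    """
    structure = model.structure
    if isinstance(data, pd.DataFrame):
        Y = data[list(structure.indicators)].to_numpy(float)
        index = data.index
    else:
        Y = np.asarray(data, float)
        index = pd.RangeIndex(len(Y))
    complete = ~np.isnan(Y).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(
            f"factor scores: {n_dropped} rows with missing tests excluded",
            RuntimeWarning,
        )
    Yc = Y[complete]
    centered = Yc - Yc.mean(axis=0)
    lam = model.loadings
    if method == "regression":
        W = lam.T @ np.linalg.inv(model.implied_covariance())
    elif method == "bartlett":
        Thi = np.diag(1.0 / model.residuals)
        W = np.linalg.solve(lam.T @ Thi @ lam, lam.T @ Thi)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    scores = centered @ W.T
    names = (
        FACTORS
        if len(model.structure.factor_names) == len(FACTORS)
        else model.structure.factor_names
    )
    return pd.DataFrame(scores, index=index[complete], columns=names)


def compare_models(fits: list) -> pd.DataFrame:
    """Rank (model, indices) pairs fitted to the same data by ascending BIC."""
    if not fits:
        raise ValueError("no models to compare")
    ref = fits[0][0]
    for m, _ in fits[1:]:
        if m.n != ref.n or m.S.shape != ref.S.shape or not np.allclose(m.S, ref.S):
            raise ValueError("models were fitted to different data")
    rows = []
    for pos, (m, idx) in enumerate(fits):
        rows.append(
            {
                "position": pos,
                "factors": len(m.structure.factor_names),
                "q": m.q,
                "BIC": idx.BIC,
                "CFI": idx.CFI,
                "TLI": idx.TLI,
                "RMSEA": idx.RMSEA,
                "meets_thresholds": bool(
                    idx.CFI > 0.95 and idx.TLI > 0.95 and idx.RMSEA < 0.05
                ),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["BIC", "position"], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def simulate_bifactor(model: BifactorModel, n: int, seed: int = 0,
                      return_factors: bool = False):
    """Draw n rows from the model (unit-variance orthogonal factors)."""
    rng = np.random.default_rng(seed)
    m = model.loadings.shape[1]
    eta = rng.standard_normal((n, m))
    eps = np.sqrt(model.residuals) * rng.standard_normal(
        (n, model.loadings.shape[0])
    )
    Y = eta @ model.loadings.T + eps
    return (Y, eta) if return_factors else Y


def single_factor_structure(indicators) -> "BifactorStructure":
    """Degenerate comparator: general factor only (no specific factors)."""
    return BifactorStructure(indicators=tuple(indicators), specific_map={})
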
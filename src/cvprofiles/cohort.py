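"""Synthetic cohort generator for the cardiovascular-risk latent-profile pipeline.

Generates cohorts of recently menopausal women with the statistical structure
the downstream analysis assumes: a two-class Gaussian mixture over seven
vascular-risk indicators (BMI, CIMT, LDL-C, HDL-C, triglycerides, fasting
glucose, Framingham point score), class membership driven by a logistic
concomitant model on age / education / ethnicity / APOE4, bi-factor-structured
cognitive test scores with class-dependent factor means, and a missing-at-random
mechanism affecting covariates and cognitive outcomes only.

Default parameters are calibrated to published class-conditional moments,
covariate odds ratios and pooled indicator correlations from a multi-site
baseline sample of recently menopausal women (n = 727, 62% / 38% class split).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.correlation_tools import corr_nearest

INDICATORS = ["bmi", "cimt", "ldl", "hdl", "triglycerides", "fbg", "fps"]
ETHNICITIES = ["non-Hispanic White", "non-Hispanic Black", "Hispanic"]
FACTORS = [
    "global_cognition",
    "verbal_memory",
    "auditory_attention_wm",
    "visual_attention_exec",
    "speeded_language",
]
#: Total-sample factor-score SDs (global, verbal, auditory, visual, speeded).
FACTOR_SDS = np.array([0.88, 0.87, 0.75, 0.73, 0.79])

# Class-conditional observed moments of the seven indicators, low-risk class
# first (high HDL-C), in INDICATORS order.
CLASS_MEANS = np.array(
    [
        [24.80, 0.70, 121.89, 74.13, 66.73, 87.31, 2.16],
        [28.97, 0.74, 138.35, 51.22, 129.26, 92.73, 6.89],
    ]
)
CLASS_SDS = np.array(
    [
        [3.88, 0.07, 28.91, 15.20, 25.74, 8.46, 2.25],
        [3.73, 0.10, 28.23, 9.80, 60.24, 9.78, 2.14],
    ]
)

# Pooled (total-sample) Pearson correlations among the seven indicators.
POOLED_CORR = np.array(
    [
        [1.000, 0.057, 0.157, -0.336, 0.330, 0.276, 0.376],
        [0.057, 1.000, 0.030, -0.046, 0.073, -0.018, 0.152],
        [0.157, 0.030, 1.000, -0.129, 0.231, 0.068, 0.399],
        [-0.336, -0.046, -0.129, 1.000, -0.486, -0.200, -0.485],
        [0.330, 0.073, 0.231, -0.486, 1.000, 0.214, 0.458],
        [0.276, -0.018, 0.068, -0.200, 0.214, 1.000, 0.238],
        [0.376, 0.152, 0.399, -0.485, 0.458, 0.238, 1.000],
    ]
)

#: Conditional odds ratios for high-risk class membership (reference:
#: below-college education, non-Hispanic White, APOE4 absent); age per year.
CONCOMITANT_ORS = {
    "age": 1.140,
    "education": 0.627,
    "eth_black": 0.951,
    "eth_hispanic": 2.621,
    "apoe4": 1.521,
}
COVARIATE_TERMS = list(CONCOMITANT_ORS)

#: 18-variable cognitive battery mapped onto four specific domains.  The test
#: names are a synthetic stand-in consistent with the published four-domain
#: bi-factor structure (the exact 18-test list is in unavailable supplements).
DEFAULT_BATTERY = {
    "verbal_memory": [
        "list_learning_total",
        "list_short_delay",
        "list_long_delay",
        "list_recognition",
        "paragraph_recall",
    ],
    "auditory_attention_wm": [
        "digit_span_forward",
        "digit_span_backward",
        "letter_number_sequencing",
        "serial_addition",
    ],
    "visual_attention_exec": [
        "trails_a",
        "trails_b",
        "symbol_digit",
        "card_rotations",
    ],
    "speeded_language": [
        "letter_fluency_c",
        "letter_fluency_f",
        "letter_fluency_l",
        "category_fluency_animals",
        "category_fluency_vegetables",
    ],
}
COGNITIVE_TESTS = [t for tests in DEFAULT_BATTERY.values() for t in tests]


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be met."""


def _default_loadings() -> tuple[np.ndarray, np.ndarray]:
    """Structured 18x5 loading matrix (general + 4 specific) and residuals.

    Loadings vary across rows for realism; residual variances are set so each
    test score has unit total variance when factor variances equal FACTOR_SDS².
    """
    n_tests = len(COGNITIVE_TESTS)
    lam = np.zeros((n_tests, 5))
    gen = [0.65, 0.72, 0.58, 0.68, 0.61, 0.70, 0.63, 0.66, 0.59, 0.74,
           0.62, 0.67, 0.71, 0.60, 0.69, 0.64, 0.73, 0.57]
    spec = [0.48, 0.52, 0.55, 0.40, 0.44, 0.50, 0.46, 0.42, 0.53, 0.38,
            0.49, 0.45, 0.41, 0.54, 0.47, 0.51, 0.39, 0.43]
    lam[:, 0] = gen
    row = 0
    for f_idx, (fac, tests) in enumerate(DEFAULT_BATTERY.items(), start=1):
        for _ in tests:
            lam[row, f_idx] = spec[row]
            row += 1
    fac_var = FACTOR_SDS**2
    theta = 1.0 - (lam**2) @ fac_var
    theta = np.maximum(theta, 0.2)
    return lam, theta


def _default_cognitive_shifts(prevalence: np.ndarray) -> np.ndarray:
    """Class-specific factor-mean shifts (2 x 5), centered at zero overall.

    The published low-minus-high differences (0.182 for global cognition,
    0.207 for speeded language & mental flexibility) are preserved and split
    so the prevalence-weighted mean of every factor is exactly zero.
    """
    diffs = np.array([0.182, 0.0, 0.0, 0.0, 0.207])
    low = prevalence[1] * diffs
    high = -prevalence[0] * diffs
    return np.vstack([low, high])


@dataclass
class GeneratorParams:
    """Full parameterization of the synthetic cohort generator."""

    n_subjects: int = 727
    class_prevalence: np.ndarray = field(
        default_factory=lambda: np.array([0.62, 0.38])
    )
    class_indicator_means: np.ndarray = field(
        default_factory=lambda: CLASS_MEANS.copy()
    )
    class_indicator_sds: np.ndarray = field(
        default_factory=lambda: CLASS_SDS.copy()
    )
    within_class_corr: np.ndarray = field(default_factory=lambda: np.eye(7))
    concomitant_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 0.0,
            **{k: float(np.log(v)) for k, v in CONCOMITANT_ORS.items()},
        }
    )
    covariate_dists: dict = field(
        default_factory=lambda: {
            "age": {"mean": 52.68, "sd": 2.60, "lower": 42.0, "upper": 58.0},
            "education": 0.735,
            "ethnicity": dict(
                zip(ETHNICITIES, (np.array([0.805, 0.078, 0.077]) / 0.960))
            ),
            "apoe4": 0.262,
        }
    )
    cognitive_class_means: np.ndarray = field(
        default_factory=lambda: _default_cognitive_shifts(
            np.array([0.62, 0.38])
        )
    )
    cognitive_factor_sds: np.ndarray = field(
        default_factory=lambda: FACTOR_SDS.copy()
    )
    bifactor_loadings: np.ndarray = None
    bifactor_residuals: np.ndarray = None
    missing_rate: float = 0.22
    fps_mode: str = "direct"  # "direct" (class-conditional) or "derived"
    seed: int = 0
    corr_adjustment: float = 0.0  # PSD-projection magnitude, set by calibration

    def __post_init__(self):
        if self.bifactor_loadings is None or self.bifactor_residuals is None:
            lam, theta = _default_loadings()
            if self.bifactor_loadings is None:
                self.bifactor_loadings = lam
            if self.bifactor_residuals is None:
                self.bifactor_residuals = theta

    def validate(self) -> None:
        pi = np.asarray(self.class_prevalence, float)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("class_prevalence must be positive and sum to 1")
        R = np.asarray(self.within_class_corr, float)
        if R.shape != (7, 7) or not np.allclose(R, R.T):
            raise ValueError("within_class_corr must be symmetric 7x7")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("within_class_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("within_class_corr must be positive semi-definite")
        w = pi @ np.asarray(self.cognitive_class_means, float)
        if np.any(np.abs(w) > 1e-9):
            raise ValueError("cognitive class means must center at 0 overall")
        lam = np.asarray(self.bifactor_loadings, float)
        if np.any(lam[:, 0] == 0):
            raise ValueError("general factor must load on all tests")
        support = lam[:, 1:] != 0
        if np.any(support.sum(axis=1) != 1):
            raise ValueError("each test must load on exactly one specific factor")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    def copy(self) -> "GeneratorParams":
        return dataclasses.replace(
            self,
            class_prevalence=self.class_prevalence.copy(),
            class_indicator_means=self.class_indicator_means.copy(),
            class_indicator_sds=self.class_indicator_sds.copy(),
            within_class_corr=self.within_class_corr.copy(),
            concomitant_coefs=dict(self.concomitant_coefs),
            covariate_dists=json.loads(json.dumps(self.covariate_dists)),
            cognitive_class_means=self.cognitive_class_means.copy(),
            cognitive_factor_sds=self.cognitive_factor_sds.copy(),
            bifactor_loadings=self.bifactor_loadings.copy(),
            bifactor_residuals=self.bifactor_residuals.copy(),
        )

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        d = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        return json.dumps(d, indent=2, sort_keys=True)


def default_params(
    n_subjects: int = 727, calibrate: bool = True, seed: int = 0
) -> GeneratorParams:
    """Paper-calibrated generator defaults.

    With ``calibrate=True`` (default) the within-class correlation matrix is
    solved from the pooled correlation targets and the concomitant intercept
    is tuned so the marginal high-risk prevalence is 38%.
    """
    params = GeneratorParams(n_subjects=n_subjects, seed=seed)
    if calibrate:
        params = calibrate_correlations(params, POOLED_CORR)
        params = calibrate_intercept(params)
    params.validate()
    return params


def _age_quadrature(dist: dict, n_nodes: int = 64):
    """Gauss-Legendre nodes/weights for the truncated-normal age marginal."""
    lo, hi = dist["lower"], dist["upper"]
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    ages = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    a, b = (lo - dist["mean"]) / dist["sd"], (hi - dist["mean"]) / dist["sd"]
    dens = stats.truncnorm.pdf(ages, a, b, loc=dist["mean"], scale=dist["sd"])
    weights = 0.5 * (hi - lo) * w * dens
    return ages, weights / weights.sum()


def marginal_high_risk_probability(params: GeneratorParams) -> float:
    """E[P(high-risk | covariates)] by numerical integration of the marginals."""
    g = params.concomitant_coefs
    dists = params.covariate_dists
    ages, aw = _age_quadrature(dists["age"])
    p_edu = dists["education"]
    p_eth = [dists["ethnicity"][e] for e in ETHNICITIES]
    p_apoe = dists["apoe4"]
    total = 0.0
    for edu, we in ((0, 1 - p_edu), (1, p_edu)):
        for eth_i, wt in enumerate(p_eth):
            for apoe, wa in ((0, 1 - p_apoe), (1, p_apoe)):
                eta = (
                    g["intercept"]
                    + g["age"] * ages
                    + g["education"] * edu
                    + g["eth_black"] * (eth_i == 1)
                    + g["eth_hispanic"] * (eth_i == 2)
                    + g["apoe4"] * apoe
                )
                total += we * wt * wa * float(aw @ (1.0 / (1.0 + np.exp(-eta))))
    return total


def calibrate_intercept(
    params: GeneratorParams, tol: float = 1e-8
) -> GeneratorParams:
    """Adjust the concomitant intercept so the marginal prevalence matches.

    Root-finds on the numerically integrated marginal P(high-risk) so that it
    equals ``class_prevalence[1]`` within ``tol``.
    """
    target = float(params.class_prevalence[1])
    out = params.copy()

    def f(c):
        out.concomitant_coefs["intercept"] = c
        return marginal_high_risk_probability(out) - target

    slopes = [v for k, v in params.concomitant_coefs.items() if k != "intercept"]
    center = float(np.log(target / (1 - target)))
    lo, hi = center - 30.0, center + 30.0
    if all(s == 0 for s in slopes):
        out.concomitant_coefs["intercept"] = center
        return out
    try:
        root = optimize.brentq(f, lo, hi, xtol=tol, maxiter=200)
    except ValueError as e:  # pragma: no cover - pathological slopes
        raise CalibrationError(f"intercept calibration failed: {e}") from e
    out.concomitant_coefs["intercept"] = float(root)
    if abs(marginal_high_risk_probability(out) - target) > max(tol, 1e-6):
        raise CalibrationError("intercept calibration did not converge")
    return out


def within_class_correlation(
    target_pooled: float,
    mu: np.ndarray,
    sd: np.ndarray,
    pi: np.ndarray,
    j: int,
    l: int,
) -> float:
    """Shared within-class correlation reproducing a pooled correlation.

    Inverts the mixture-moment identity
    pooled_cov = Σ_k π_k ρ_w σ_jk σ_lk + Σ_k π_k (μ_jk−μ̄_j)(μ_lk−μ̄_l)
    for ρ_w.
    """
    mbar = pi @ mu
    dev = mu - mbar
    between = float(pi @ (dev[:, j] * dev[:, l]))
    pooled_var = pi @ (sd**2 + dev**2)
    target_cov = target_pooled * np.sqrt(pooled_var[j] * pooled_var[l])
    within_scale = float(pi @ (sd[:, j] * sd[:, l]))
    return float((target_cov - between) / within_scale)


def calibrate_correlations(
    params: GeneratorParams, target_pooled_corr: np.ndarray
) -> GeneratorParams:
    """Solve the shared within-class correlation matrix from pooled targets.

    Per indicator pair the mixture-moment identity is inverted; the resulting
    matrix is projected to the nearest correlation matrix if it is not PSD,
    and the projection magnitude is stored on the returned params.
    """
    pi = np.asarray(params.class_prevalence, float)
    mu = np.asarray(params.class_indicator_means, float)
    sd = np.asarray(params.class_indicator_sds, float)
    T = np.asarray(target_pooled_corr, float)
    R = np.eye(7)
    for j in range(7):
        for l in range(j + 1, 7):
            r = within_class_correlation(T[j, l], mu, sd, pi, j, l)
            if abs(r) >= 1.0:
                pair = (INDICATORS[j], INDICATORS[l])
                raise CalibrationError(
                    f"infeasible pooled correlation for {pair}: "
                    f"requires within-class correlation {r:.3f}"
                )
            R[j, l] = R[l, j] = r
    adjustment = 0.0
    if np.linalg.eigvalsh(R).min() < 1e-10:
        R_psd = corr_nearest(R, threshold=1e-10)
        adjustment = float(np.abs(R_psd - R).max())
        R = R_psd
    out = params.copy()
    out.within_class_corr = R
    out.corr_adjustment = adjustment
    return out


def _draw_covariates(params: GeneratorParams, n: int, rng) -> pd.DataFrame:
    d = params.covariate_dists
    a = (d["age"]["lower"] - d["age"]["mean"]) / d["age"]["sd"]
    b = (d["age"]["upper"] - d["age"]["mean"]) / d["age"]["sd"]
    # inverse-CDF truncated-normal sampling
    u = rng.uniform(size=n)
    age = stats.truncnorm.ppf(u, a, b, loc=d["age"]["mean"], scale=d["age"]["sd"])
    education = (rng.uniform(size=n) < d["education"]).astype(int)
    eth_p = np.array([d["ethnicity"][e] for e in ETHNICITIES])
    ethnicity = rng.choice(len(ETHNICITIES), size=n, p=eth_p / eth_p.sum())
    apoe4 = (rng.uniform(size=n) < d["apoe4"]).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "education": education,
            "ethnicity": [ETHNICITIES[i] for i in ethnicity],
            "apoe4": apoe4,
        }
    )


def concomitant_linear_predictor(
    params: GeneratorParams, cov: pd.DataFrame
) -> np.ndarray:
    g = params.concomitant_coefs
    eth = cov["ethnicity"].to_numpy()
    return (
        g["intercept"]
        + g["age"] * cov["age"].to_numpy()
        + g["education"] * cov["education"].to_numpy()
        + g["eth_black"] * (eth == ETHNICITIES[1])
        + g["eth_hispanic"] * (eth == ETHNICITIES[2])
        + g["apoe4"] * cov["apoe4"].to_numpy()
    )


def _draw_fps_components(cls: np.ndarray, rng) -> pd.DataFrame:
    """Blood pressure, total cholesterol and smoking, consistent with class.

    Class-conditional marginals chosen so the pooled moments match the
    published totals (SBP 117.4±14.9, DBP 75.3±9.2, TC 208.1±33.7, 6.9%
    smokers) with the high-risk class shifted toward higher values.
    """
    n = len(cls)
    sbp_mean = np.where(cls == 1, 124.0, 113.4)
    dbp_mean = np.where(cls == 1, 79.0, 73.0)
    tc_mean = np.where(cls == 1, 221.0, 200.1)
    z = rng.multivariate_normal(np.zeros(2), [[1.0, 0.7], [0.7, 1.0]], size=n)
    dbp = dbp_mean + 8.5 * z[:, 0]
    pulse = np.maximum(5.0, (sbp_mean - dbp_mean) + 10.0 * z[:, 1])
    sbp = dbp + pulse
    tc = tc_mean + 32.0 * rng.standard_normal(n)
    tc = np.maximum(tc, 100.0)
    smoke_p = np.where(cls == 1, 0.10, 0.05)
    smoker = (rng.uniform(size=n) < smoke_p).astype(int)
    return pd.DataFrame(
        {"sbp": sbp, "dbp": dbp, "total_cholesterol": tc, "smoker": smoker}
    )


def simulate_cohort(params: GeneratorParams, seed: int | None = None) -> pd.DataFrame:
    """Draw a complete cohort (before missingness).

    Covariates from their marginals, true class from the concomitant logistic
    model, the seven indicators from the class-conditional multivariate normal
    with shared within-class correlation, Framingham-score components
    consistent with class, and cognitive scores from the bi-factor model with
    class-shifted factor means.
    """
    params.validate()
    if params.n_subjects < 4:
        raise ValueError("n_subjects must be at least 2 per class")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n = params.n_subjects

    cov = _draw_covariates(params, n, rng)
    eta = concomitant_linear_predictor(params, cov)
    p_high = 1.0 / (1.0 + np.exp(-eta))
    cls = (rng.uniform(size=n) < p_high).astype(int)

    L = np.linalg.cholesky(params.within_class_corr + 1e-12 * np.eye(7))
    z = rng.standard_normal((n, 7)) @ L.T
    mu = params.class_indicator_means[cls]
    sd = params.class_indicator_sds[cls]
    X = mu + z * sd
    # physical floors; binding with negligible probability under defaults
    X[:, INDICATORS.index("bmi")] = np.maximum(X[:, INDICATORS.index("bmi")], 12.0)
    X[:, INDICATORS.index("hdl")] = np.maximum(X[:, INDICATORS.index("hdl")], 5.0)
    tg = INDICATORS.index("triglycerides")
    X[:, tg] = np.maximum(X[:, tg], 5.0)
    X[:, INDICATORS.index("cimt")] = np.maximum(X[:, INDICATORS.index("cimt")], 0.3)

    comp = _draw_fps_components(cls, rng)

    df = pd.DataFrame(X, columns=INDICATORS)
    if params.fps_mode == "direct":
        df["fps"] = np.round(df["fps"]).astype(int)
    elif params.fps_mode == "derived":
        from .framingham import fps_column, load_point_table

        table = load_point_table()
        tmp = pd.concat([cov[["age"]], comp, df[["hdl"]]], axis=1)
        df["fps"] = fps_column(tmp, table)
    else:
        raise ValueError(f"unknown fps_mode {params.fps_mode!r}")

    # factor scores: class shift + within-class normal, total SD per factor
    shifts = params.cognitive_class_means
    pi = params.class_prevalence
    between = pi[0] * pi[1] * (shifts[0] - shifts[1]) ** 2
    within_sd = np.sqrt(np.maximum(params.cognitive_factor_sds**2 - between, 1e-6))
    etas = shifts[cls] + within_sd * rng.standard_normal((n, 5))
    tests = etas @ params.bifactor_loadings.T + np.sqrt(
        params.bifactor_residuals
    ) * rng.standard_normal((n, len(COGNITIVE_TESTS)))

    out = pd.concat(
        [
            pd.DataFrame({"subject_id": np.arange(1, n + 1)}),
            cov,
            pd.DataFrame({"true_class": cls}),
            df,
            comp,
            pd.DataFrame(tests, columns=COGNITIVE_TESTS),
            pd.DataFrame(etas, columns=[f"true_{f}" for f in FACTORS]),
        ],
        axis=1,
    )
    return out


def apply_missingness(
    cohort: pd.DataFrame, params: GeneratorParams, seed: int | None = None
) -> pd.DataFrame:
    """MAR missingness on covariates and cognitive outcomes.

    Each subject's probability of being incomplete depends only on age and
    education (always observed); the seven indicators are never blanked.
    Expected fraction of subjects with >= 1 missing cell = missing_rate.
    """
    if not (0.0 <= params.missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if params.missing_rate == 0.0:
        return cohort.copy()
    if seed is None:
        seed = params.seed + 1
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    zage = (out["age"] - out["age"].mean()) / out["age"].std(ddof=0)
    lin = 0.3 * zage.to_numpy() - 0.3 * out["education"].to_numpy()

    def mean_p(c):
        return np.mean(1.0 / (1.0 + np.exp(-(c + lin)))) - params.missing_rate

    c0 = optimize.brentq(mean_p, -20, 20)
    p_inc = 1.0 / (1.0 + np.exp(-(c0 + lin)))
    flagged = rng.uniform(size=n) < p_inc
    # among incomplete subjects, blank APOE4 and/or the cognitive battery at
    # rates mirroring the observed analytic sample sizes (596 and 662 of 727)
    blank_apoe = rng.uniform(size=n) < 0.82
    blank_cog = rng.uniform(size=n) < 0.40
    blank_apoe |= ~blank_cog
    blank_apoe &= flagged
    blank_cog &= flagged
    out.loc[blank_apoe, "apoe4"] = np.nan
    out.loc[blank_cog, COGNITIVE_TESTS] = np.nan
    return out


def write_cohort(cohort: pd.DataFrame, path, params: GeneratorParams | None = None,
                 seed: int | None = None) -> None:
    """Write the cohort CSV (empty string = missing) plus a JSON sidecar."""
    cohort.to_csv(path, index=False, na_rep="")
    if params is not None:
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            meta = json.loads(params.to_json())
            meta["simulation_seed"] = seed if seed is not None else params.seed
            json.dump(meta, fh, indent=2, sort_keys=True)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`.

    Empty cells are missing; a literal ``.`` token is rejected.  Numeric
    columns are validated cell-by-cell with row/column diagnostics.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], dtype=str)
    numeric = [c for c in df.columns if c not in ("ethnicity", "subject_id")]
    out = pd.DataFrame()
    if "subject_id" in df.columns:
        out["subject_id"] = pd.to_numeric(df["subject_id"]).astype(int)
    for col in df.columns:
        if col == "subject_id":
            continue
        if col == "ethnicity":
            out[col] = df[col]
            continue
        vals = df[col]
        bad = vals[vals.notna() & (vals.str.strip() == ".")]
        if len(bad):
            raise ValueError(
                f"missing-value token '.' at row {bad.index[0]}, column {col!r}"
            )
        try:
            out[col] = pd.to_numeric(vals)
        except (ValueError, TypeError):
            conv = pd.to_numeric(vals, errors="coerce")
            row = vals.index[conv.isna() & vals.notna()][0]
            raise ValueError(
                f"non-numeric value {vals[row]!r} at row {row}, column {col!r}"
            ) from None
    _ = numeric
    return out
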
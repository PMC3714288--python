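# Methods

`cvprofiles` implements a latent-profile characterization of cardiovascular
(CV) risk in recently menopausal women, end to end: a calibrated synthetic
cohort generator, Framingham point scoring, a Gaussian latent profile (LP)
model with concomitant covariates, a bi-factor cognitive measurement model
whose factor scores serve as distal outcomes, and a random-forest
cross-validation of the class solution.  This note records the models, their
assumptions, the defaults and why, and what the synthetic experiments do and
do not demonstrate.

## The latent profile model

The seven risk indicators (BMI, CIMT, LDL-C, HDL-C, triglycerides, fasting
glucose, Framingham point score) are standardized to z-scores using the
analysis sample's moments and modeled as a K-class finite mixture of
diagonal Gaussians:

    f(y_i) = Σ_k π_k Π_{j ∈ obs(i)} N(y_ij ; μ_jk, σ²_jk)

Local independence (diagonal within-class covariance) is assumed by the
model; the product runs over each subject's observed cells only, which is
full-information maximum likelihood under missing-at-random.  Estimation is
multistart EM: by default 50 random initializations (class means drawn from
random subjects, pooled variances) run 20 burn-in iterations, the best five
continue to convergence (absolute log-likelihood gain < 1e-7, max 2000
iterations), and the top solution is kept.  Empty-class collapses
(π_k < 1e-6) discard the start.  Label switching is resolved by sorting
classes on the HDL-C mean, descending, so class 1 is always the "low-risk"
(high-HDL) profile; exact ties break on the triglycerides mean.

**Variance structure.** The default is class-varying diagonal variances
(q = (K−1) + 7K + 7K).  The class-conditional spreads of the target
population differ strongly (triglyceride SDs of roughly 26 vs 60 mg/dL
between classes); forcing a shared variance is misspecified under those
conditions and biases the recovered low-risk prevalence upward by about
3 percentage points on default synthetic cohorts.  A class-invariant option
(`variance_structure="invariant"`, q = (K−1) + 7K + 7) remains available.

**Model selection.** For each K, the report tabulates log-likelihood, BIC
(−2·loglik + q·ln n) and relative entropy

    E = 1 − [Σ_i Σ_k (−p_ik ln p_ik)] / (n ln K),

1 for perfectly separated classes, 0 for uninformative posteriors.  The
analytic Lo–Mendell–Rubin adjusted LRT is replaced by a parametric bootstrap
LRT (BLRT): the observed statistic 2(loglik_K − loglik_{K−1}) is referred to
B refits on datasets simulated from the fitted (K−1)-class model with the
same n and missingness pattern, p = (1 + #{LR_b ≥ LR}) / (B + 1).  The LMR
approximation's closed form is implementation-specific and not reproducible
from published material; the BLRT is the standard, simulation-consistent
substitute, and shortened inner EM schedules keep it calibrated because the
observed and bootstrap statistics are computed by the identical procedure.
Enumeration accepts K+1 over K only if the BLRT is significant (α = 0.05),
every class holds ≥ 5% of the sample, and relative entropy does not fall
more than 0.05 below the current solution's — the entropy guard encodes the
"classification quality degrades" argument that favors two classes over a
marginally significant third on this kind of data.

## Concomitant (conditional) model

With K = 2, mixing weights are replaced by a subject-specific logistic
prior: logit P(high-risk | x_i) = γ₀ + γ'x_i with covariates age (years,
untransformed), education (college degree or higher vs below), ethnicity
(non-Hispanic Black and Hispanic vs non-Hispanic White) and APOE4 carrier
status.  The EM M-step for γ is a weighted logistic regression with the
posteriors as fractional responses (Newton iterations, ridge-stabilized with
a step cap against separation).  Subjects with incomplete covariates keep
contributing to the measurement part: they form a stratum with a free
mixing weight estimated as that stratum's mean posterior, which preserves a
proper, monotone ML algorithm while the logistic sub-model is complete-case.
Standard errors come from the observed information of the full observed-data
log-likelihood (central finite differences over γ, class means, log
variances and the stratum weight), and the odds-ratio table reports
exp(γ), Wald 95% CIs, two-sided z p-values and the confidence-limit ratio.
The education effect is reported in both directions (high-risk OR and its
reciprocal).  Age is centered internally for conditioning; reported slopes
are per raw year.

## Bi-factor cognitive model

Eighteen test scores load on one general factor (global cognition) and on
exactly one of four orthogonal specific factors (verbal learning & memory;
auditory attention & working memory; visual attention & executive function;
speeded language & mental flexibility).  Factors have unit variance
(identification); loadings and residual variances are free.  The fit
minimizes the ML discrepancy F_ML = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with
an analytic gradient (L-BFGS-B; residual variances bounded below at 1e-3
with a Heywood warning naming the indicator; jittered restarts on
non-convergence).  Fit indices use T = (n−1)·F_ML against the independence
baseline: CFI, TLI, RMSEA and BIC, with the conventional 0.95/0.95/0.05
adequacy thresholds.  Factor scores use the regression method
η̂ = Λ'Σ(θ)⁻¹(y − ȳ) (shrunken, variance ≤ 1) on complete rows only;
Bartlett scoring is available behind a flag.  Robust (sandwich) standard
errors for loadings are out of scope.  The shipped 18-test battery is a
synthetic stand-in with plausible test names: the four-domain structure is
faithful, the exact test list is not public.

## Distal outcomes

Each factor score is compared across classes two ways.  (1) Classes are
fixed at the modal (highest-posterior) assignment; class means and SEs feed
a Wald χ²(1) equality test, χ² = (m₁−m₂)²/(SE₁²+SE₂²).  A
posterior-weighted mode (means Σp_ik y_i/Σp_ik with linearized SEs)
quantifies sensitivity to classification error.  No three-step (BCH/ML)
correction is applied; modal assignment attenuates class contrasts toward
zero, which materially limits the power of the Wald test for the modest
cognitive shifts simulated here (roughly 50–60% at n = 727) — the test
suite asserts dominance of the shifted factor over the unshifted ones
rather than near-certain significance.  (2) A post-hoc OLS regression of
the outcome on P(high-risk), adjusting for age and education.  Unadjusted
p-values are flagged at α = 0.05; a Bonferroni column is printed for
transparency but not used for flags.

## Random-forest validation

Modal class labels are predicted from the seven standardized indicators by
a 1000-tree forest (√7 ≈ 2 features per split), with stratified 10-fold
cross-validated accuracy and out-of-bag error (scikit-learn backed).
Permutation importance — mean decrease in OOB accuracy — is computed over a
bagged ensemble with explicit per-tree OOB bookkeeping, since the library
forest does not expose OOB membership publicly.  The report states the
circularity plainly: the labels being predicted were derived from the same
indicators, so accuracy measures separability and stability of the class
solution, not external validity.

## Framingham point score and MAP

The women's categorical point system (total-cholesterol variant) ships as a
versioned JSON table: integer points for age, total cholesterol, HDL-C,
blood pressure, smoking and diabetes, summed.  Blood pressure classifies
SBP and DBP separately and lets the higher-risk category govern discordant
readings.  Diabetes points exist in the table but default to absent.  Out of
range inputs raise rather than clamp.  Mean arterial pressure uses the
standard one-third pulse pressure formula MAP = DBP + (SBP − DBP)/3; applied
to the published cohort mean pressures it gives 89.34 vs a printed 89.62 mm
Hg (per-subject rounding), so MAP is deliberately not a recovery target.

## Synthetic cohort generator

The generator emulates the baseline structure of a multi-site cohort of 727
recently menopausal women.  Defaults: two classes at 62%/38% prevalence;
class-conditional indicator means/SDs set to the published observed
within-class moments (e.g. BMI 24.80±3.88 vs 28.97±3.73, HDL-C 74.13±15.20
vs 51.22±9.80); covariate marginals age ~ N(52.68, 2.60²) truncated to
[42, 58] (inverse-CDF), education P = 0.735, ethnicity 0.805/0.078/0.077
renormalized over the three modeled groups, APOE4 P = 0.262; concomitant
log-odds ln(1.140)/year of age, ln(0.627) college education, ln(2.621)
Hispanic, ln(0.951) non-Hispanic Black, ln(1.521) APOE4, with the intercept
root-found so the integrated marginal P(high-risk) equals 0.38 to 1e-8.

**Within-class correlation.** The LP model assumes local independence, so
within-class dependence is a deliberate realism knob: for every indicator
pair the shared within-class correlation is solved from the mixture-moment
identity

    pooled_cov = Σ_k π_k ρ_w σ_jk σ_lk + Σ_k π_k (μ_jk−μ̄_j)(μ_lk−μ̄_l)

against the published pooled correlation matrix (e.g. the −0.486 HDL-C–
triglyceride correlation implies ρ_w ≈ −0.22), then projected to the
nearest correlation matrix if needed (projection magnitude recorded; zero
under defaults).  Setting `within_class_corr` to the identity recovers the
model-faithful, locally independent generator used in oracle tests.

**Cognition.** Factor scores are class-shifted normals scaled so each
factor's total SD matches the published values (0.88, 0.87, 0.75, 0.73,
0.79); the 18 test scores follow the bi-factor measurement model with
loadings varying across rows and residuals giving unit test variance.  The
published class means for the two affected factors are mutually inconsistent
with overall-centered factor scores (their prevalence-weighted means are not
zero, grossly so for global cognition), so the generator preserves the
published *between-class differences* (0.207 speeded language, 0.182 global
cognition, taking 0.072 as the low-risk global mean) and splits them as
low = π_high·Δ, high = −π_low·Δ, which centers every factor exactly.

**Framingham score paths.** For LP analysis the FPS indicator is drawn
directly from its class-conditional moments and rounded to integers (fast
path).  A coherent path derives it from generated age, blood pressure,
total cholesterol, HDL-C and smoking via the point table; those components
are drawn class-conditionally so their pooled moments match the published
totals (SBP 117.4±14.9, DBP 75.3±9.2, TC 208.1±33.7, 6.9% smokers).

**Missingness.** 22% of subjects are incomplete under a MAR mechanism
driven only by always-observed age and education (older, less-educated
subjects more likely incomplete); missingness hits APOE4 and/or the
cognitive battery at rates mirroring the published analytic sample sizes
(596 and 662 of 727), never the seven indicators.

**What the generator does not emulate:** site-level clustering,
longitudinal follow-up, treatment effects, the excluded small ethnic
groups, non-normal indicator distributions (real triglycerides are
right-skewed), and — importantly — the fact that published *observed*
within-class moments come from a modal partition, which overstates the true
component separation.  Recovery results on these cohorts therefore show
that the pipeline estimates the printed parameters correctly under the
stated structure, not that the original study's real-data fit statistics
would reproduce.  The clearest consequence: simulated 2-class solutions
have relative entropy ≈ 0.87 versus the published 0.802, because the
generator's components are cleaner than the real mixture's.  The entropy
recovery check is accordingly expected to sit above the published value and
is the one calibration target this package reports as out of band.

## Problem sizes and numerical choices

Recovery experiments average 25 cohorts of n = 727 (10 seeds for the
forest stage, 1000 trees each); the generator-calibration check uses one
cohort of n = 100,000.  BLRT size is checked on 1-class data with n = 200,
B = 99 and 200 outer replicates using a shortened inner EM (one start,
100 iterations, tol 1e-4) — calibration is preserved because observed and
bootstrap statistics share the procedure.  EM tolerance 1e-7 (absolute
loglik gain), variance floor 1e-6; bootstrap inner failures abort beyond a
10% rate.  Posterior ties in modal assignment break to the lowest class
index.  CSV missing cells are empty strings; a literal `.` is rejected.
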
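# cvprofiles

Latent profile analysis of cardiovascular (CV) risk phenotypes in recently
menopausal women, with cognitive distal outcomes — built for biostatisticians
and epidemiologists who want a transparent, testable implementation of the
full modeling chain rather than a black-box mixture run.

Global CV-risk scores hide large between-woman heterogeneity. This package
models seven continuous vascular-risk indicators — BMI, carotid intima-media
thickness (CIMT), LDL-C, HDL-C, triglycerides, fasting glucose, and the
Framingham point score (FPS) — as a K-class Gaussian latent profile model

    f(y_i) = Σ_k π_k Π_{j∈obs(i)} N(y_ij ; μ_jk, σ²_jk)

fitted by multistart EM with full-information maximum likelihood over each
subject's observed cells (MAR). On top of the mixture it provides:

- **class enumeration**: BIC, relative entropy, and a parametric bootstrap
  likelihood-ratio test for K vs K−1;
- **concomitant covariates**: class membership regressed on age, education,
  ethnicity and APOE4 inside the likelihood, reported as Wald odds ratios;
- **bi-factor cognitive CFA**: one general + four orthogonal specific
  factors over 18 test scores, ML-fitted with CFI/TLI/RMSEA/BIC and
  regression-method factor scores;
- **distal outcomes**: class-specific cognitive means with Wald χ²(1)
  equality tests and posterior-probability regressions;
- **random-forest validation**: 10-fold CV accuracy and permutation
  importance (mean decrease in OOB accuracy) for the class solution;
- **a calibrated synthetic cohort generator** reproducing the published
  class moments (62%/38% prevalence), pooled indicator correlations,
  covariate odds ratios, cognitive shifts, and 22% MAR incompleteness —
  so the whole pipeline is testable without any restricted data.

## Worked example

```python
import cvprofiles as cv

params = cv.default_params()                       # calibrated defaults
cohort = cv.simulate_cohort(params, seed=1)        # n = 727 synthetic women
cohort = cv.apply_missingness(cohort, params, seed=2)
X = cv.standardize(cohort)                         # z-scored indicators
res = cv.enumerate_classes(X, K_max=3, B=29, seed=7, n_starts=20)
print(res.table.round(3).to_string(index=False))
```

prints the enumeration table

```
 K    loglik  q       BIC  entropy  min_class_share  blrt_lr  blrt_p
 1 -7220.978 14 14534.201      NaN            1.000      NaN     NaN
 2 -6603.416 29 13397.911    0.897            0.364 1235.125   0.033
 3 -6574.167 44 13438.246    0.676            0.321   58.498   0.033
selected K = 2
```

Two classes win: the bootstrap LRT overwhelmingly rejects one class, while a
third buys almost no BIC and degrades classification entropy from 0.90 to
0.68. The selected solution's back-transformed class profile shows the
low-risk class (63.6% of the sample here) with HDL-C 73.7 vs 50.6 mg/dL,
triglycerides 67 vs 131 mg/dL, and FPS 2.0 vs 7.1 — the high-risk class is
worse on every indicator. A 1000-tree random forest re-predicts these labels
from the indicators with 97% 10-fold CV accuracy, ranking FPS,
triglycerides, HDL-C and BMI as the most important variables, and the
conditional model estimates an age odds ratio of about 1.13 per year
(95% CI 1.04–1.22) for high-risk membership on this seed.

The `examples/` directory has one short script per capability (simulation,
enumeration, covariate effects, cognition, forest validation, Framingham
scoring); each prints the numbers above with a line on how to read them.
A thin CLI mirrors the stages:

```bash
cvprofiles simulate --n 727 --seed 1 --out cohort.csv
cvprofiles fit-lpa --in cohort.csv --k 2 --out model.json
cvprofiles run-all --seed 1 --out-dir results/
```

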
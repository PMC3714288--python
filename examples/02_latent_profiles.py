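"""Fit latent profile models and enumerate the number of risk classes.

Standardizes the seven indicators, fits K = 1..3 mixtures, runs the
bootstrap likelihood-ratio test for each step, and prints the enumeration
table plus the selected solution's class profile in raw units.
"""

import cvprofiles as cv

params = cv.default_params()
cohort = cv.apply_missingness(cv.simulate_cohort(params, seed=1), params, seed=2)
X = cv.standardize(cohort)

res = cv.enumerate_classes(X, K_max=3, B=29, seed=7, n_starts=20)
print(res.table.round(3).to_string(index=False))
print(f"\nselected K = {res.selected_K}: {res.rationale}")

model, post = res.models[res.selected_K], res.posteriors[res.selected_K]
print(f"\nmixing weights: {model.pi.round(3)}   "
      f"relative entropy: {cv.relative_entropy(post):.3f}")
print("class means (raw units), low-risk then high-risk:")
raw = X.back_transform(model.mu)
for j, col in enumerate(cv.INDICATORS):
    print(f"  {col:>13}: {raw[0, j]:8.2f}   {raw[1, j]:8.2f}")
# A two-class solution should win: the BLRT strongly rejects one class,
# while a third class degrades classification entropy without a meaningful
# BIC gain; the low-risk class carries higher HDL-C and lower everything else.
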
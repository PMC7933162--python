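"""Mixed-model confirmation of a sentence-type effect.

Simulates electrode-level window values for 12 patients with a +5%
sentence-type effect, 3% patient random intercepts and patient
covariates, fits the linear mixed model, and prints the coefficient
table.  Also shows the power helper: the smallest standardized effect a
one-sample t test can detect at a given electrode count.
"""

import numpy as np
import pandas as pd

from hgmod import detectable_effect_size, fit_window_lmm, generate_cohort

rng = np.random.default_rng(5)
patients, _, _ = generate_cohort(12, {"left": {"others": 1}},
                                 trial_counts=3, rng_seed=6)
rows = []
for p in patients:
    u = rng.normal(0.0, 3.0)
    for _ in range(5):
        for stype, shift in (("concrete_first", 5.0), ("wh_first", 0.0)):
            rows.append({"value": u + shift + rng.normal(0.0, 5.0),
                         "sentence_type": stype, "patient_id": p.patient_id})

fit = fit_window_lmm(pd.DataFrame(rows), patients)
with pd.option_context("display.float_format", "{:8.3f}".format):
    print(fit.coefficients[["estimate", "ci_low", "ci_high", "p"]])
print(f"patient random-intercept variance: {fit.random_intercept_var:.2f}")

for n in (15, 30, 57):
    print(f"detectable effect size at n={n}: "
          f"{detectable_effect_size(n, 0.05, 0.8):.2f}")
# The sentence_type row should recover ~+5 with a CI covering the truth;
# covariates drawn independently of the outcome should hover near zero.
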
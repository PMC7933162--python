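"""Sentence-type contrast in 100-ms windows with the bootstrap-t test.

Simulates electrode-level window values where concrete-first trials run
+6% above wh-first trials, tests the difference with the studentized
bootstrap, and prints the estimate, CI and FDR-adjusted p-value per
window.
"""

import numpy as np

from hgmod import contrast_windows, default_windows

rng = np.random.default_rng(3)
windows = default_windows()
values = {}
for w in windows:
    shift = 6.0 if w.label in ("2b", "2c") else 0.0  # effect in two windows
    concrete = rng.normal(shift, 8.0, size=30)
    wh = rng.normal(0.0, 8.0, size=30)
    values[("posterior_MFG", "left", w.label)] = (concrete, wh)

for c in contrast_windows(values=values, n_boot=2000, rng_seed=4):
    flag = " *" if c.p_fdr < 0.05 else ""
    print(f"window {c.window}: diff {c.mean_diff:+6.2f}% "
          f"[{c.ci95[0]:+6.2f}, {c.ci95[1]:+6.2f}], "
          f"|t|={abs(c.t_stat):.2f}, FDR p={c.p_fdr:.3f}{flag}")
# Only windows carrying the simulated +6% difference (2b and 2c) can
# come out significant after FDR across the 11-window family; with 30
# electrodes per group the test has moderate power, so typically one or
# both are flagged and the null windows are not.
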
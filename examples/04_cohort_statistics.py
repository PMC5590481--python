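"""Group comparison and interobserver concordance.

Recomputes the Welch t-test for the reference cohort's most significant
combination (RA region, CI-scaled integration, threshold 0.04 1/s) from
its published group summaries, then shows the concordance sweep and a
simulated cohort at the same effect size.
"""

import numpy as np

from rhvort import (
    CohortSimParams,
    cohort_grid,
    concordance,
    concordance_sweep,
    simulate_cohort,
    welch_t_from_summary,
)
from rhvort.reference import N_CONTROL, N_RVDD, REFERENCE_COHORT_ROWS

row = REFERENCE_COHORT_ROWS[0]  # RA / SS / tau = 0.04
t, df, p = welch_t_from_summary(N_CONTROL, row.control_mean, row.control_sd,
                                N_RVDD, row.rvdd_mean, row.rvdd_sd)
print(f"reference cohort, {row.roi}/{row.scheme}/tau={row.tau}:")
print(f"  control {row.control_mean:.0f} +/- {row.control_sd:.0f} (n={N_CONTROL}), "
      f"RVDD {row.rvdd_mean:.0f} +/- {row.rvdd_sd:.0f} (n={N_RVDD})")
print(f"  Welch t = {t:.2f}, df = {df:.1f}, p = {p:.3f} (published: {row.p_printed})")

print(f"\nLin concordance of (1,2,3) vs (2,3,4): {concordance([1, 2, 3], [2, 3, 4]):.4f} "
      f"(= 4/7)")
rng = np.random.default_rng(0)
a = rng.uniform(100, 3000, size=(23, 20))
sweep = concordance_sweep(a, a.copy())
print(f"identical observers: rho_c = {sweep.rho_c.min():.1f} at all "
      f"{len(sweep.thresholds)} thresholds ({sweep.thresholds[0]}-{sweep.thresholds[-1]} 1/s)")

subjects = simulate_cohort(CohortSimParams(seed=1))
grid = cohort_grid(subjects, ["RA"], ["SS"], [0.04])
r = grid[0]
print(f"\nsimulated cohort at the reference effect size (seed 1):")
print(f"  control {r.mean1:.0f} +/- {r.sd1:.0f}, RVDD {r.mean2:.0f} +/- {r.sd2:.0f}, "
      f"p = {r.p_value:.2g}")
# A single simulated cohort fluctuates around the reference values; the
# rejection rate over many seeds matches the analytic Welch power (~0.69).
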
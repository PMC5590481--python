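"""Reference cohort summary statistics.

Published group summaries from the clinical cohort this pipeline
operationalizes: 14 controls and 20 subjects with right ventricular
diastolic dysfunction, with integrated peak early-diastolic right-heart
vorticity summarised per (ROI, scaling scheme, threshold) combination for
every combination that separated the groups at p < 0.05.  Means and SDs
are in the study's integrated-vorticity units; thresholds in s^-1.

These summaries are the inputs for reproducing the group-comparison
analysis (raw per-subject scans are not available), and the distributional
parameters for cohort-level simulation defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CohortSummaryRow",
    "REFERENCE_COHORT_ROWS",
    "N_CONTROL",
    "N_RVDD",
    "CONTROL_CI_MEAN",
    "RVDD_CI_MEAN",
]

N_CONTROL = 14
N_RVDD = 20

#: group-mean cardiac index, L/min/m^2
CONTROL_CI_MEAN = 2.4
RVDD_CI_MEAN = 2.5


@dataclass(frozen=True)
class CohortSummaryRow:
    """One (ROI, scheme, threshold) column of the published result grid."""

    p_printed: float
    roi: str
    scheme: str
    tau: float
    control_mean: float
    control_sd: float
    rvdd_mean: float
    rvdd_sd: float


#: all combinations published with p < 0.05, ordered by ascending p
REFERENCE_COHORT_ROWS = (
    CohortSummaryRow(0.011, "RA", "SS", 0.04, 709.0, 325.0, 408.0, 303.0),
    CohortSummaryRow(0.012, "RA", "SS", 0.05, 425.0, 219.0, 222.0, 208.0),
    CohortSummaryRow(0.015, "RA", "SS", 0.06, 255.0, 145.0, 127.0, 136.0),
    CohortSummaryRow(0.024, "RA", "SS", 0.03, 1121.0, 466.0, 749.0, 417.0),
    CohortSummaryRow(0.025, "RA", "TS", 0.04, 1826.0, 886.0, 1109.0, 834.0),
    CohortSummaryRow(0.029, "RA", "TS", 0.03, 2685.0, 1026.0, 1870.0, 998.0),
    CohortSummaryRow(0.034, "RH", "TS", 0.05, 1184.0, 712.0, 653.0, 632.0),
    CohortSummaryRow(0.045, "RA", "SS", 0.04, 1353.0, 518.0, 887.0, 785.0),
    CohortSummaryRow(0.047, "RA", "TS", 0.06, 750.0, 531.0, 387.0, 449.0),
    CohortSummaryRow(0.048, "RH", "SS", 0.03, 2051.0, 707.0, 1450.0, 995.0),
)
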
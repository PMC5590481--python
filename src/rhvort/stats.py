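"""Cohort statistics: Lin concordance and Welch t-tests over metric grids.

Two statistical questions arise downstream of the vorticity metric:

* **Interobserver reliability** — two analysts place the ROI boxes
  independently; Lin's concordance correlation coefficient rho_c between
  their integrated-vorticity values, swept over the vorticity threshold,
  shows how strongly thresholding suppresses the effect of box placement.

* **Group separation** — for every (ROI, scaling scheme, threshold)
  combination, a two-sample t-test between the control and RVDD groups.
  The unequal-variance (Welch) form is used: the reference cohort's
  published p-values are reproduced exactly by Welch's test from its
  printed group summaries, while the pooled-variance form is not, and the
  group SDs genuinely differ.  Tests are two-sided, and raw p-values are
  reported (no multiplicity correction) to match how such grids are
  usually presented; a Bonferroni column is available on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GROUP_CONTROL, GROUP_RVDD, SubjectRecord

__all__ = [
    "ConcordanceSweep",
    "GroupComparison",
    "DEFAULT_THRESHOLD_SWEEP",
    "concordance",
    "concordance_sweep",
    "welch_t_from_summary",
    "welch_power_from_summary",
    "cohort_grid",
]

#: constant (unscaled) thresholds for the interobserver sweep:
#: 0.005 to 0.100 s^-1 in 0.005 s^-1 increments
DEFAULT_THRESHOLD_SWEEP = tuple(np.round(np.arange(1, 21) * 0.005, 3))


def concordance(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``
    with population (1/n) moments, per Lin's original definition.  Ranges
    over [-1, 1]; 1 only when y == x.  Degenerate inputs: if both series
    are constant, returns 1.0 when they are equal and 0.0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population moments
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # identical constants
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / denom)


@dataclass
class ConcordanceSweep:
    """rho_c between two observers at each vorticity threshold."""

    thresholds: np.ndarray
    rho_c: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.rho_c = np.asarray(self.rho_c, dtype=float)
        if self.thresholds.shape != self.rho_c.shape or self.thresholds.ndim != 1:
            raise ValueError("thresholds and rho_c must be 1-D and equal length")
        if self.thresholds.size >= 2 and not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "rho_c": self.rho_c})


def concordance_sweep(
    observer_a: np.ndarray,
    observer_b: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_SWEEP,
    subjects_a: Optional[Sequence[str]] = None,
    subjects_b: Optional[Sequence[str]] = None,
) -> ConcordanceSweep:
    """rho_c per threshold over subjects.

    ``observer_a`` and ``observer_b`` are (n_subjects, n_thresholds) arrays
    of integrated vorticity, rows covering the identical subject set in the
    same order (pass ``subjects_a``/``subjects_b`` to have that checked).
    """
    a = np.atleast_2d(np.asarray(observer_a, dtype=float))
    b = np.atleast_2d(np.asarray(observer_b, dtype=float))
    thresholds = np.asarray(thresholds, dtype=float)
    if subjects_a is not None or subjects_b is not None:
        if list(subjects_a or []) != list(subjects_b or []):
            raise ValueError("observers must cover the identical subject set in the same order")
    if a.shape != b.shape:
        raise ValueError(f"observer arrays differ in shape: {a.shape} vs {b.shape}")
    if a.shape[1] != thresholds.size:
        raise ValueError("number of columns must match the threshold list")
    rho = np.array([concordance(a[:, j], b[:, j]) for j in range(thresholds.size)])
    return ConcordanceSweep(thresholds, rho)


def welch_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float, float]:
    """Welch's two-sample t-test from group summary statistics.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom
    and a two-sided p-value.  SDs are sample (1/(n-1)) standard deviations.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    a, b = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(a + b)
    df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def welch_power_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, alpha: float = 0.05
) -> float:
    """Analytic power of the two-sided Welch test at the given effect size.

    Uses the noncentral t distribution with the Welch–Satterthwaite df and
    noncentrality ``(mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2)``.
    """
    a, b = sd1**2 / n1, sd2**2 / n2
    ncp = (mean1 - mean2) / np.sqrt(a + b)
    df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    tcrit = sps.t.isf(alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


@dataclass
class GroupComparison:
    """One row of the cohort result grid."""

    roi_label: str
    scheme: str
    tau_ref: float
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    t_statistic: float
    df: float
    p_value: float
    p_bonferroni: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


def cohort_grid(
    subjects: Sequence[SubjectRecord],
    rois: Sequence[str],
    schemes: Sequence[str],
    taus: Sequence[float],
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """Welch test per (ROI, scheme, threshold) combination, sorted by p.

    Every subject must carry a metric for every requested combination;
    missing entries are reported together, not one at a time.  Group 1 is
    the control group, group 2 RVDD, so a positive t means controls have
    the larger mean vorticity.
    """
    combos = [(roi, scheme, tau) for roi in rois for scheme in schemes for tau in taus]
    missing = [
        (s.subject_id, key) for s in subjects for key in combos if key not in s.metrics
    ]
    if missing:
        raise ValueError(f"missing metric values for {len(missing)} (subject, combo) pairs: "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    results = []
    n_tests = len(combos)
    for roi, scheme, tau in combos:
        g1 = np.array([s.metrics[(roi, scheme, tau)] for s in subjects if s.group == GROUP_CONTROL])
        g2 = np.array([s.metrics[(roi, scheme, tau)] for s in subjects if s.group == GROUP_RVDD])
        m1, m2 = g1.mean(), g2.mean()
        s1, s2 = g1.std(ddof=1), g2.std(ddof=1)  # sample SDs for the t-test
        t, df, p = welch_t_from_summary(g1.size, m1, s1, g2.size, m2, s2)
        results.append(
            GroupComparison(
                roi_label=roi,
                scheme=scheme,
                tau_ref=float(tau),
                n1=int(g1.size),
                mean1=float(m1),
                sd1=float(s1),
                n2=int(g2.size),
                mean2=float(m2),
                sd2=float(s2),
                t_statistic=t,
                df=df,
                p_value=p,
                p_bonferroni=min(1.0, p * n_tests) if bonferroni else None,
            )
        )
    return sorted(results, key=lambda r: r.p_value)


def grid_to_frame(results: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
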
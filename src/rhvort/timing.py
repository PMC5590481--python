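"""Cardiac event timing from through-plane flowrates and volume curves.

The timestep of peak early diastole (E-wave) anchors the vorticity
analysis.  In subjects with normal filling (peak E velocity > peak A
velocity) it is read directly off the tricuspid flowrate curve.  In
diastolic dysfunction the A-wave dominates and the E peak may be barely
visible, so a hybrid method is used: the E-to-A interval (diastasis
duration) is measured on the left-ventricular dV/dt curve, where both
peaks are distinct, and subtracted from the time of the dominant
right-heart A-wave peak.

Flowrates are computed by numerically integrating the velocity component
normal to a circular disk probe placed at the valve plane, using trilinear
interpolation of the voxel data on a uniform in-plane quadrature grid.
The disk is fixed in space: the estimate is only accurate near the
timestep the disk position was chosen for, which is acceptable because
only the peak-E timestep is consumed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .core import FlowrateSeries, GridSpec, VelocityField4D, VolumeSeries

__all__ = [
    "DiskProbe",
    "TimingEstimate",
    "EWaveAmbiguousError",
    "disk_flowrate",
    "flowrate_series",
    "dvdt",
    "detect_events_direct",
    "detect_events_hybrid",
]

#: in-plane quadrature spacing, as a fraction of the smallest voxel edge
DEFAULT_QUADRATURE_FRACTION = 0.25

#: a local maximum counts as a distinct wave peak if its prominence exceeds
#: this fraction of the series range
DEFAULT_PROMINENCE_FRACTION = 0.05


class EWaveAmbiguousError(RuntimeError):
    """Raised when no distinct E-wave peak exists in the diastolic window.

    Callers should fall back to :func:`detect_events_hybrid`.
    """


@dataclass(frozen=True)
class DiskProbe:
    """Circular probe approximating the area of flow through a valve plane."""

    center_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if not math.isclose(float(np.linalg.norm(n)), 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("disk normal must have unit norm")
        if self.radius_mm <= 0:
            raise ValueError("disk radius must be positive")


@dataclass
class TimingEstimate:
    """Estimated cardiac event times, ms from the cycle start."""

    t_peak_systole_ms: Optional[float]
    t_E_ms: float
    t_A_ms: Optional[float]
    method: str  # "direct" | "hybrid"
    lv_diastasis_dt_ms: Optional[float] = None
    a_wave_possibly_truncated: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("direct", "hybrid"):
            raise ValueError("method must be 'direct' or 'hybrid'")
        if self.t_A_ms is not None and not self.t_E_ms < self.t_A_ms:
            raise ValueError("t_E must precede t_A when both are present")


def _canonical_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis independent of the normal's sign.

    Flipping the probe normal must negate the flowrate *exactly*, so the
    quadrature points may not depend on the sign of the normal.
    """
    canon = np.asarray(normal, dtype=float).copy()
    for comp in canon:
        if comp != 0.0:
            if comp < 0:
                canon = -canon
            break
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(canon)))] = 1.0
    e1 = np.cross(canon, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(canon, e1)
    return e1, e2


def disk_sample_points(
    disk: DiskProbe, grid: GridSpec, spacing_mm: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """Quadrature points (N, 3, world mm) covering the disk, and their spacing.

    Raises ``ValueError`` if any point falls outside the voxel-center
    bounding box of the grid (the disk must lie fully inside the data).
    """
    if spacing_mm is None:
        spacing_mm = DEFAULT_QUADRATURE_FRACTION * min(grid.spacing_mm)
    if spacing_mm <= 0:
        raise ValueError("sampling spacing must be positive")
    e1, e2 = _canonical_basis(np.asarray(disk.normal, dtype=float))
    m = int(np.floor(2.0 * disk.radius_mm / spacing_mm)) + 1
    off = (np.arange(m) - (m - 1) / 2.0) * spacing_mm
    A, B = np.meshgrid(off, off, indexing="ij")
    keep = np.hypot(A, B) <= disk.radius_mm
    a, b = A[keep], B[keep]
    pts = (
        np.asarray(disk.center_mm, dtype=float)[None, :]
        + a[:, None] * e1[None, :]
        + b[:, None] * e2[None, :]
    )
    idx = grid.world_to_index(pts)
    hi = np.array(grid.shape) - 1
    if np.any(idx < -1e-9) or np.any(idx > hi + 1e-9):
        raise ValueError("disk extends outside the grid; shrink or move the probe")
    return pts, spacing_mm


def disk_flowrate(
    field: VelocityField4D,
    disk: DiskProbe,
    t: int,
    sampling_spacing_mm: Optional[float] = None,
) -> float:
    """Area-integrated normal flow through the disk at one timestep, mL/s.

    Velocities are sampled with trilinear interpolation at the points of a
    uniform in-plane grid restricted to ``r <= radius``, each weighted by
    ``spacing**2``.  The sign follows the disk normal.
    """
    if not 0 <= t < field.grid.n_timesteps:
        raise IndexError(f"timestep {t} out of range")
    pts, s = disk_sample_points(disk, field.grid, sampling_spacing_mm)
    coords = field.grid.world_to_index(pts).T  # (3, N)
    n = np.asarray(disk.normal, dtype=float)
    vn = np.zeros(pts.shape[0])
    for c in range(3):
        vn += n[c] * map_coordinates(field.values[c, ..., t], coords, order=1, mode="nearest")
    # v [cm/s] * 10 -> mm/s; * s^2 [mm^2] -> mm^3/s; / 1000 -> mL/s
    return float(vn.sum() * 10.0 * s * s / 1000.0)


def flowrate_series(
    field: VelocityField4D,
    disk: DiskProbe,
    sampling_spacing_mm: Optional[float] = None,
) -> FlowrateSeries:
    """:func:`disk_flowrate` at every timestep; times are ``k * dt``."""
    values = np.array(
        [disk_flowrate(field, disk, t, sampling_spacing_mm) for t in range(field.grid.n_timesteps)]
    )
    return FlowrateSeries(field.grid.times_ms.copy(), values)


def dvdt(volume: VolumeSeries) -> FlowrateSeries:
    """Time derivative of a uniformly sampled volume curve, mL/s.

    Central differences at interior samples; first-order forward/backward
    differences at the first and last samples.
    """
    if volume.times_ms.size < 3:
        raise ValueError("need at least 3 volume samples")
    dt = volume.uniform_dt_ms
    if dt is None:
        raise ValueError("volume curve must be uniformly sampled")
    deriv = np.gradient(volume.values_ml, dt, edge_order=1) * 1e3  # mL/ms -> mL/s
    return FlowrateSeries(volume.times_ms.copy(), deriv)


def _distinct_peaks(q: FlowrateSeries, prominence_fraction: float) -> np.ndarray:
    rng = float(np.ptp(q.values_ml_s))
    if rng == 0.0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(q.values_ml_s, prominence=prominence_fraction * rng)
    return peaks


def _default_hint(times: np.ndarray) -> float:
    return float(times[0] + 0.5 * (times[-1] - times[0]))


def detect_events_direct(
    q: FlowrateSeries,
    systole_end_hint_ms: Optional[float] = None,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> TimingEstimate:
    """Read E- and A-wave times directly off a flowrate curve.

    ``t_E`` is the largest distinct local maximum in the diastolic window
    (samples after ``systole_end_hint_ms``, default: the second half of the
    cycle); ``t_A`` is the last distinct local maximum after ``t_E`` (absent
    if none).  Earliest sample wins ties.  Raises
    :class:`EWaveAmbiguousError` when the window holds no distinct local
    maximum — e.g. monotone decay, or an A-dominant pattern whose only
    "peak" is the truncated final sample — in which case the hybrid method
    should be used.
    """
    times = q.times_ms
    hint = _default_hint(times) if systole_end_hint_ms is None else float(systole_end_hint_ms)
    peaks = _distinct_peaks(q, prominence_fraction)
    dias = peaks[times[peaks] > hint]
    if dias.size == 0:
        raise EWaveAmbiguousError(
            "no distinct local maximum in the diastolic window; fall back to the hybrid method"
        )
    i_e = dias[int(np.argmax(q.values_ml_s[dias]))]  # argmax returns the first (earliest) tie
    after = dias[dias > i_e]
    t_a = float(times[after[-1]]) if after.size else None

    sys_idx = np.nonzero(times <= hint)[0]
    t_sys = float(times[sys_idx[np.argmax(q.values_ml_s[sys_idx])]]) if sys_idx.size else None

    window = np.nonzero(times > hint)[0]
    truncated = bool(window.size and int(window[np.argmax(q.values_ml_s[window])]) == times.size - 1)
    return TimingEstimate(
        t_peak_systole_ms=t_sys,
        t_E_ms=float(times[i_e]),
        t_A_ms=t_a,
        method="direct",
        a_wave_possibly_truncated=truncated,
    )


def _refine_peak_ms(times: np.ndarray, values: np.ndarray, i: int) -> float:
    """Quadratic sub-sample refinement of a discrete peak position."""
    if i == 0 or i == times.size - 1:
        return float(times[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(times[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(times[i] + np.clip(delta, -0.5, 0.5) * (times[i] - times[i - 1]))


def detect_events_hybrid(
    q_rv: FlowrateSeries,
    dvdt_lv: FlowrateSeries,
    systole_end_hint_ms: Optional[float] = None,
    lv_systole_end_hint_ms: Optional[float] = None,
    gating_offset_ms: float = 0.0,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> TimingEstimate:
    """Back off from the dominant A-wave by the LV diastasis duration.

    The E-to-A interval ``dt`` is measured between the two distinct positive
    diastolic peaks of the LV dV/dt curve (with quadratic sub-sample peak
    refinement, since the cine-derived curve is smooth and usually better
    sampled than the 4D Flow data).  ``t_A`` is the diastolic argmax of the
    right-heart flowrate, and ``t_E = t_A - dt`` snapped to the nearest
    flowrate sample.  ``gating_offset_ms`` is added to LV-derived absolute
    times before use (it cancels in the E-to-A difference, but is applied
    explicitly so a prospective/retrospective gating offset between the two
    acquisitions is never corrected silently).
    """
    lv_times = dvdt_lv.times_ms + gating_offset_ms
    lv_hint = (
        _default_hint(lv_times) if lv_systole_end_hint_ms is None else float(lv_systole_end_hint_ms)
    )
    peaks = _distinct_peaks(dvdt_lv, prominence_fraction)
    peaks = peaks[(dvdt_lv.values_ml_s[peaks] > 0) & (lv_times[peaks] > lv_hint)]
    if peaks.size < 2:
        raise ValueError(
            f"hybrid timing needs two distinct positive diastolic LV dV/dt peaks, found {peaks.size}"
        )
    t_e_lv = _refine_peak_ms(lv_times, dvdt_lv.values_ml_s, int(peaks[0]))
    t_a_lv = _refine_peak_ms(lv_times, dvdt_lv.values_ml_s, int(peaks[-1]))
    diastasis = t_a_lv - t_e_lv

    times = q_rv.times_ms
    hint = _default_hint(times) if systole_end_hint_ms is None else float(systole_end_hint_ms)
    window = np.nonzero(times > hint)[0]
    if window.size == 0:
        raise ValueError("no samples after systole_end_hint")
    i_a = window[int(np.argmax(q_rv.values_ml_s[window]))]
    t_a = float(times[i_a])
    t_e_raw = t_a - diastasis
    t_e = float(times[int(np.argmin(np.abs(times - t_e_raw)))])

    sys_idx = np.nonzero(times <= hint)[0]
    t_sys = float(times[sys_idx[np.argmax(q_rv.values_ml_s[sys_idx])]]) if sys_idx.size else None
    return TimingEstimate(
        t_peak_systole_ms=t_sys,
        t_E_ms=t_e,
        t_A_ms=t_a,
        method="hybrid",
        lv_diastasis_dt_ms=float(diastasis),
        a_wave_possibly_truncated=bool(int(i_a) == times.size - 1),
    )
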
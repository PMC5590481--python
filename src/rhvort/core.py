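"""Core data containers for 4D phase-contrast velocity analysis.

Conventions used throughout the package:

* Voxel indices are 0-based; axis order is (x, y, z); world coordinates are
  in millimetres at voxel centers (``world = origin + index * spacing``).
* Velocities are stored in cm/s, the native unit of phase-contrast exports.
  Numeric kernels (curl, flow integration) convert to SI internally.
* Time is in milliseconds; timestep ``k`` of a field is at ``k * dt``.
* Velocity arrays have shape ``(3, nx, ny, nz, nt)`` — component first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GridSpec",
    "VelocityField4D",
    "MagnitudeSeries",
    "FlowrateSeries",
    "VolumeSeries",
    "SubjectRecord",
    "GROUP_CONTROL",
    "GROUP_RVDD",
]

GROUP_CONTROL = "control"
GROUP_RVDD = "rvdd"


@dataclass(frozen=True)
class GridSpec:
    """Regular-grid geometry of a time-resolved volume.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``; each must be at least 2.
    spacing_mm
        Voxel edge lengths ``(dx, dy, dz)`` in mm.  Anisotropic voxels
        (e.g. 2 x 2 x 3 mm, typical of 4D Flow acquisitions) are supported.
    origin_mm
        World coordinates of the center of voxel (0, 0, 0), in mm.
    n_timesteps
        Number of cardiac phases.
    dt_ms
        Temporal resolution in ms (50 ms is a common 4D Flow compromise
        between data quality and exam time).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_timesteps: int = 1
    dt_ms: float = 50.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise ValueError(f"grid shape must be 3 entries each >= 2, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be positive, got {self.spacing_mm}")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_timesteps) * self.dt_ms

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel center, three (nx, ny, nz) arrays."""
        return np.meshgrid(*(self.axis_coords_mm(a) for a in range(3)), indexing="ij")

    def center_mm(self) -> np.ndarray:
        """World coordinates of the grid center."""
        return np.array(
            [
                self.origin_mm[a] + 0.5 * (self.shape[a] - 1) * self.spacing_mm[a]
                for a in range(3)
            ]
        )

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (..., 3) to fractional voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.array(self.origin_mm)) / np.array(self.spacing_mm)


def _check_values(values: np.ndarray, grid: GridSpec, leading: tuple[int, ...]) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    expected = leading + grid.shape + (grid.n_timesteps,)
    if values.shape != expected:
        raise ValueError(f"values shape {values.shape} does not match grid {expected}")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite everywhere")
    return values


@dataclass
class VelocityField4D:
    """Three-component, time-resolved velocity on a regular grid.

    ``values[c, i, j, k, t]`` is the c-th velocity component (cm/s) at voxel
    (i, j, k) and timestep t.  ``venc_cm_s`` is the velocity-encoding limit
    of the acquisition: raw phase-contrast values lie in [-venc, venc) and
    true speeds beyond it alias by multiples of 2 venc.
    """

    values: np.ndarray
    grid: GridSpec
    venc_cm_s: float
    gating: str = "prospective"

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, self.grid, (3,))
        if self.venc_cm_s <= 0:
            raise ValueError("venc must be positive")
        if self.gating not in ("prospective", "retrospective"):
            raise ValueError(f"unknown gating {self.gating!r}")

    def copy(self) -> "VelocityField4D":
        return replace(self, values=self.values.copy())


@dataclass
class MagnitudeSeries:
    """Anatomical magnitude image series co-registered with a velocity field.

    Intensity is in arbitrary scanner units, non-negative.  ``max_intensity``
    is recorded so fractional noise thresholds ("about 3% of the maximum")
    can be resolved without rescanning the data.
    """

    values: np.ndarray
    grid: GridSpec
    max_intensity: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, self.grid, ())
        if np.any(self.values < 0):
            raise ValueError("magnitude intensities must be non-negative")
        if self.max_intensity is None:
            self.max_intensity = float(self.values.max())


def _check_series(times_ms, values, value_name: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError(f"times and {value_name} must be 1-D and equal length")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return t, v


@dataclass
class FlowrateSeries:
    """Volumetric flowrate Q(t) through a probe, mL/s at ms sample times."""

    times_ms: np.ndarray
    values_ml_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms, self.values_ml_s = _check_series(
            self.times_ms, self.values_ml_s, "flowrates"
        )

    @property
    def uniform_dt_ms(self) -> Optional[float]:
        """Sample spacing if uniform (to 1e-6 ms), else None."""
        if self.times_ms.size < 2:
            return None
        d = np.diff(self.times_ms)
        return float(d[0]) if np.allclose(d, d[0], atol=1e-6) else None


@dataclass
class VolumeSeries:
    """Ventricular volume V(t), mL at ms sample times (non-negative)."""

    times_ms: np.ndarray
    values_ml: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms, self.values_ml = _check_series(self.times_ms, self.values_ml, "volumes")
        if np.any(self.values_ml < 0):
            raise ValueError("volumes must be non-negative")

    @property
    def uniform_dt_ms(self) -> Optional[float]:
        if self.times_ms.size < 2:
            return None
        d = np.diff(self.times_ms)
        return float(d[0]) if np.allclose(d, d[0], atol=1e-6) else None


@dataclass
class SubjectRecord:
    """Per-subject metadata and derived vorticity metrics.

    ``metrics`` maps ``(roi_label, scheme_name, tau_ref)`` to the scaled,
    integrated early-diastolic vorticity for that combination.
    """

    subject_id: str
    group: str
    cardiac_index: Optional[float] = None  # L/min/m^2
    cardiac_output: Optional[float] = None  # L/min
    heart_rate: Optional[float] = None  # bpm
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (GROUP_CONTROL, GROUP_RVDD):
            raise ValueError(f"group must be '{GROUP_CONTROL}' or '{GROUP_RVDD}'")
        if self.cardiac_index is not None and self.cardiac_index <= 0:
            raise ValueError("cardiac_index must be positive when given")
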
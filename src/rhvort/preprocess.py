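"""Noise masking and velocity anti-aliasing for phase-contrast data.

Phase-contrast velocity in air and low-signal tissue is essentially random,
so velocity is zeroed wherever the co-registered anatomical magnitude image
falls at or below an intensity threshold (an absolute scanner value, or a
fraction of the maximum intensity — about 3% is a good compromise between
noise removal and loss of real velocity data).

True speeds beyond the encoding limit venc alias into [-venc, venc) by
multiples of 2 venc.  Aliasing is corrected iteratively, with a hard cap of
10 iterations; heavily aliased images typically resolve within about five.

Two pieces of machinery are exposed:

* :func:`detect_aliased` — a local diagnostic: a voxel is flagged when its
  value is more than venc away from the median of its (up to 6) face
  neighbours, with the wrap count ``k = round((median - v) / (2 venc))``.
  It is reliable for isolated aliased voxels and for the rim of an aliased
  region, but a large aliased region is *internally* self-consistent (the
  wrap is locally just a constant shift), so its interior is invisible to
  any purely local test.

* :func:`unwrap` — the corrector.  Each iteration partitions each volume
  into connected regions of mutual consistency (face neighbours differing
  by at most venc), then rigidly shifts every region adjacent to the
  dominant (largest) region by the integer multiple of 2 venc that matches
  it to the dominant region's boundary values.  Aliased regions merge into
  the dominant region one adjacency layer per iteration, so nested
  (multiply-wrapped) regions resolve in as many iterations as their
  nesting depth.  Corrections are exact multiples of 2 venc, so a field
  wrapped from a smooth truth is recovered bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .core import MagnitudeSeries, VelocityField4D

__all__ = [
    "NoiseMaskParams",
    "UnwrapReport",
    "noise_mask",
    "detect_aliased",
    "unwrap",
]

MAX_UNWRAP_ITERATIONS = 10


@dataclass(frozen=True)
class NoiseMaskParams:
    """How the magnitude-image noise threshold is specified.

    ``fraction_of_max`` resolves the threshold as
    ``threshold_value * max_intensity`` of the magnitude series, which
    reproduces absolute scanner thresholds (e.g. 14 on images whose maximum
    is about 467) without hard-coding an intensity scale.
    """

    threshold_mode: str = "fraction_of_max"
    threshold_value: float = 0.03

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("absolute", "fraction_of_max"):
            raise ValueError("threshold_mode must be 'absolute' or 'fraction_of_max'")
        if self.threshold_mode == "fraction_of_max" and not 0.0 < self.threshold_value < 1.0:
            raise ValueError("fractional threshold must be in (0, 1)")
        if self.threshold_mode == "absolute" and self.threshold_value < 0:
            raise ValueError("absolute threshold must be >= 0")

    def resolve(self, magnitude: MagnitudeSeries) -> float:
        if self.threshold_mode == "absolute":
            return float(self.threshold_value)
        return float(self.threshold_value * magnitude.max_intensity)


@dataclass
class UnwrapReport:
    """What the anti-aliasing pass did.

    ``converged`` is true iff the last iteration corrected zero voxels
    (i.e. the algorithm stopped because there was nothing left to do, not
    because it hit the iteration cap).
    """

    iterations_run: int
    voxels_corrected_per_iteration: list[int] = dc_field(default_factory=list)
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "iterations_run": self.iterations_run,
            "voxels_corrected_per_iteration": list(self.voxels_corrected_per_iteration),
            "converged": self.converged,
        }


def noise_mask(
    field: VelocityField4D,
    magnitude: MagnitudeSeries,
    params: NoiseMaskParams = NoiseMaskParams(),
) -> VelocityField4D:
    """Zero all three velocity components wherever intensity <= threshold.

    The rule is inclusive ("an intensity value of 14 or less"): a voxel
    exactly at the threshold is zeroed.  Voxels above the threshold are
    untouched, which makes the operation idempotent.
    """
    if magnitude.grid != field.grid:
        raise ValueError("field and magnitude must share the same grid")
    thr = params.resolve(magnitude)
    low = magnitude.values <= thr  # (nx, ny, nz, nt)
    out = field.copy()
    out.values = np.where(low[None, ...], 0.0, out.values)
    return out


def mask_below_threshold(
    magnitude: MagnitudeSeries, params: NoiseMaskParams = NoiseMaskParams()
) -> np.ndarray:
    """Boolean (nx, ny, nz, nt) array of voxels at or below the noise threshold."""
    return magnitude.values <= params.resolve(magnitude)


def _neighbor_median(vals: np.ndarray) -> np.ndarray:
    """Median over available face neighbours along the 3 spatial axes.

    ``vals`` has spatial axes in positions -4, -3, -2 and may contain NaN
    for excluded voxels; boundary voxels simply have fewer neighbours.
    """
    stacks = []
    for ax in (-4, -3, -2):
        for shift in (1, -1):
            b = np.roll(vals, shift, axis=ax)
            edge = [slice(None)] * vals.ndim
            edge[ax] = 0 if shift == 1 else -1
            b[tuple(edge)] = np.nan
            stacks.append(b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmedian(np.stack(stacks), axis=0)


def detect_aliased(
    field: VelocityField4D,
    venc_cm_s: Optional[float] = None,
    exclude: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-voxel per-component wrap-count estimates from the neighbour median.

    Returns an integer array shaped like ``field.values``; ``k`` is the
    number of ``2 venc`` offsets to add.  Excluded (e.g. noise-masked)
    voxels contribute nothing to their neighbours' medians and are never
    flagged themselves.
    """
    venc = field.venc_cm_s if venc_cm_s is None else float(venc_cm_s)
    if venc <= 0:
        raise ValueError("venc must be positive")
    vals = field.values.astype(float, copy=True)
    if exclude is not None:
        ex = np.asarray(exclude, dtype=bool)
        if ex.shape != field.grid.shape + (field.grid.n_timesteps,):
            raise ValueError("exclude mask shape must be (nx, ny, nz, nt)")
        vals[:, ex] = np.nan
    med = _neighbor_median(vals)
    diff = med - vals
    with np.errstate(invalid="ignore"):
        flag = np.abs(diff) > venc
    flag &= np.isfinite(diff)
    k = np.zeros_like(vals, dtype=np.int64)
    k[flag] = np.round(diff[flag] / (2.0 * venc)).astype(np.int64)
    return k


def _axis_pairs(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of all face-neighbour pairs of a 3-D grid."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    a_list, b_list = [], []
    for ax in range(3):
        a = np.take(idx, range(0, shape[ax] - 1), axis=ax).ravel()
        b = np.take(idx, range(1, shape[ax]), axis=ax).ravel()
        a_list.append(a)
        b_list.append(b)
    return np.concatenate(a_list), np.concatenate(b_list)


def _unwrap_volume(
    vol: np.ndarray,
    venc: float,
    max_iterations: int,
    valid: Optional[np.ndarray],
    pair_a: np.ndarray,
    pair_b: np.ndarray,
) -> tuple[np.ndarray, list[int], bool]:
    """Region-merging unwrap of a single 3-D volume.  See module docstring."""
    shape = vol.shape
    n = vol.size
    flat = vol.ravel().copy()
    if valid is not None:
        vmask = valid.ravel()
        keep = vmask[pair_a] & vmask[pair_b]
        pair_a, pair_b = pair_a[keep], pair_b[keep]
    else:
        vmask = None
    counts: list[int] = []
    for _ in range(max_iterations):
        diff = flat[pair_a] - flat[pair_b]
        consistent = np.abs(diff) <= venc
        g = sparse.coo_matrix(
            (np.ones(int(consistent.sum())), (pair_a[consistent], pair_b[consistent])),
            shape=(n, n),
        )
        ncomp, labels = connected_components(g, directed=False)
        if vmask is not None:
            sizes = np.bincount(labels[vmask], minlength=ncomp)
        else:
            sizes = np.bincount(labels, minlength=ncomp)
        if (sizes > 0).sum() <= 1:
            counts.append(0)
            break
        anchor = int(np.argmax(sizes))  # ties -> lowest label, i.e. raster-first
        ia = np.concatenate([pair_a[~consistent], pair_b[~consistent]])
        ib = np.concatenate([pair_b[~consistent], pair_a[~consistent]])
        touching = (labels[ia] == anchor) & (labels[ib] != anchor)
        ia, ib = ia[touching], ib[touching]
        corrected = 0
        if ia.size:
            ks = (flat[ia] - flat[ib]) / (2.0 * venc)
            new = flat.copy()
            for comp in np.unique(labels[ib]):
                sel = labels[ib] == comp
                k = float(np.round(np.median(ks[sel])))
                if k != 0.0:
                    members = labels == comp
                    if vmask is not None:
                        members &= vmask
                    new[members] += 2.0 * venc * k
                    corrected += int(members.sum())
            flat = new
        counts.append(corrected)
        if corrected == 0:
            break
    converged = bool(counts and counts[-1] == 0)
    return flat.reshape(shape), counts, converged


def unwrap(
    field: VelocityField4D,
    venc_cm_s: Optional[float] = None,
    max_iterations: int = MAX_UNWRAP_ITERATIONS,
    exclude: Optional[np.ndarray] = None,
) -> tuple[VelocityField4D, UnwrapReport]:
    """Correct velocity aliasing; every change is an exact multiple of 2 venc.

    Each velocity component at each timestep is unwrapped independently.
    Non-convergence within ``max_iterations`` is reported (not raised):
    pathological inputs exist for which no assignment of wrap counts is
    self-consistent, and the report's per-iteration correction counts are
    the right diagnostic for them.

    ``exclude`` marks voxels (e.g. noise-masked background) that must not
    be corrected and must not anchor anyone else's correction.
    """
    venc = field.venc_cm_s if venc_cm_s is None else float(venc_cm_s)
    if venc <= 0:
        raise ValueError("venc must be positive")
    grid = field.grid
    ex = None
    if exclude is not None:
        ex = np.asarray(exclude, dtype=bool)
        if ex.shape != grid.shape + (grid.n_timesteps,):
            raise ValueError("exclude mask shape must be (nx, ny, nz, nt)")
    pair_a, pair_b = _axis_pairs(grid.shape)
    out = field.copy()
    all_counts: list[list[int]] = []
    all_converged = True
    for c in range(3):
        for t in range(grid.n_timesteps):
            valid = None if ex is None else ~ex[..., t]
            corrected, counts, conv = _unwrap_volume(
                out.values[c, ..., t], venc, max_iterations, valid, pair_a, pair_b
            )
            out.values[c, ..., t] = corrected
            all_counts.append(counts)
            all_converged &= conv
    iters = max(len(c) for c in all_counts)
    per_iter = [sum(c[i] for c in all_counts if i < len(c)) for i in range(iters)]
    report = UnwrapReport(
        iterations_run=iters,
        voxels_corrected_per_iteration=per_iter,
        converged=all_converged,
    )
    return out, report
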
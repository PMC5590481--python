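"""End-to-end orchestration: mask -> unwrap -> timing -> vorticity -> stats.

`run_subject` executes the full per-subject chain and is numerically
identical to invoking the stage operations in sequence (it *is* that
sequence); `run_cohort` maps it over a manifest and hands the metric grid
to the cohort statistics.  Stage boundaries match the library modules, so
any intermediate can be persisted and re-ingested without changing the
final metrics.

The timestep fed into vorticity integration is the single peak-E timestep
(early-diastolic vorticity is the metric of interest); per-timestep output
across the whole cycle is available via ``all_timesteps=True``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import preprocess, stats, timing, vorticity
from .core import MagnitudeSeries, SubjectRecord, VelocityField4D, VolumeSeries
from .preprocess import NoiseMaskParams, UnwrapReport
from .timing import DiskProbe, EWaveAmbiguousError, TimingEstimate
from .vorticity import OrientedBoxROI, ThresholdScheme

__all__ = ["RunConfig", "SubjectInput", "SubjectResult", "run_subject", "run_cohort"]

log = logging.getLogger("rhvort.pipeline")


def _log_stage(stage: str, t0: float, **params) -> None:
    log.info(json.dumps({"stage": stage, "duration_s": round(time.perf_counter() - t0, 4), **params}))


@dataclass
class RunConfig:
    """Everything a subject run needs besides the data itself."""

    rois: Sequence[OrientedBoxROI]
    tv_disk: DiskProbe
    schemes: Sequence[str] = ("NONE", "SS", "TS", "SS_TS")
    taus: Sequence[float] = (vorticity.DEFAULT_TAU_REF,)
    ci_ref: float = vorticity.DEFAULT_CI_REF
    mask_params: NoiseMaskParams = dc_field(default_factory=NoiseMaskParams)
    apply_mask: bool = True
    apply_unwrap: bool = True
    max_unwrap_iterations: int = preprocess.MAX_UNWRAP_ITERATIONS
    systole_end_hint_ms: Optional[float] = None
    gating_offset_ms: float = 0.0
    mpa_disk: Optional[DiskProbe] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.schemes:
            if s not in vorticity.SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")


@dataclass
class SubjectInput:
    """One manifest entry for a cohort run."""

    record: SubjectRecord
    field: VelocityField4D
    magnitude: Optional[MagnitudeSeries] = None
    lv_volume: Optional[VolumeSeries] = None


@dataclass
class SubjectResult:
    record: SubjectRecord
    timing: TimingEstimate
    unwrap_report: Optional[UnwrapReport]
    peak_e_timestep: int
    metrics_by_timestep: Optional[pd.DataFrame] = None


def run_subject(
    config: RunConfig,
    field: VelocityField4D,
    magnitude: Optional[MagnitudeSeries],
    record: SubjectRecord,
    lv_volume: Optional[VolumeSeries] = None,
    all_timesteps: bool = False,
) -> SubjectResult:
    """Run the full per-subject chain, filling ``record.metrics`` in place.

    Timing tries direct E-wave detection on the tricuspid flowrate first
    and falls back to the hybrid method (which needs ``lv_volume``) when no
    distinct diastolic peak exists.  Stage failures propagate with the
    stage named.
    """
    stage = "noise_mask"
    try:
        t0 = time.perf_counter()
        exclude = None
        if config.apply_mask and magnitude is not None:
            field = preprocess.noise_mask(field, magnitude, config.mask_params)
            exclude = preprocess.mask_below_threshold(magnitude, config.mask_params)
            _log_stage(stage, t0, threshold=config.mask_params.resolve(magnitude))

        stage = "unwrap"
        t0 = time.perf_counter()
        report: Optional[UnwrapReport] = None
        if config.apply_unwrap:
            field, report = preprocess.unwrap(
                field, max_iterations=config.max_unwrap_iterations, exclude=exclude
            )
            _log_stage(stage, t0, **report.to_dict())

        stage = "timing"
        t0 = time.perf_counter()
        q_tv = timing.flowrate_series(field, config.tv_disk)
        # Direct detection is trusted only when a distinct later A-peak
        # confirms the normal E-before-A pattern; an A-dominant curve puts
        # its largest peak last, in which case the putative "E" is really
        # the A-wave and the hybrid back-off is used instead.
        est = None
        try:
            direct = timing.detect_events_direct(q_tv, config.systole_end_hint_ms)
            if direct.t_A_ms is not None:
                est = direct
        except EWaveAmbiguousError:
            if lv_volume is None:
                raise
        if est is None:
            if lv_volume is None:
                raise EWaveAmbiguousError(
                    "E-wave not confirmed by a later A-peak and no LV volume curve "
                    "is available for the hybrid method"
                )
            est = timing.detect_events_hybrid(
                q_tv,
                timing.dvdt(lv_volume),
                systole_end_hint_ms=config.systole_end_hint_ms,
                lv_systole_end_hint_ms=config.systole_end_hint_ms,
                gating_offset_ms=config.gating_offset_ms,
            )
        dt = field.grid.dt_ms
        peak_e_t = int(np.clip(round(est.t_E_ms / dt), 0, field.grid.n_timesteps - 1))
        _log_stage(stage, t0, method=est.method, t_E_ms=est.t_E_ms, timestep=peak_e_t)

        stage = "vorticity"
        t0 = time.perf_counter()
        timesteps = range(field.grid.n_timesteps) if all_timesteps else [peak_e_t]
        rows = []
        for t in timesteps:
            omega = vorticity.compute_vorticity(field, t)
            for roi in config.rois:
                for scheme_name in config.schemes:
                    for tau in config.taus:
                        scheme = ThresholdScheme(scheme_name, tau_ref=tau, ci_ref=config.ci_ref)
                        metric = vorticity.subject_metric(
                            omega, roi, scheme, ci_subject=record.cardiac_index
                        )
                        if t == peak_e_t:
                            record.metrics[(roi.label, scheme_name, tau)] = metric.value
                        rows.append(
                            dict(
                                timestep=t,
                                roi=roi.label,
                                scheme=scheme_name,
                                tau=tau,
                                threshold_used=metric.threshold_used,
                                value=metric.value,
                            )
                        )
        _log_stage(stage, t0, timestep=peak_e_t, n_metrics=len(record.metrics))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed for {record.subject_id}: {exc}") from exc

    return SubjectResult(
        record=record,
        timing=est,
        unwrap_report=report,
        peak_e_timestep=peak_e_t,
        metrics_by_timestep=pd.DataFrame(rows) if all_timesteps else None,
    )


def run_cohort(
    config: RunConfig,
    manifest: Sequence[SubjectInput],
) -> tuple[pd.DataFrame, list[stats.GroupComparison]]:
    """Run every manifest subject, then the group-comparison grid.

    Returns the long-format per-subject metric table and the sorted list
    of :class:`~rhvort.stats.GroupComparison` rows.  Completion does not
    depend on statistical significance.
    """
    if not manifest:
        raise ValueError("empty manifest")
    ids = [m.record.subject_id for m in manifest]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate subject ids in manifest: {sorted(dupes)}")
    groups = pd.Series([m.record.group for m in manifest]).value_counts()
    if len(groups) < 2 or groups.min() < 2:
        raise ValueError("manifest needs at least 2 subjects in each of the two groups")

    results = [
        run_subject(config, m.field, m.magnitude, m.record, lv_volume=m.lv_volume)
        for m in manifest
    ]
    records = [r.record for r in results]
    rows = []
    for rec in records:
        for (roi, scheme, tau), value in rec.metrics.items():
            rows.append(
                dict(
                    subject_id=rec.subject_id,
                    group=rec.group,
                    cardiac_index=rec.cardiac_index,
                    roi=roi,
                    scheme=scheme,
                    tau=tau,
                    value=value,
                )
            )
    table = pd.DataFrame(rows)
    grid = stats.cohort_grid(
        records,
        rois=[roi.label for roi in config.rois],
        schemes=list(config.schemes),
        taus=list(config.taus),
    )
    return table, grid
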
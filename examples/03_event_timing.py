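"""E-wave timing on normal and dysfunction-like phantoms.

A normal subject shows a dominant early-diastolic (E) inflow peak that can
be read directly off the tricuspid flowrate curve.  With impaired
relaxation the late (A) peak dominates and the E-peak is barely visible,
so the hybrid method measures the E-to-A interval on the LV dV/dt curve
and backs off from the dominant A-peak.
"""

from rhvort import (
    CardiacWaveformParams,
    DiskProbe,
    GridSpec,
    detect_events_direct,
    detect_events_hybrid,
    dvdt,
    make_cardiac_phantom,
)
from rhvort.timing import flowrate_series

grid = GridSpec(shape=(32, 32, 24), spacing_mm=(2.0, 2.0, 3.0), n_timesteps=20, dt_ms=50.0)
disk = DiskProbe(tuple(grid.center_mm()), (0.0, 0.0, 1.0), radius_mm=15.0)

normal = CardiacWaveformParams(t_E_ms=400.0, t_A_ms=750.0,
                               peak_E_Q_ml_s=300.0, peak_A_Q_ml_s=150.0)
field, q_true, lv = make_cardiac_phantom(normal, grid, disk)
q = flowrate_series(field, disk)  # probe the 3-D field, don't reuse the truth
est = detect_events_direct(q, systole_end_hint_ms=280.0)
print("normal filling (E > A):")
print(f"  true t_E = {normal.t_E_ms:.0f} ms, estimated {est.t_E_ms:.0f} ms "
      f"({est.method}); t_A estimated {est.t_A_ms:.0f} ms")

rvdd = CardiacWaveformParams(t_E_ms=400.0, t_A_ms=800.0,
                             peak_E_Q_ml_s=100.0, peak_A_Q_ml_s=280.0, lv_delay_ms=30.0)
field, _, lv = make_cardiac_phantom(rvdd, grid, disk)
q = flowrate_series(field, disk)
est = detect_events_hybrid(q, dvdt(lv), systole_end_hint_ms=280.0,
                           lv_systole_end_hint_ms=310.0)
print("impaired relaxation (A > E):")
print(f"  true t_E = {rvdd.t_E_ms:.0f} ms, estimated {est.t_E_ms:.0f} ms "
      f"({est.method}, LV diastasis {est.lv_diastasis_dt_ms:.0f} ms)")
# Both estimates land within one 50 ms timestep of the truth; the hybrid
# back-off is what makes the A-dominant case tractable at all.
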
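"""Velocity aliasing and its iterative correction.

Builds a smooth velocity field whose peak speed (150 cm/s) exceeds the
encoding limit (venc = 100 cm/s), wraps it the way a phase-contrast scan
would, and recovers the truth with the region-merging unwrapper.
"""

import numpy as np

from rhvort import GridSpec, make_smooth_blob_field, unwrap, wrap_velocities

venc = 100.0
grid = GridSpec(shape=(24, 24, 24), spacing_mm=(2.0, 2.0, 3.0))
truth = make_smooth_blob_field(grid, venc_cm_s=venc, peak_fraction=1.5, seed=42)

wrapped = wrap_velocities(truth, venc)
n_aliased = int(np.count_nonzero(wrapped.values != truth.values))
recovered, report = unwrap(wrapped, venc)

print(f"peak speed              : {np.abs(truth.values).max():.1f} cm/s (venc = {venc:.0f})")
print(f"aliased samples         : {n_aliased}")
print(f"iterations run          : {report.iterations_run} (cap 10)")
print(f"corrected per iteration : {report.voxels_corrected_per_iteration}")
print(f"converged               : {report.converged}")
print(f"recovered bit-exactly   : {np.array_equal(recovered.values, truth.values)}")
# Aliased voxels appear where the jet exceeds +/-venc; every correction is
# an exact multiple of 2*venc, so recovery of a smooth field is lossless.
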
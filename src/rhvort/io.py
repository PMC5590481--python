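"""Reading and writing velocity fields, magnitude series and time series.

Storage convention: one 4-D scalar NIfTI volume per velocity component
(x, y, z component order), plus a JSON sidecar carrying acquisition
metadata the NIfTI header cannot hold::

    {"venc_cm_s": 150.0, "dt_ms": 50.0, "gating": "prospective",
     "velocity_unit": "cm/s"}

Geometry (voxel spacing, origin) lives in the NIfTI affine, which is
restricted here to axis-aligned scaling plus translation.  Volumes are
written float32; CSV time series are written in full decimal text, so all
round trips are lossless at the declared precision.

A legacy-ASCII VTK structured-points writer is included for viewing fields
in VTK-based tools; the matching minimal reader exists so round trips can
be verified without a VTK installation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FlowrateSeries, GridSpec, MagnitudeSeries, VelocityField4D, VolumeSeries
from .vorticity import VorticityField

__all__ = [
    "write_velocity",
    "read_velocity",
    "write_magnitude",
    "read_magnitude",
    "export_vtk",
    "read_vtk_structured_points",
    "read_timeseries",
    "write_timeseries",
]

_AXIS_NAMES = "xyzt"


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing_mm)
    aff[:3, 3] = grid.origin_mm
    return aff


def _grid_from_nifti(img: nib.Nifti1Image, dt_ms: float) -> GridSpec:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError("only axis-aligned affines are supported")
    shape = img.shape[:3]
    nt = img.shape[3] if len(img.shape) == 4 else 1
    return GridSpec(
        shape=tuple(int(n) for n in shape),
        spacing_mm=tuple(float(aff[i, i]) for i in range(3)),
        origin_mm=tuple(float(aff[i, 3]) for i in range(3)),
        n_timesteps=int(nt),
        dt_ms=float(dt_ms),
    )


def write_velocity(
    field: VelocityField4D,
    component_paths: Sequence[Union[str, Path]],
    sidecar_path: Union[str, Path],
) -> None:
    """Write one 4-D float32 NIfTI per component plus the JSON sidecar."""
    if len(component_paths) != 3:
        raise ValueError("need exactly three component paths (x, y, z)")
    aff = _affine(field.grid)
    for c, path in enumerate(component_paths):
        img = nib.Nifti1Image(field.values[c].astype(np.float32), aff)
        img.header.set_xyzt_units("mm", "msec")
        nib.save(img, str(path))
    sidecar = {
        "venc_cm_s": field.venc_cm_s,
        "dt_ms": field.grid.dt_ms,
        "gating": field.gating,
        "velocity_unit": "cm/s",
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_velocity(
    component_paths: Sequence[Union[str, Path]],
    sidecar_path: Union[str, Path],
) -> VelocityField4D:
    """Assemble a velocity field from three per-component volumes + sidecar.

    Components must agree in shape and affine; the sidecar must supply
    venc.  Values are converted to cm/s if the sidecar declares m/s.
    """
    if len(component_paths) != 3:
        raise ValueError("need exactly three component paths (x, y, z)")
    meta = json.loads(Path(sidecar_path).read_text())
    if "venc_cm_s" not in meta:
        raise ValueError("sidecar is missing required key 'venc_cm_s'")
    imgs = [nib.load(str(p)) for p in component_paths]
    ref_shape = imgs[0].shape
    for c, img in enumerate(imgs[1:], start=1):
        if img.shape != ref_shape:
            for ax, (a, b) in enumerate(zip(ref_shape, img.shape)):
                if a != b:
                    raise ValueError(
                        f"component {c} shape mismatch along axis {_AXIS_NAMES[ax]}: {a} vs {b}"
                    )
            raise ValueError(f"component {c} dimensionality mismatch: {ref_shape} vs {img.shape}")
        if not np.allclose(img.affine, imgs[0].affine, atol=1e-6):
            raise ValueError(f"component {c} affine differs from component 0")
    grid = _grid_from_nifti(imgs[0], dt_ms=float(meta.get("dt_ms", 50.0)))
    data = np.stack([np.asarray(img.dataobj, dtype=np.float64) for img in imgs])
    if data.ndim == 4:  # single-timestep volumes
        data = data[..., None]
    unit = meta.get("velocity_unit", "cm/s")
    if unit == "m/s":
        data = data * 100.0
    elif unit != "cm/s":
        raise ValueError(f"unsupported velocity unit {unit!r}")
    return VelocityField4D(
        values=data,
        grid=grid,
        venc_cm_s=float(meta["venc_cm_s"]),
        gating=meta.get("gating", "prospective"),
    )


def write_magnitude(magnitude: MagnitudeSeries, path: Union[str, Path]) -> None:
    img = nib.Nifti1Image(magnitude.values.astype(np.float32), _affine(magnitude.grid))
    img.header.set_xyzt_units("mm", "msec")
    nib.save(img, str(path))


def read_magnitude(path: Union[str, Path], dt_ms: float = 50.0) -> MagnitudeSeries:
    img = nib.load(str(path))
    grid = _grid_from_nifti(img, dt_ms=dt_ms)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    return MagnitudeSeries(values=data, grid=grid)


def export_vtk(
    obj: Union[VelocityField4D, VorticityField],
    path: Union[str, Path],
    timestep: int = 0,
) -> None:
    """Write a legacy-ASCII VTK structured-points file with point vectors.

    The vector array is named ``"velocity"`` for velocity fields and
    ``"vorticity"`` for vorticity fields, so downstream VTK-based viewers
    pick it up by name.  Values are written at float32 precision.
    """
    if isinstance(obj, VelocityField4D):
        vectors = obj.values[..., timestep]
        name = "velocity"
        grid = obj.grid
    elif isinstance(obj, VorticityField):
        vectors = obj.vectors
        name = "vorticity"
        grid = obj.grid
    else:
        raise TypeError("export_vtk accepts a VelocityField4D or VorticityField")
    nx, ny, nz = grid.shape
    # VTK point order: x fastest, then y, then z -> Fortran raveling
    flat = np.stack([vectors[c].ravel(order="F") for c in range(3)], axis=1).astype(np.float32)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"rhvort {name} export\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN {} {} {}\n".format(*grid.origin_mm))
        fh.write("SPACING {} {} {}\n".format(*grid.spacing_mm))
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"VECTORS {name} float\n")
        np.savetxt(fh, flat, fmt="%.9g")


def read_vtk_structured_points(path: Union[str, Path]):
    """Minimal reader for files produced by :func:`export_vtk`.

    Returns ``(vectors, spacing_mm, origin_mm, array_name)`` with vectors
    shaped (3, nx, ny, nz).
    """
    lines = Path(path).read_text().splitlines()
    dims = spacing = origin = None
    name = None
    data_start = None
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "DIMENSIONS":
            dims = tuple(int(x) for x in parts[1:4])
        elif parts[0] == "SPACING":
            spacing = tuple(float(x) for x in parts[1:4])
        elif parts[0] == "ORIGIN":
            origin = tuple(float(x) for x in parts[1:4])
        elif parts[0] == "VECTORS":
            name = parts[1]
            data_start = i + 1
            break
    if dims is None or data_start is None:
        raise ValueError("not a structured-points vector file")
    n = int(np.prod(dims))
    flat = np.loadtxt(lines[data_start : data_start + n], dtype=np.float64).reshape(n, 3)
    vectors = np.stack([flat[:, c].reshape(dims, order="F") for c in range(3)])
    return vectors, spacing, origin, name


_VALUE_COLUMNS = {
    "flowrate_ml_s": ("flowrate", FlowrateSeries),
    "flow_ml_s": ("flowrate", FlowrateSeries),
    "volume_ml": ("volume", VolumeSeries),
}


def read_timeseries(path: Union[str, Path]) -> Union[FlowrateSeries, VolumeSeries]:
    """Read a two-column CSV time series; units come from the header suffix.

    The first column must be ``time_ms``; the second is ``flowrate_ml_s``
    (or ``flow_ml_s``) for flowrates and ``volume_ml`` for volumes.
    Non-monotone times are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if len(cols) != 2 or cols[0] != "time_ms":
        raise ValueError(f"expected columns [time_ms, <value_unit>], got {cols}")
    if cols[1] not in _VALUE_COLUMNS:
        raise ValueError(
            f"unrecognised value column {cols[1]!r}; expected one of {sorted(_VALUE_COLUMNS)}"
        )
    _, cls = _VALUE_COLUMNS[cols[1]]
    return cls(df[cols[0]].to_numpy(dtype=float), df[cols[1]].to_numpy(dtype=float))


def write_timeseries(series: Union[FlowrateSeries, VolumeSeries], path: Union[str, Path]) -> None:
    if isinstance(series, FlowrateSeries):
        col, values = "flowrate_ml_s", series.values_ml_s
    elif isinstance(series, VolumeSeries):
        col, values = "volume_ml", series.values_ml
    else:
        raise TypeError("write_timeseries accepts a FlowrateSeries or VolumeSeries")
    df = pd.DataFrame({"time_ms": series.times_ms, col: values})
    df.to_csv(path, index=False, float_format="%.17g")  # lossless float64 text
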
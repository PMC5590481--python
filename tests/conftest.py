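import numpy as np
import pytest

from rhvort import (
    AnalyticFlowParams,
    CardiacWaveformParams,
    DiskProbe,
    GridSpec,
    make_analytic_field,
    make_cardiac_phantom,
)


@pytest.fixture
def small_grid():
    return GridSpec(shape=(16, 16, 16), spacing_mm=(2.0, 2.0, 2.0), n_timesteps=1)


@pytest.fixture
def aniso_grid():
    """Anisotropic voxels typical of a 4D Flow acquisition (2 x 2 x 3 mm)."""
    return GridSpec(shape=(20, 20, 14), spacing_mm=(2.0, 2.0, 3.0), n_timesteps=2)


@pytest.fixture
def solid_body_field(small_grid):
    params = AnalyticFlowParams("solid_body", angular_velocity_s=(0.0, 0.0, 5.0))
    return make_analytic_field(params, small_grid)


@pytest.fixture
def phantom_grid():
    return GridSpec(shape=(32, 32, 24), spacing_mm=(2.0, 2.0, 3.0), n_timesteps=20, dt_ms=50.0)


@pytest.fixture
def valve_disk(phantom_grid):
    return DiskProbe(tuple(phantom_grid.center_mm()), (0.0, 0.0, 1.0), 15.0)


@pytest.fixture
def normal_phantom(phantom_grid, valve_disk):
    """E-dominant (normal filling) phantom: field, flowrate truth, LV volume."""
    params = CardiacWaveformParams(
        t_systole_ms=150.0, t_E_ms=400.0, t_A_ms=750.0,
        peak_systolic_Q_ml_s=350.0, peak_E_Q_ml_s=300.0, peak_A_Q_ml_s=150.0,
    )
    field, q, vol = make_cardiac_phantom(params, phantom_grid, valve_disk)
    return params, field, q, vol


@pytest.fixture
def rvdd_phantom(phantom_grid, valve_disk):
    """A-dominant (impaired relaxation) phantom: E-wave small, A-wave dominant."""
    params = CardiacWaveformParams(
        t_systole_ms=150.0, t_E_ms=400.0, t_A_ms=800.0,
        peak_systolic_Q_ml_s=350.0, peak_E_Q_ml_s=100.0, peak_A_Q_ml_s=280.0,
    )
    field, q, vol = make_cardiac_phantom(params, phantom_grid, valve_disk)
    return params, field, q, vol
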
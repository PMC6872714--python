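import numpy as np
import pytest

from airwaycp import (
    AIR,
    BreathingWaveform,
    CpStarResult,
    GeometryParams,
    SolverSettings,
    build_geometry,
    generate_cohort,
    run_cohort,
    solve,
    uniform_tube_params,
)

SEVERITY_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@pytest.fixture(scope="session")
def default_waveform():
    """500 ml tidal volume, tau = 5 s, dt = 1 ms, inhalation half-cycle."""
    return BreathingWaveform.from_tidal_volume()


@pytest.fixture(scope="session")
def uniform_tube():
    """0.22 m long, 16 mm diameter circular tube."""
    return build_geometry(uniform_tube_params())


@pytest.fixture(scope="session")
def severity_sweep(default_waveform):
    """Solved fields + Cp* results across the severity grid (shared: the
    sweep is the most expensive repeated computation in the suite)."""
    out = {}
    settings = SolverSettings()
    for s in SEVERITY_GRID:
        g = build_geometry(GeometryParams(severity=s))
        fields = solve(g, default_waveform, AIR, settings)
        res = CpStarResult.from_fields(fields, g, settings.sample_time_s)
        out[s] = (g, fields, res)
    return out


@pytest.fixture(scope="session")
def noise_free_cohort20(default_waveform):
    """Noise-free 20-patient virtual cohort with its simulated metrics table."""
    patients = generate_cohort(20, seed=0, sigma_geom=0.0, sigma_ahi=0.0)
    table = run_cohort(patients, default_waveform)
    return patients, table
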
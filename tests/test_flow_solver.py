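import math

import numpy as np
import pytest

from airwaycp import (
    AIR,
    BreathingWaveform,
    ConstantFlow,
    GeometryParams,
    ParameterError,
    SolverError,
    SolverSettings,
    build_geometry,
    friction_factor,
    grid_convergence_study,
    solve,
    uniform_tube_params,
    wall_shear_stress,
)
from airwaycp.geometry import AirwayGeometry, Landmarks

STEADY = SolverSettings(sample_time_s=0.001)


def steady_flow(q):
    return ConstantFlow(q, duration_s=0.002, time_step_s=1e-3)


class TestFrictionFactor:
    def test_laminar_value(self):
        assert friction_factor(1000.0) == pytest.approx(0.064, rel=1e-12)

    def test_blasius_value(self):
        assert friction_factor(10000.0) == pytest.approx(0.0316, rel=1e-12)

    def test_blend_midpoint(self):
        lo, hi = friction_factor(2000.0), friction_factor(4000.0)
        assert friction_factor(3000.0) == pytest.approx(0.5 * (lo + hi), rel=1e-12)

    def test_continuous_at_regime_edges(self):
        assert friction_factor(2000.0) == pytest.approx(64.0 / 2000.0)
        assert friction_factor(4000.0) == pytest.approx(0.316 * 4000.0**-0.25)

    def test_negative_reynolds_rejected(self):
        with pytest.raises(ParameterError):
            friction_factor(-1.0)


class TestWallShearStress:
    def test_zero_velocity(self):
        assert wall_shear_stress(0.0, 0.016) == 0.0

    def test_laminar_closed_form(self):
        # 8 mu |u| / D with air viscosity
        assert wall_shear_stress(1.0, 0.016) == pytest.approx(
            8 * 1.82e-5 / 0.016, rel=1e-12
        )

    def test_laminar_linearity_in_velocity(self):
        assert wall_shear_stress(0.5, 0.016) == pytest.approx(
            2 * wall_shear_stress(0.25, 0.016), rel=1e-12
        )

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ParameterError):
            wall_shear_stress(1.0, 0.0)


class TestSolveOracles:
    def test_no_flow_gives_null_fields(self, uniform_tube):
        fields = solve(uniform_tube, steady_flow(0.0), AIR, STEADY)
        assert np.all(fields.pressure_pa == 0.0)
        assert np.all(fields.velocity_mps == 0.0)
        assert np.all(fields.wss_pa == 0.0)

    @pytest.mark.parametrize("reynolds", [10.0, 100.0, 1000.0])
    def test_hagen_poiseuille(self, uniform_tube, reynolds):
        """Laminar steady uniform-tube pressure drop matches the closed form
        128 mu L Q / (pi D^4) within 0.1% across Re 10-1000."""
        mu, rho, d, length = 1.82e-5, 1.204, 0.016, 0.22
        u = reynolds * mu / (rho * d)
        q = u * math.pi * d**2 / 4.0
        st = SolverSettings(friction_model="laminar_only", sample_time_s=0.001)
        fields = solve(uniform_tube, steady_flow(q), AIR, st)
        expected = 128.0 * mu * length * q / (math.pi * d**4)
        assert fields.pressure_drop(0.001) == pytest.approx(expected, rel=1e-3)

    def test_bernoulli_total_pressure_constant(self):
        """Inviscid steady flow through a constricted airway conserves
        P + rho u^2 / 2 along the axis within 0.1%."""
        g = build_geometry(GeometryParams(severity=0.5))
        st = SolverSettings(
            friction_model="inviscid", expansion_loss_enabled=False, sample_time_s=0.001
        )
        fields = solve(g, steady_flow(3e-4), AIR, st)
        snap = fields.at_time(0.001)
        total = snap["pressure_pa"] + 0.5 * AIR.density_kgm3 * snap["velocity_mps"] ** 2
        assert np.ptp(total) <= 1e-3 * abs(total).max()

    def test_mass_conservation_every_time_step(self, severity_sweep):
        """u * A equals the driving flow rate at every station and time to
        10 significant digits (rigid incompressible continuity)."""
        _, fields, _ = severity_sweep[0.75]
        flux = fields.velocity_mps * fields.area_m2[None, :]
        np.testing.assert_allclose(
            flux, fields.flow_m3s[:, None] * np.ones_like(flux), rtol=1e-10
        )

    def test_wss_nonnegative_and_zero_at_rest(self, severity_sweep):
        _, fields, _ = severity_sweep[0.5]
        assert np.all(fields.wss_pa >= 0.0)
        # t = 0: sinusoidal flow is zero
        assert np.all(fields.wss_pa[0] == 0.0)

    def test_inviscid_pressure_symmetric_over_full_cycle(self, uniform_tube):
        """Without friction the pressure field at mirrored instants t and
        tau - t coincides (equal |Q| and equal acceleration)."""
        w = BreathingWaveform.from_tidal_volume(duration_s=5.0)
        st = SolverSettings(
            friction_model="inviscid", expansion_loss_enabled=False, sample_time_s=1.0
        )
        fields = solve(uniform_tube, w, AIR, st)
        p_t = fields.at_time(1.0)["pressure_pa"]
        p_mirror = fields.at_time(4.0)["pressure_pa"]
        np.testing.assert_allclose(p_t, p_mirror, atol=1e-12)


class TestSeverityMonotonicity:
    """Narrowing the velopharynx raises jet velocity, wall shear stress and
    the pharyngeal pressure drop at peak inhalation."""

    def test_velopharyngeal_velocity(self, severity_sweep):
        v = [res.landmarks.v_velopharynx_mps for _, _, res in severity_sweep.values()]
        assert all(b >= a for a, b in zip(v, v[1:]))

    def test_peak_wall_shear_stress(self, severity_sweep):
        peaks = [
            fields.at_time(1.25)["wss_pa"].max()
            for _, fields, _ in severity_sweep.values()
        ]
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))

    def test_inlet_to_oropharynx_pressure_drop(self, severity_sweep):
        drops = []
        for g, fields, _ in severity_sweep.values():
            drops.append(fields.pressure_drop(1.25, 0, g.landmarks.oropharynx_plane))
        assert all(b >= a for a, b in zip(drops, drops[1:]))


class TestSolverErrors:
    def test_area_below_floor_names_station(self, uniform_tube):
        g = build_geometry(GeometryParams())
        area = g.area_m2.copy()
        area[60] = 5e-8
        bad = AirwayGeometry(
            x_m=g.x_m,
            area_m2=area,
            region=g.region,
            landmarks=g.landmarks,
            severity=0.0,
        )
        with pytest.raises(SolverError, match="station 60"):
            solve(bad, steady_flow(1e-4), AIR, STEADY)


class TestGridConvergence:
    def test_uniform_tube_resolution_independent(self, default_waveform):
        table = grid_convergence_study(
            uniform_tube_params(), default_waveform, station_counts=(50, 100, 200)
        )
        assert np.all(table["rel_change_vs_finest"].to_numpy() < 1e-9)

    def test_constricted_changes_decrease_with_refinement(self, default_waveform):
        table = grid_convergence_study(
            GeometryParams(severity=0.5),
            default_waveform,
            station_counts=(50, 100, 200, 400),
        )
        rel = table["rel_change_vs_finest"].to_numpy()[:-1]
        assert np.all(np.diff(rel) < 0)

    def test_deterministic(self, default_waveform):
        kwargs = dict(station_counts=(50, 100, 200))
        a = grid_convergence_study(
            GeometryParams(severity=0.25), default_waveform, **kwargs
        )
        b = grid_convergence_study(
            GeometryParams(severity=0.25), default_waveform, **kwargs
        )
        assert a.equals(b)

    def test_too_few_resolutions_rejected(self, default_waveform):
        with pytest.raises(ParameterError):
            grid_convergence_study(
                GeometryParams(), default_waveform, station_counts=(50, 100)
            )
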
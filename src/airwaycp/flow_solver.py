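"""Quasi-1D unsteady flow through a rigid airway.

The three-dimensional airway flow is reduced to an area-averaged description
along the duct axis.  Rigid walls and incompressible air make the volumetric
flow rate spatially uniform, so the velocity field is algebraic,
``u(x, t) = Q(t) / A(x)``, and the gauge pressure follows from an unsteady
mechanical-energy balance referenced to the nasal inlet (P = 0 at x = 0):

    P(x, t) = - rho * Q'(t) * I(x)                      (flow acceleration)
              - rho/2 * (u(x,t)^2 - u(0,t)^2)           (convective, reversible)
              - Lf(x, t)                                (wall friction)
              - Lm(x, t)                                (sudden-expansion losses)

with ``I(x) = integral_0^x dx'/A(x')``.  Friction uses a Darcy friction
factor closure: the laminar closed form (64/Re, i.e. a pressure gradient of
32 mu u / D^2) up to Re = 2000, the Blasius correlation 0.316 Re^-0.25 from
Re = 4000, and a linear blend in Re in between.  Irreversible losses at
sudden expansions follow Borda–Carnot, K = (1 - A_up/A_down)^2, applied at
every interface where the area grows by more than 10% between adjacent
stations.  Wall shear stress comes from the same closure,
tau_w = f_D/8 * rho * u^2 (= 8 mu |u| / D in the laminar regime).

This solver replaces a resolved 3D turbulence simulation with closures; it
reproduces exactly the area-averaged plane pressures and velocities that the
Cp* metric consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .exceptions import NumericalError, ParameterError, SolverError
from .geometry import AirwayGeometry, build_geometry, GeometryParams

__all__ = [
    "FluidProperties",
    "AIR",
    "SolverSettings",
    "ConstantFlow",
    "FlowFields",
    "friction_factor",
    "wall_shear_stress",
    "solve",
    "grid_convergence_study",
]

_RE_LAMINAR = 2000.0
_RE_TURBULENT = 4000.0


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density [kg/m3] and dynamic viscosity [Pa s]."""

    density_kgm3: float = 1.204
    viscosity_pas: float = 1.82e-5

    def __post_init__(self) -> None:
        if self.density_kgm3 <= 0:
            raise ParameterError("density_kgm3: must be positive")
        if self.viscosity_pas <= 0:
            raise ParameterError("viscosity_pas: must be positive")


#: Air at roughly 20 degrees C.
AIR = FluidProperties()

FrictionModel = Literal["laminar_turbulent_blend", "laminar_only", "inviscid"]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for :func:`solve`.

    ``sample_time_s`` is the instant at which downstream metrics are read
    (peak inhalation, 1.25 s, by default).  ``area_floor_m2`` guards the
    rigid-wall model against near-closed lumens where the quasi-1D balance
    loses meaning.
    """

    time_step_s: float = 1e-3
    sample_time_s: float = 1.25
    friction_model: FrictionModel = "laminar_turbulent_blend"
    expansion_loss_enabled: bool = True
    expansion_threshold: float = 0.10
    area_floor_m2: float = 1e-7

    def __post_init__(self) -> None:
        if self.time_step_s <= 0:
            raise ParameterError("time_step_s: must be positive")
        if self.friction_model not in (
            "laminar_turbulent_blend",
            "laminar_only",
            "inviscid",
        ):
            raise ParameterError(f"friction_model: unknown model {self.friction_model!r}")


@dataclass(frozen=True)
class ConstantFlow:
    """Steady drive Q(t) = q0, used by the closed-form validation oracles."""

    q_m3s: float
    duration_s: float = 1.0
    time_step_s: float = 1e-3

    def flow_rate(self, t):
        arr = np.asarray(t, dtype=float)
        q = np.full_like(arr, self.q_m3s)
        return float(q) if arr.ndim == 0 else q

    def flow_rate_derivative(self, t):
        arr = np.asarray(t, dtype=float)
        dq = np.zeros_like(arr)
        return float(dq) if arr.ndim == 0 else dq

    def times(self) -> np.ndarray:
        n = int(round(self.duration_s / self.time_step_s))
        return np.linspace(0.0, self.duration_s, n + 1)


def friction_factor(reynolds):
    """Darcy friction factor f_D(Re).

    64/Re for 0 < Re <= 2000; Blasius 0.316 Re^-0.25 for Re >= 4000; linear
    interpolation in Re between.  Diverges as Re -> 0: callers must fall back
    to the laminar closed form (the loss term 32 mu u / D^2 stays finite).
    """
    arr = np.asarray(reynolds, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("reynolds: must be nonnegative")
    with np.errstate(divide="ignore"):
        lam = np.where(arr > 0, 64.0 / np.where(arr > 0, arr, 1.0), np.inf)
    turb = 0.316 * np.maximum(arr, 1e-300) ** -0.25
    f_lo = 64.0 / _RE_LAMINAR
    f_hi = 0.316 * _RE_TURBULENT**-0.25
    w = (arr - _RE_LAMINAR) / (_RE_TURBULENT - _RE_LAMINAR)
    blend = f_lo + (f_hi - f_lo) * w
    f = np.where(arr <= _RE_LAMINAR, lam, np.where(arr >= _RE_TURBULENT, turb, blend))
    return float(f) if arr.ndim == 0 else f


def _wss(u, d_h, fluid: FluidProperties, model: FrictionModel) -> np.ndarray:
    if model == "inviscid":
        return np.zeros_like(np.asarray(u, dtype=float))
    rho, mu = fluid.density_kgm3, fluid.viscosity_pas
    u = np.asarray(u, dtype=float)
    lam = 8.0 * mu * np.abs(u) / d_h
    if model == "laminar_only":
        return lam
    re = rho * np.abs(u) * d_h / mu
    turb = friction_factor(np.maximum(re, _RE_LAMINAR)) / 8.0 * rho * u**2
    return np.where(re <= _RE_LAMINAR, lam, turb)


def wall_shear_stress(u, d_h: float, fluid: FluidProperties = AIR):
    """Wall shear stress magnitude tau_w = f_D/8 rho u^2 [Pa].

    Reduces to 8 mu |u| / D in the laminar regime; zero at u = 0.
    """
    if np.any(np.asarray(d_h) <= 0):
        raise ParameterError("d_h: hydraulic diameter must be positive")
    out = _wss(u, d_h, fluid, "laminar_turbulent_blend")
    arr = np.asarray(u)
    return float(out) if arr.ndim == 0 else out


def _friction_gradient(
    u: np.ndarray, d: np.ndarray, fluid: FluidProperties, model: FrictionModel
) -> np.ndarray:
    """Signed friction pressure-gradient (f_D / D) * rho u |u| / 2 [Pa/m]."""
    if model == "inviscid":
        return np.zeros_like(u)
    rho, mu = fluid.density_kgm3, fluid.viscosity_pas
    lam = 32.0 * mu * u / d**2  # 64/Re closed form, finite at u -> 0
    if model == "laminar_only":
        return lam
    re = rho * np.abs(u) * d / mu
    gen = friction_factor(np.maximum(re, _RE_LAMINAR)) / d * rho * u * np.abs(u) / 2.0
    return np.where(re <= _RE_LAMINAR, lam, gen)


@dataclass
class FlowFields:
    """Solution on the (time x station) grid.

    Pressure is gauge, referenced to 0 at the nasal inlet.  All 2D arrays
    are shaped (n_times, n_stations).
    """

    times_s: np.ndarray
    x_m: np.ndarray
    area_m2: np.ndarray
    flow_m3s: np.ndarray
    pressure_pa: np.ndarray
    velocity_mps: np.ndarray
    reynolds: np.ndarray
    wss_pa: np.ndarray
    geometry: AirwayGeometry = field(repr=False, default=None)

    def _time_weights(self, t: float) -> tuple[int, int, float]:
        t0, t1 = self.times_s[0], self.times_s[-1]
        if not (t0 <= t <= t1 * (1 + 1e-12)):
            raise ParameterError(f"t: {t} s outside the simulated window [{t0}, {t1}] s")
        i = int(np.searchsorted(self.times_s, t, side="right")) - 1
        i = min(max(i, 0), self.times_s.size - 2)
        w = (t - self.times_s[i]) / (self.times_s[i + 1] - self.times_s[i])
        return i, i + 1, float(np.clip(w, 0.0, 1.0))

    def at_time(self, t: float) -> dict[str, np.ndarray]:
        """Linear time-interpolation of every field to instant ``t``."""
        i, j, w = self._time_weights(t)
        out = {}
        for name in ("pressure_pa", "velocity_mps", "reynolds", "wss_pa"):
            arr = getattr(self, name)
            out[name] = (1.0 - w) * arr[i] + w * arr[j]
        out["flow_m3s"] = (1.0 - w) * self.flow_m3s[i] + w * self.flow_m3s[j]
        return out

    def pressure_drop(self, t: float, i_from: int = 0, i_to: int = -1) -> float:
        """P(i_from) - P(i_to) at instant ``t`` [Pa]."""
        p = self.at_time(t)["pressure_pa"]
        return float(p[i_from] - p[i_to])

    def to_dataframe(self, stride_t: int = 1) -> pd.DataFrame:
        """Long-format table, one row per (t, x)."""
        ts = self.times_s[::stride_t]
        nt, ns = ts.size, self.x_m.size
        return pd.DataFrame(
            {
                "t_s": np.repeat(ts, ns),
                "x_m": np.tile(self.x_m, nt),
                "area_m2": np.tile(self.area_m2, nt),
                "u_mps": self.velocity_mps[::stride_t].ravel(),
                "P_Pa": self.pressure_pa[::stride_t].ravel(),
                "Re": self.reynolds[::stride_t].ravel(),
                "wss_Pa": self.wss_pa[::stride_t].ravel(),
            }
        )

    def summary_record(self, t: float) -> dict:
        """Compact per-instant JSON-ready summary."""
        snap = self.at_time(t)
        return {
            "t_s": t,
            "flow_m3s": float(snap["flow_m3s"]),
            "peak_velocity_mps": float(np.max(np.abs(snap["velocity_mps"]))),
            "peak_wss_pa": float(np.max(snap["wss_pa"])),
            "inlet_to_outlet_dp_pa": float(snap["pressure_pa"][0] - snap["pressure_pa"][-1]),
        }

    def write_summary(self, path, t: float) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary_record(t), fh, indent=2, sort_keys=True)
            fh.write("\n")


def solve(
    g: AirwayGeometry,
    waveform,
    fluid: FluidProperties = AIR,
    settings: SolverSettings = SolverSettings(),
) -> FlowFields:
    """Integrate the quasi-1D balance over the waveform's time window.

    ``waveform`` needs ``times()``, ``flow_rate(t)`` and
    ``flow_rate_derivative(t)`` — a :class:`~airwaycp.breathing.BreathingWaveform`
    or a :class:`ConstantFlow`.
    """
    area = g.area_m2
    bad = np.flatnonzero(area <= settings.area_floor_m2)
    if bad.size:
        raise SolverError(
            f"degenerate geometry: area {area[bad[0]]:.3e} m2 at station {bad[0]} "
            f"is below the solver floor {settings.area_floor_m2:.1e} m2"
        )

    rho = fluid.density_kgm3
    x = g.x_m
    d = np.sqrt(4.0 * area / np.pi)
    times = waveform.times()
    q = np.atleast_1d(waveform.flow_rate(times))
    dq = np.atleast_1d(waveform.flow_rate_derivative(times))

    u = q[:, None] / area[None, :]
    re = rho * np.abs(u) * d[None, :] / fluid.viscosity_pas

    # accumulated friction loss along x
    grad = _friction_gradient(u, d[None, :], fluid, settings.friction_model)
    lf = cumulative_trapezoid(grad, x, axis=1, initial=0.0)

    # Borda–Carnot losses at detected sudden expansions
    lm = np.zeros_like(u)
    if settings.expansion_loss_enabled:
        ratio = area[1:] / area[:-1]
        interfaces = np.flatnonzero(ratio > 1.0 + settings.expansion_threshold)
        if interfaces.size:
            contrib = np.zeros_like(u)
            for i in interfaces:
                k = (1.0 - area[i] / area[i + 1]) ** 2
                contrib[:, i + 1] += k * rho * u[:, i] * np.abs(u[:, i]) / 2.0
            lm = np.cumsum(contrib, axis=1)

    inertance = cumulative_trapezoid(1.0 / area, x, initial=0.0)
    pressure = (
        -rho * dq[:, None] * inertance[None, :]
        - 0.5 * rho * (u**2 - u[:, :1] ** 2)
        - lf
        - lm
    )

    wss = _wss(u, d[None, :], fluid, settings.friction_model)

    for name, arr in (("pressure", pressure), ("velocity", u), ("wss", wss)):
        if not np.all(np.isfinite(arr)):
            it, ix = np.argwhere(~np.isfinite(arr))[0]
            raise NumericalError(
                f"non-finite {name} at time index {it} (t = {times[it]:.4g} s), "
                f"station {ix}"
            )

    return FlowFields(
        times_s=times,
        x_m=x,
        area_m2=area,
        flow_m3s=q,
        pressure_pa=pressure,
        velocity_mps=u,
        reynolds=re,
        wss_pa=wss,
        geometry=g,
    )


def grid_convergence_study(
    params: GeometryParams,
    waveform,
    fluid: FluidProperties = AIR,
    settings: SolverSettings = SolverSettings(),
    station_counts=(50, 100, 200, 400),
) -> pd.DataFrame:
    """Axial-grid refinement study of the end-to-end pressure drop.

    Re-solves the same configuration on successively finer station grids and
    reports, at the sample instant, the inlet-to-outlet pressure drop and its
    relative change versus the finest grid.  The refinement analogue of a 3D
    mesh-independence study.
    """
    counts = list(station_counts)
    if len(counts) < 3:
        raise ParameterError("station_counts: at least 3 resolutions required")
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ParameterError("station_counts: must be strictly increasing")

    drops = []
    for n in counts:
        g = build_geometry(params.model_copy(update={"n_stations": n}))
        fields = solve(g, waveform, fluid, settings)
        drops.append(fields.pressure_drop(settings.sample_time_s))
    finest = drops[-1]
    rel = [abs(dp - finest) / abs(finest) for dp in drops]
    return pd.DataFrame(
        {
            "station_count": counts,
            "dp_pa": drops,
            "rel_change_vs_finest": rel,
        }
    )
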
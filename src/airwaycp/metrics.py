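"""Landmark-plane sampling and the adjusted pressure coefficient Cp*.

Cp* relates the pressure change across the collapse-prone pharyngeal
segment to the jet velocity through its narrowest cross-section:

    Cp* = sqrt(|P_o - P_n|) / V_v

where P_n and P_o are the pressures at the nasopharyngeal and oropharyngeal
planes and V_v is the mean velocity magnitude at the minimum-area
velopharyngeal plane, all read at peak inhalation (t* = 1.25 s by default).
As printed the statistic is not dimensionless — its SI units are
sqrt(kg/m3) — and it is carried as-is; a conventional pressure coefficient
|dP| / (rho V_v^2 / 2) is available separately but never substituted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError, UndefinedMetricError
from .flow_solver import AIR, FlowFields, FluidProperties, SolverSettings, solve
from .geometry import REGION_ORDER, AirwayGeometry

__all__ = [
    "LandmarkSamples",
    "CpStarResult",
    "sample_landmarks",
    "cp_star",
    "conventional_cp",
    "regional_wss_summary",
    "evaluate_patient",
]


@dataclass(frozen=True)
class LandmarkSamples:
    """Plane samples at the metric instant t*."""

    p_nasopharynx_pa: float
    p_oropharynx_pa: float
    v_velopharynx_mps: float
    t_star_s: float

    def __post_init__(self) -> None:
        if self.v_velopharynx_mps < 0:
            raise ParameterError("v_velopharynx_mps: velocity magnitude must be >= 0")

    @property
    def pressure_drop_pa(self) -> float:
        return abs(self.p_oropharynx_pa - self.p_nasopharynx_pa)


def sample_landmarks(fields: FlowFields, g: AirwayGeometry, t_star: float) -> LandmarkSamples:
    """Read P_n, P_o and V_v from a solved field, linearly interpolated to t*."""
    snap = fields.at_time(t_star)
    lm = g.landmarks
    return LandmarkSamples(
        p_nasopharynx_pa=float(snap["pressure_pa"][lm.nasopharynx_plane]),
        p_oropharynx_pa=float(snap["pressure_pa"][lm.oropharynx_plane]),
        v_velopharynx_mps=float(abs(snap["velocity_mps"][lm.velopharynx_plane])),
        t_star_s=t_star,
    )


def cp_star(lm: LandmarkSamples) -> float:
    """Adjusted pressure coefficient sqrt(|P_o - P_n|) / V_v [sqrt(kg/m3)]."""
    if lm.v_velopharynx_mps == 0.0:
        raise UndefinedMetricError(
            "cp_star is undefined at zero velopharyngeal velocity"
        )
    return math.sqrt(lm.pressure_drop_pa) / lm.v_velopharynx_mps


def conventional_cp(lm: LandmarkSamples, fluid: FluidProperties = AIR) -> float:
    """Dimensionless pressure coefficient |dP| / (rho V_v^2 / 2)."""
    if lm.v_velopharynx_mps == 0.0:
        raise UndefinedMetricError(
            "conventional_cp is undefined at zero velopharyngeal velocity"
        )
    return lm.pressure_drop_pa / (0.5 * fluid.density_kgm3 * lm.v_velopharynx_mps**2)


def regional_wss_summary(
    fields: FlowFields, g: AirwayGeometry, t_star: float
) -> pd.DataFrame:
    """Peak and wall-area-weighted mean wall shear stress per region at t*.

    The mean weights each station segment by its wall area (perimeter times
    axial extent), so long wide segments count proportionally.
    """
    snap = fields.at_time(t_star)
    wss = snap["wss_pa"]
    d = np.sqrt(4.0 * g.area_m2 / np.pi)
    dx = np.gradient(g.x_m)
    weight = np.pi * d * dx
    rows = []
    for name in REGION_ORDER:
        mask = g.region == name
        if not mask.any():
            continue
        w = weight[mask]
        rows.append(
            {
                "region": name,
                "wss_peak_pa": float(wss[mask].max()),
                "wss_mean_pa": float(np.average(wss[mask], weights=w)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CpStarResult:
    """Cp* and the supporting plane samples and WSS summaries for one airway."""

    landmarks: LandmarkSamples
    cp_star: float
    pressure_drop_pa: float
    conventional_cp: float
    regional_wss: pd.DataFrame

    def __post_init__(self) -> None:
        lm = self.landmarks
        if self.cp_star < 0:
            raise ParameterError("cp_star: must be nonnegative")
        if (self.cp_star == 0.0) != (lm.pressure_drop_pa == 0.0):
            raise ParameterError("cp_star: zero exactly when P_o equals P_n")
        if lm.v_velopharynx_mps > 0 and lm.pressure_drop_pa > 0:
            ident = self.cp_star**2 * lm.v_velopharynx_mps**2
            if not math.isclose(ident, lm.pressure_drop_pa, rel_tol=1e-10):
                raise ParameterError(
                    "cp_star: algebraic identity cp^2 V^2 = |dP| violated"
                )

    @classmethod
    def from_fields(
        cls,
        fields: FlowFields,
        g: AirwayGeometry,
        t_star: float,
        fluid: FluidProperties = AIR,
    ) -> "CpStarResult":
        lm = sample_landmarks(fields, g, t_star)
        return cls(
            landmarks=lm,
            cp_star=cp_star(lm),
            pressure_drop_pa=lm.pressure_drop_pa,
            conventional_cp=conventional_cp(lm, fluid),
            regional_wss=regional_wss_summary(fields, g, t_star),
        )

    def to_record(self, patient_id: str | None = None) -> dict:
        """JSON-ready per-patient metrics record."""
        rec = {
            "patient_id": patient_id,
            "t_star_s": self.landmarks.t_star_s,
            "P_n_Pa": self.landmarks.p_nasopharynx_pa,
            "P_o_Pa": self.landmarks.p_oropharynx_pa,
            "V_v_mps": self.landmarks.v_velopharynx_mps,
            "pressure_drop_Pa": self.pressure_drop_pa,
            "cp_star": self.cp_star,
            "conventional_cp": self.conventional_cp,
            "regional_wss": self.regional_wss.to_dict(orient="records"),
        }
        return rec

    def write_record(self, path, patient_id: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_record(patient_id), fh, indent=2, sort_keys=True)
            fh.write("\n")


def evaluate_patient(
    g: AirwayGeometry,
    waveform,
    fluid: FluidProperties = AIR,
    settings: SolverSettings = SolverSettings(),
) -> CpStarResult:
    """Solve one airway and extract its Cp* result at the configured t*."""
    fields = solve(g, waveform, fluid, settings)
    return CpStarResult.from_fields(fields, g, settings.sample_time_s, fluid)
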
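"""Parametric axisymmetric upper-airway geometries.

The airway is modeled as a straight duct of circular cross-section whose
diameter varies along the axial coordinate ``x`` (0 at the nasal inlet,
increasing toward the trachea).  Seven anatomical regions appear in fixed
order: nasal inlet, nasopharynx, velopharynx, oropharynx, hypopharynx,
larynx, trachea.  Disease severity ``s`` in [0, 1] narrows the velopharynx —
the most collapse-prone pharyngeal segment — by a linear constriction law

    d_min = d_base * (1 - 0.75 * s)

so that at s = 1 the velopharyngeal lumen retains 25% of its baseline
diameter (6.25% of its baseline area).  The constriction ramps in smoothly
over the proximal quarter of the region, holds a plateau over the middle
half, and recovers *abruptly* at three quarters of the region length: the
inspiratory jet that forms in a narrowed velopharynx separates rather than
diffusing, so the model presents a genuine area step there for the solver's
sudden-expansion loss to act on.

Three landmark planes are carried with the geometry: the distal ends of the
nasopharynx and oropharynx (where pressures are sampled) and the
minimum-area velopharyngeal station (where velocity is sampled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .exceptions import ParameterError

__all__ = [
    "REGION_ORDER",
    "GeometryParams",
    "Landmarks",
    "AirwayGeometry",
    "build_geometry",
    "equivalent_diameter",
    "uniform_tube_params",
    "geometry_to_csv",
    "geometry_from_csv",
]

#: Anatomical regions in proximal-to-distal order.
REGION_ORDER = (
    "nasal_inlet",
    "nasopharynx",
    "velopharynx",
    "oropharynx",
    "hypopharynx",
    "larynx",
    "trachea",
)

#: Fraction of baseline diameter lost at full severity (d_min = d_base * 0.25).
CONSTRICTION_SLOPE = 0.75
#: Constriction shape, as fractions of the velopharynx length:
#: cosine ramp over [0, RAMP_END], plateau over [RAMP_END, STEP_AT],
#: abrupt recovery at STEP_AT.
RAMP_END = 0.25
STEP_AT = 0.75


class GeometryParams(BaseModel):
    """Parameters of the parametric airway, SI units (meters).

    Defaults are order-of-magnitude adult anatomy: total length 220 mm,
    pharyngeal equivalent diameter 16 mm, glottic (laryngeal) diameter 12 mm.
    """

    nasal_inlet_length_m: float = Field(0.020, gt=0)
    nasopharynx_length_m: float = Field(0.030, gt=0)
    velopharynx_length_m: float = Field(0.025, gt=0)
    oropharynx_length_m: float = Field(0.030, gt=0)
    hypopharynx_length_m: float = Field(0.025, gt=0)
    larynx_length_m: float = Field(0.030, gt=0)
    trachea_length_m: float = Field(0.060, gt=0)
    baseline_diameter_m: float = Field(0.016, gt=0)
    larynx_diameter_m: float = Field(0.012, gt=0)
    severity: float = Field(0.0, ge=0.0, le=1.0)
    n_stations: int = Field(201, ge=50)

    def region_lengths(self) -> dict[str, float]:
        return {
            "nasal_inlet": self.nasal_inlet_length_m,
            "nasopharynx": self.nasopharynx_length_m,
            "velopharynx": self.velopharynx_length_m,
            "oropharynx": self.oropharynx_length_m,
            "hypopharynx": self.hypopharynx_length_m,
            "larynx": self.larynx_length_m,
            "trachea": self.trachea_length_m,
        }

    def region_diameters(self) -> dict[str, float]:
        d = {name: self.baseline_diameter_m for name in REGION_ORDER}
        d["larynx"] = self.larynx_diameter_m
        return d

    def total_length(self) -> float:
        return sum(self.region_lengths().values())


def uniform_tube_params(
    diameter_m: float = 0.016, n_stations: int = 201
) -> GeometryParams:
    """Parameters for a uniform circular tube (all regions share one diameter).

    With the default region lengths this is a 0.22 m tube — the reference
    configuration for the Hagen–Poiseuille and Bernoulli validation oracles.
    """
    return GeometryParams(
        baseline_diameter_m=diameter_m,
        larynx_diameter_m=diameter_m,
        severity=0.0,
        n_stations=n_stations,
    )


@dataclass(frozen=True)
class Landmarks:
    """Station indices of the three measurement planes."""

    nasopharynx_plane: int
    velopharynx_plane: int
    oropharynx_plane: int


@dataclass
class AirwayGeometry:
    """Discretized axial area profile with region labels and landmark planes.

    ``x_m`` is strictly increasing starting at 0; ``area_m2`` is the circular
    cross-sectional area at each station; ``region`` holds one label from
    :data:`REGION_ORDER` per station.
    """

    x_m: np.ndarray
    area_m2: np.ndarray
    region: np.ndarray
    landmarks: Landmarks
    severity: float = 0.0
    params: GeometryParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.area_m2 = np.asarray(self.area_m2, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        if self.x_m.ndim != 1 or self.x_m.size < 50:
            raise ParameterError("x_m: at least 50 stations are required")
        if self.x_m[0] != 0.0:
            raise ParameterError("x_m: first station must sit at x = 0")
        if not np.all(np.diff(self.x_m) > 0):
            raise ParameterError("x_m: stations must be strictly increasing")
        if self.area_m2.shape != self.x_m.shape:
            raise ParameterError("area_m2: must match the station grid")
        if not np.all(self.area_m2 > 0):
            raise ParameterError("area_m2: all areas must be positive")
        lm = self.landmarks
        if not (lm.nasopharynx_plane < lm.velopharynx_plane < lm.oropharynx_plane):
            raise ParameterError(
                "landmarks: planes must be ordered nasopharynx < velopharynx < oropharynx"
            )

    @property
    def n_stations(self) -> int:
        return self.x_m.size

    @property
    def diameter_m(self) -> np.ndarray:
        return equivalent_diameter(self.area_m2)

    def min_velopharyngeal_area(self) -> float:
        mask = self.region == "velopharynx"
        return float(self.area_m2[mask].min())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_m": self.x_m,
                "area_m2": self.area_m2,
                "diameter_m": self.diameter_m,
                "region": self.region.astype(str),
            }
        )


def equivalent_diameter(area):
    """Diameter of the circle with the given area: sqrt(4 A / pi).

    Accepts a scalar or array; every area must be strictly positive.
    """
    arr = np.asarray(area, dtype=float)
    if not np.all(arr > 0):
        raise ParameterError("area: must be strictly positive")
    d = np.sqrt(4.0 * arr / math.pi)
    return float(d) if np.isscalar(area) or arr.ndim == 0 else d


def _station_grid(params: GeometryParams) -> np.ndarray:
    """Uniform grid plus forced stations at region boundaries and at the
    constriction's plateau center / recovery step.

    Forcing these points makes the landmark planes and the detected
    sudden-expansion interface sit at the same axial positions at every
    resolution, which keeps grid-refinement studies comparing the same
    physical configuration.
    """
    lengths = params.region_lengths()
    boundaries = np.cumsum([0.0] + [lengths[r] for r in REGION_ORDER])
    total = boundaries[-1]
    a = boundaries[2]  # velopharynx start
    L = lengths["velopharynx"]
    forced = np.concatenate(
        [boundaries, [a + RAMP_END * L, a + 0.5 * L, a + STEP_AT * L]]
    )
    base = np.linspace(0.0, total, params.n_stations)
    x = np.unique(np.concatenate([base, forced]))
    # drop base points indistinguishable from a forced point
    keep = np.ones(x.size, dtype=bool)
    keep[1:] = np.diff(x) > 1e-12 * total
    return x[keep]


def _baseline_diameter_profile(x: np.ndarray, params: GeometryParams) -> np.ndarray:
    lengths = params.region_lengths()
    diam = params.region_diameters()
    boundaries = np.cumsum([0.0] + [lengths[r] for r in REGION_ORDER])
    d = np.empty_like(x)
    for i, name in enumerate(REGION_ORDER):
        mask = (x >= boundaries[i]) & (x <= boundaries[i + 1])
        d[mask] = diam[name]
    # cosine-taper every transition where adjacent region diameters differ
    for i in range(1, len(REGION_ORDER)):
        d_l = diam[REGION_ORDER[i - 1]]
        d_r = diam[REGION_ORDER[i]]
        if d_l == d_r:
            continue
        xb = boundaries[i]
        w = 0.5 * min(lengths[REGION_ORDER[i - 1]], lengths[REGION_ORDER[i]])
        mask = (x > xb - w) & (x < xb + w)
        frac = (x[mask] - (xb - w)) / (2.0 * w)
        d[mask] = d_l + (d_r - d_l) * 0.5 * (1.0 - np.cos(math.pi * frac))
    return d


def _constriction_factor(x: np.ndarray, params: GeometryParams) -> np.ndarray:
    s = params.severity
    factor = np.ones_like(x)
    if s == 0.0:
        return factor
    lengths = params.region_lengths()
    a = params.nasal_inlet_length_m + params.nasopharynx_length_m
    L = lengths["velopharynx"]
    xi = (x - a) / L
    depth = CONSTRICTION_SLOPE * s
    ramp = (xi >= 0.0) & (xi < RAMP_END)
    factor[ramp] = 1.0 - depth * 0.5 * (1.0 - np.cos(math.pi * xi[ramp] / RAMP_END))
    plateau = (xi >= RAMP_END) & (xi <= STEP_AT)  # step recovery just past STEP_AT
    factor[plateau] = 1.0 - depth
    return factor


def _region_labels(x: np.ndarray, params: GeometryParams) -> np.ndarray:
    lengths = params.region_lengths()
    boundaries = np.cumsum([lengths[r] for r in REGION_ORDER])
    idx = np.searchsorted(boundaries[:-1], x, side="right")
    return np.array([REGION_ORDER[i] for i in idx], dtype=object)


def build_geometry(params: GeometryParams | dict) -> AirwayGeometry:
    """Construct a validated :class:`AirwayGeometry` from parameters.

    The velopharyngeal minimum diameter equals
    ``baseline_diameter * (1 - 0.75 * severity)``; at severity 0 the baseline
    profile is reproduced exactly.
    """
    if isinstance(params, dict):
        params = GeometryParams(**params)
    x = _station_grid(params)
    d = _baseline_diameter_profile(x, params) * _constriction_factor(x, params)
    area = math.pi * d**2 / 4.0
    region = _region_labels(x, params)

    lengths = params.region_lengths()
    x_naso_end = lengths["nasal_inlet"] + lengths["nasopharynx"]
    x_oro_end = x_naso_end + lengths["velopharynx"] + lengths["oropharynx"]
    naso_plane = int(np.argmin(np.abs(x - x_naso_end)))
    oro_plane = int(np.argmin(np.abs(x - x_oro_end)))

    velo_mask = region == "velopharynx"
    velo_idx = np.flatnonzero(velo_mask)
    a_min = area[velo_idx].min()
    candidates = velo_idx[np.isclose(area[velo_idx], a_min, rtol=1e-12, atol=0.0)]
    x_center = x_naso_end + 0.5 * lengths["velopharynx"]
    velo_plane = int(candidates[np.argmin(np.abs(x[candidates] - x_center))])

    return AirwayGeometry(
        x_m=x,
        area_m2=area,
        region=region,
        landmarks=Landmarks(naso_plane, velo_plane, oro_plane),
        severity=params.severity,
        params=params,
    )


def geometry_to_csv(g: AirwayGeometry, path) -> None:
    """Write the profile as CSV with columns x_m, area_m2, diameter_m, region."""
    g.to_dataframe().to_csv(path, index=False, lineterminator="\n")


def geometry_from_csv(path) -> AirwayGeometry:
    """Load a profile written by :func:`geometry_to_csv`.

    Landmarks are recomputed from the labels: pressure planes at the first
    station of the region following the nasopharynx / oropharynx, the
    velocity plane at the minimum-area velopharyngeal station.
    """
    df = pd.read_csv(path)
    for col in ("x_m", "area_m2", "region"):
        if col not in df.columns:
            raise ParameterError(f"{col}: column missing from geometry file")
    x = df["x_m"].to_numpy(float)
    area = df["area_m2"].to_numpy(float)
    region = df["region"].to_numpy(object)
    velo_idx = np.flatnonzero(region == "velopharynx")
    if velo_idx.size == 0:
        raise ParameterError("region: no velopharynx stations in geometry file")
    naso_plane = int(np.flatnonzero(region == "nasopharynx")[-1]) + 1
    oro_plane = int(np.flatnonzero(region == "oropharynx")[-1]) + 1
    velo_plane = int(velo_idx[np.argmin(area[velo_idx])])
    return AirwayGeometry(
        x_m=x,
        area_m2=area,
        region=region,
        landmarks=Landmarks(naso_plane, velo_plane, oro_plane),
        severity=float("nan"),
    )
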
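"""Virtual patient cohorts and clinical cohort tables.

The synthetic cohort generator emulates the statistical structure the Cp*
analysis assumes in a CT cohort: a latent anatomical severity ``s`` in
[0, 1] drives both the velopharyngeal narrowing of each patient's airway and
their apnea–hypopnea index (AHI).  Severities are drawn uniformly; the
geometry receives a truncated-Gaussian perturbed copy of ``s`` (imaging /
anatomy noise); AHI follows a noisy monotone power law

    AHI = clip(110 * s^1.5 * exp(eps) - 2, 0, 120),  eps ~ N(0, sigma_ahi^2)

rounded to an integer, which spans the clinically observed range of roughly
1–98 events/h from healthy to severe OSA.  The law is synthetic: its
parameters are exposed and documented, not fitted to any patient data.

Clinical severity bands follow the standard AHI cutoffs: none < 5 <= mild
< 15 <= moderate < 30 <= severe (an AHI >= 5 is diagnostic of OSA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breathing import BreathingWaveform
from .exceptions import AirwayError, DegenerateDataError, ParameterError
from .flow_solver import AIR, FluidProperties, SolverSettings, solve
from .geometry import GeometryParams, build_geometry
from .metrics import CpStarResult

__all__ = [
    "CLASSIFICATIONS",
    "REFERENCE_AHI",
    "classify_ahi",
    "VirtualPatient",
    "generate_cohort",
    "severity_for_ahi",
    "run_cohort",
    "save_cohort",
    "load_cohort",
]

CLASSIFICATIONS = ("none", "mild", "moderate", "severe")

#: AHI values (events/h) of a reference seven-patient clinical cohort
#: spanning healthy to severe OSA; used in tests and worked examples.
REFERENCE_AHI = (1, 10, 19, 22, 51, 91, 98)

# synthetic AHI generative law defaults
AHI_SCALE = 110.0
AHI_EXPONENT = 1.5
AHI_OFFSET = 2.0
AHI_CAP = 120.0


def classify_ahi(ahi: float) -> str:
    """Clinical severity band for an AHI value (events per hour)."""
    if ahi < 0:
        raise ParameterError("ahi: must be nonnegative")
    if ahi < 5:
        return "none"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def severity_for_ahi(ahi: float) -> float:
    """Noise-free inverse of the synthetic AHI law: the latent severity that
    would generate the given AHI.  Useful for constructing stand-in cohorts
    with prescribed AHI values."""
    if ahi < 0:
        raise ParameterError("ahi: must be nonnegative")
    s = ((ahi + AHI_OFFSET) / AHI_SCALE) ** (1.0 / AHI_EXPONENT)
    return float(np.clip(s, 0.0, 1.0))


@dataclass(frozen=True)
class VirtualPatient:
    """One synthetic patient: latent severity, its (possibly noisy) airway
    geometry, and the generated AHI with its clinical band."""

    patient_id: str
    severity: float
    geometry_params: GeometryParams
    ahi: int
    classification: str

    def __post_init__(self) -> None:
        if self.ahi < 0:
            raise ParameterError("ahi: must be nonnegative")
        if self.classification != classify_ahi(self.ahi):
            raise ParameterError(
                "classification: inconsistent with the AHI cutoffs 5/15/30"
            )


def generate_cohort(
    n: int,
    seed: int,
    sigma_geom: float = 0.05,
    sigma_ahi: float = 0.2,
    base_params: GeometryParams | None = None,
    severities: np.ndarray | None = None,
) -> list[VirtualPatient]:
    """Draw ``n`` virtual patients, fully reproducible from ``seed``.

    ``sigma_geom`` perturbs the severity seen by the geometry (truncated to
    [0, 1]); ``sigma_ahi`` is the log-normal noise of the AHI law.  Passing
    ``severities`` overrides the uniform draw (noise is still applied), which
    is how prescribed-AHI stand-in cohorts are built.
    """
    if n < 2:
        raise ParameterError("n: at least 2 patients are required")
    if sigma_geom < 0 or sigma_ahi < 0:
        raise ParameterError("sigma_geom/sigma_ahi: must be nonnegative")
    base = base_params or GeometryParams()
    rng = np.random.default_rng(seed)
    if severities is None:
        severities = rng.uniform(0.0, 1.0, size=n)
    else:
        severities = np.asarray(severities, dtype=float)
        if severities.shape != (n,):
            raise ParameterError("severities: must have length n")
        if np.any((severities < 0) | (severities > 1)):
            raise ParameterError("severities: must lie in [0, 1]")
    geom_noise = rng.normal(0.0, sigma_geom, size=n) if sigma_geom > 0 else np.zeros(n)
    ahi_noise = rng.normal(0.0, sigma_ahi, size=n) if sigma_ahi > 0 else np.zeros(n)

    patients = []
    for i in range(n):
        s = float(severities[i])
        s_geom = float(np.clip(s + geom_noise[i], 0.0, 1.0))
        raw = AHI_SCALE * s**AHI_EXPONENT * np.exp(ahi_noise[i]) - AHI_OFFSET
        ahi = int(round(float(np.clip(raw, 0.0, AHI_CAP))))
        patients.append(
            VirtualPatient(
                patient_id=f"P{i + 1:03d}",
                severity=s,
                geometry_params=base.model_copy(update={"severity": s_geom}),
                ahi=ahi,
                classification=classify_ahi(ahi),
            )
        )
    return patients


COHORT_COLUMNS = (
    "patient_id",
    "ahi",
    "classification",
    "severity",
    "cp_star",
    "pressure_drop_Pa",
    "v_v_mps",
    "wss_peak_Pa",
    "error",
)


def run_cohort(
    patients: list[VirtualPatient],
    waveform: BreathingWaveform | None = None,
    fluid: FluidProperties = AIR,
    settings: SolverSettings = SolverSettings(),
    return_details: bool = False,
):
    """Simulate every patient and assemble the cohort metrics table.

    A failure for an individual patient (degenerate geometry, numerical
    blow-up, undefined metric) is recorded in that patient's ``error``
    column; the remaining rows are unaffected.
    """
    if not patients:
        raise ParameterError("patients: cohort must not be empty")
    waveform = waveform or BreathingWaveform.from_tidal_volume(
        time_step_s=settings.time_step_s
    )
    rows = []
    details: dict[str, CpStarResult] = {}
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "ahi": p.ahi,
            "classification": p.classification,
            "severity": p.severity,
            "cp_star": np.nan,
            "pressure_drop_Pa": np.nan,
            "v_v_mps": np.nan,
            "wss_peak_Pa": np.nan,
            "error": "",
        }
        try:
            g = build_geometry(p.geometry_params)
            fields = solve(g, waveform, fluid, settings)
            res = CpStarResult.from_fields(fields, g, settings.sample_time_s, fluid)
        except (AirwayError, ValueError) as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        else:
            snap = fields.at_time(settings.sample_time_s)
            row.update(
                cp_star=res.cp_star,
                pressure_drop_Pa=res.pressure_drop_pa,
                v_v_mps=res.landmarks.v_velopharynx_mps,
                wss_peak_Pa=float(np.max(snap["wss_pa"])),
            )
            details[p.patient_id] = res
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return (table, details) if return_details else table


def save_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as comma-separated text with a header row."""
    table.to_csv(path, index=False, lineterminator="\n")


def load_cohort(path) -> pd.DataFrame:
    """Load a cohort table, matching columns by header name.

    Accepts the full layout written by :func:`save_cohort`, a minimal
    (patient_id, ahi) table, or a (patient_id, ahi, cp_star) table; extra
    columns are preserved.  Patient ids must be unique and AHI complete.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "patient_id" not in df.columns or "ahi" not in df.columns:
        raise ParameterError("cohort file must have patient_id and ahi columns")
    if df["patient_id"].duplicated().any():
        raise DegenerateDataError("patient_id: duplicate ids in cohort table")
    if df["ahi"].isna().any():
        raise DegenerateDataError("ahi: missing values in cohort table")
    if (df["ahi"] < 0).any():
        raise ParameterError("ahi: must be nonnegative")
    if "classification" not in df.columns:
        df["classification"] = [classify_ahi(a) for a in df["ahi"]]
    return df
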
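"""End-to-end workflow: cohort generation -> per-patient simulation ->
Cp* metrics -> Cp*-AHI correlation, with all artifacts written to disk.

Given the same configuration (including the seed) the run is fully
deterministic: the cohort table it writes is byte-identical across runs, and
a run manifest (config echo + package version + seed) is emitted so any
output can be regenerated from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import generate_cohort, run_cohort, save_cohort
from .exceptions import DegenerateDataError, ParameterError
from .config import PipelineConfig
from .stats import CorrelationResult, CpStarAhiModel

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("airwaycp")


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    correlation: CorrelationResult | None
    manifest: dict
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full workflow described by ``config``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise NotADirectoryError(f"output_dir: {out} is not a directory")

    wcfg = config.waveform
    phase = math.sin(2.0 * math.pi * wcfg.sample_time_s / wcfg.cycle_period_s)
    if abs(phase) < 1e-9:
        warnings.warn(
            f"sample_time_s = {wcfg.sample_time_s} s falls at zero flow for "
            f"cycle_period_s = {wcfg.cycle_period_s} s; Cp* is undefined there. "
            "Peak inhalation is at tau/4.",
            stacklevel=2,
        )

    waveform = wcfg.build()
    fluid = config.fluid.build()
    settings = config.solver.build(wcfg)
    log.info(
        "pipeline: n=%d seed=%d stations=%d dt=%g s t*=%g s",
        config.cohort.n,
        config.cohort.seed,
        config.geometry.n_stations,
        settings.time_step_s,
        settings.sample_time_s,
    )

    patients = generate_cohort(
        n=config.cohort.n,
        seed=config.cohort.seed,
        sigma_geom=config.cohort.sigma_geom,
        sigma_ahi=config.cohort.sigma_ahi,
        base_params=config.geometry,
    )
    table, details = run_cohort(
        patients, waveform, fluid, settings, return_details=True
    )
    save_cohort(table, out / "cohort.csv")

    metrics_dir = out / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    for pid, res in details.items():
        res.write_record(metrics_dir / f"{pid}.json", patient_id=pid)

    try:
        correlation = CpStarAhiModel.from_dataframe(table).fit().corr
        corr_record = correlation.to_record()
    except (ParameterError, DegenerateDataError) as exc:
        log.warning("correlation undefined for this cohort: %s", exc)
        correlation = None
        corr_record = {"r": None, "p_two_tailed": None, "n": 0, "significant": False}
    with open(out / "correlation.json", "w", encoding="utf-8") as fh:
        json.dump(corr_record, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "package": "airwaycp",
        "version": __version__,
        "seed": config.cohort.seed,
        "config": config.model_dump(),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        cohort=table, correlation=correlation, manifest=manifest, output_dir=out
    )
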
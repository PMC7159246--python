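"""End-to-end study pipeline: simulate -> extract -> stats -> spatial -> calibrate.

:func:`run_pipeline` reproduces the full analysis on simulated data (or on
file inputs via the CLI stages) and emits the study's result tables: the
per-specimen mechanical-property table, the grouped summary with Dunn
p-values, the spatial coefficient and percent-drop tables per response, the
calibration fit, and per-biopsy concentration estimates.

Every random stage consumes a seed derived deterministically from the config
seed, so re-running with an unchanged config is byte-identical at the CSV
level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import calibration as calib
from . import groupstats, io, mechanics, spatial, synthetic
from .core import LoadingProtocol

logger = logging.getLogger("tendonmech")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending item."""


@dataclass
class PipelineConfig:
    """Configuration of the full simulated-study pipeline."""

    seed: int = 0
    out_dir: Optional[str] = None
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(synthetic.DEFAULT_GROUP_SIZES)
    )
    noise: bool = True
    window: Optional[int] = None
    range_mode: str = "ramp_only"
    dunn_adjustment: str = "none"
    distances: Sequence[float] = spatial.DEFAULT_DESIGN_DISTANCES
    n_spectral_per_group: int = 9
    calib_levels: Sequence[float] = synthetic.DEFAULT_CALIB_LEVELS
    calib_n_per_level: int = 10
    calib_beta0: float = synthetic.DEFAULT_CALIB_BETA0
    calib_beta1: float = synthetic.DEFAULT_CALIB_BETA1
    calib_noise_sd: float = synthetic.DEFAULT_CALIB_NOISE_SD
    protocol: LoadingProtocol = field(default_factory=LoadingProtocol)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        protocol = LoadingProtocol(**raw.pop("protocol", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(protocol=protocol, **raw)

    def digest(self) -> str:
        payload = dict(dataclasses.asdict(self))
        payload["protocol"] = dataclasses.asdict(self.protocol)
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StudyReport:
    """All result tables of one pipeline run."""

    properties: pd.DataFrame
    summary: pd.DataFrame
    spatial_coefficients: pd.DataFrame
    spatial_drops: pd.DataFrame
    calibration_fit: calib.CalibrationFit
    concentrations: pd.DataFrame
    config_digest: str = ""


def _stage(name: str, func, *args, item: str = "", **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        where = f" (item {item})" if item else ""
        raise PipelineError(f"stage {name!r} failed{where}: {exc}") from exc


def extract_cohort(
    config: PipelineConfig, seed: int
) -> pd.DataFrame:
    """Simulate the cohort and extract per-specimen mechanical properties."""
    cohort_cfg = synthetic.default_cohort_config(config.group_sizes, noise=config.noise)
    rows = []
    for rec in synthetic.iter_cohort(cohort_cfg, config.protocol, seed):
        try:
            props = mechanics.extract_all(
                rec.trace, rec.specimen, config.protocol,
                window=config.window, range_mode=config.range_mode,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"stage 'extract' failed (specimen {rec.specimen.id}): {exc}"
            ) from exc
        row = {"specimen_id": rec.specimen.id, "group": rec.specimen.group}
        row.update(props.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute simulate -> extract -> stats -> spatial -> calibrate -> report."""
    ss = np.random.SeedSequence(config.seed)
    seed_mech, seed_spec, seed_cal = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    logger.info("pipeline start: config %s, seed %d", config.digest(), config.seed)

    properties = extract_cohort(config, seed_mech)
    logger.info("extract: %d specimens", len(properties))

    summary = _stage(
        "stats",
        groupstats.group_summary,
        properties.drop(columns=["specimen_id"]),
        adjustment=config.dunn_adjustment,
    )

    spectral = _stage(
        "spatial",
        synthetic.generate_spectral_profiles,
        n_per_group=config.n_spectral_per_group,
        seed=seed_spec,
    )
    coef_tables, drop_tables = [], []
    for response in ("fluorescence", "absorption"):
        fit = _stage(
            "spatial", spatial.fit_spatial_model, spectral, response,
            distances=config.distances, item=response,
        )
        coef_tables.append(spatial.coefficient_table(fit))
        drop_tables.append(spatial.drop_table(fit))
    spatial_coefficients = pd.concat(coef_tables, ignore_index=True)
    spatial_drops = pd.concat(drop_tables, ignore_index=True)
    logger.info("spatial: %d biopsies", len(spectral))

    calib_table = _stage(
        "calibrate",
        synthetic.generate_calibration_samples,
        levels=config.calib_levels,
        n_per_level=config.calib_n_per_level,
        beta0=config.calib_beta0,
        beta1=config.calib_beta1,
        noise_sd=config.calib_noise_sd,
        seed=seed_cal,
    )
    fit = _stage("calibrate", calib.fit_calibration_table, calib_table)
    concentrations = _stage("calibrate", calib.concentration_table, spectral, fit)
    logger.info("calibrate: %d samples, R2adj=%.3f", fit.n_used + fit.n_background,
                fit.r2_adj)

    report = StudyReport(
        properties=properties,
        summary=summary,
        spatial_coefficients=spatial_coefficients,
        spatial_drops=spatial_drops,
        calibration_fit=fit,
        concentrations=concentrations,
        config_digest=config.digest(),
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_table_csv(report.properties, out / "properties.csv")
    io.write_table_csv(report.summary, out / "group_summary.csv")
    io.write_table_csv(report.spatial_coefficients, out / "spatial_coefficients.csv")
    io.write_table_csv(report.spatial_drops, out / "spatial_drops.csv")
    io.write_table_csv(report.concentrations, out / "concentrations.csv")
    fit = report.calibration_fit
    lines = [
        f"beta0 = {fit.beta0:.10g}",
        f"beta1 = {fit.beta1:.10g}",
        f"r2_adj = {fit.r2_adj:.10g}",
        f"n_used = {fit.n_used}",
        f"background_mean = {fit.background_mean:.10g}",
        f"n_background = {fit.n_background}",
        f"slope_per_percent = {calib.slope_per_percent(fit):.10g}",
    ]
    (out / "calibration_fit.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
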
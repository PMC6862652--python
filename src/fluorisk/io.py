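"""CSV readers/writers, run configuration, and the pipeline driver.

One CSV dialect throughout: comma-separated, UTF-8, period decimal
separator, mandatory header row; an empty cell means "absent". Display
rounding applies only to the report table — every CSV written here carries
full precision, so writing and re-reading reproduces the in-memory records
exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .monte_carlo import MonteCarloSettings, RiskResult, cumulative_curve, run_simulation, summarize_to_table
from .risk_model import ConcentrationSummary, ExposurePopulation, RiskConfig

__all__ = [
    "STUDY_COLUMNS",
    "POPULATION_COLUMNS",
    "read_studies",
    "read_populations",
    "write_studies",
    "write_measurements",
    "results_frame",
    "write_results",
    "write_ecdf",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("fluorisk")

STUDY_COLUMNS = [
    "study_id", "location", "tea_type", "n_brands", "n_samples", "year",
    "mean_mgL", "min_mgL", "max_mgL", "sd_mgL", "eval_conc_mgL",
]
POPULATION_COLUMNS = ["name", "ir_L_per_day", "ef_days_per_year", "ed_years", "bw_kg", "at_days"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _opt(value, cast=float):
    return None if pd.isna(value) else cast(value)


def read_studies(path) -> list[ConcentrationSummary]:
    """Parse a study-summary CSV into validated summaries.

    Documented anomalies (impossible SD, evaluation concentration outside
    the range) surface as warnings; structural problems (missing column,
    non-numeric concentration, min > max) are errors naming the row.
    """
    df = pd.read_csv(path, dtype={"study_id": str})
    _check_columns(df, STUDY_COLUMNS, path)
    summaries = []
    for i, row in df.iterrows():
        try:
            summaries.append(
                ConcentrationSummary(
                    study_id=str(row["study_id"]),
                    location=str(row["location"]) if not pd.isna(row["location"]) else "",
                    tea_type=str(row["tea_type"]) if not pd.isna(row["tea_type"]) else "",
                    n_brands=int(_opt(row["n_brands"], int) or 0),
                    n_samples=_opt(row["n_samples"], int),
                    year=_opt(row["year"], int),
                    mean_conc=float(row["mean_mgL"]),
                    min_conc=float(row["min_mgL"]),
                    max_conc=float(row["max_mgL"]),
                    sd_conc=_opt(row["sd_mgL"]),
                    eval_conc=_opt(row["eval_conc_mgL"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    logger.info("read %d studies from %s", len(summaries), path)
    return summaries


def read_populations(path) -> list[ExposurePopulation]:
    df = pd.read_csv(path)
    _check_columns(df, POPULATION_COLUMNS, path)
    pops = []
    for i, row in df.iterrows():
        try:
            pops.append(
                ExposurePopulation(
                    name=str(row["name"]),
                    ir=float(row["ir_L_per_day"]),
                    ef=float(row["ef_days_per_year"]),
                    ed=float(row["ed_years"]),
                    bw=float(row["bw_kg"]),
                    at=float(row["at_days"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    logger.info("read %d populations from %s", len(pops), path)
    return pops


def write_studies(summaries: Sequence[ConcentrationSummary], path) -> None:
    """Emit the same study-summary dialect `read_studies` consumes."""
    df = pd.DataFrame(
        {
            "study_id": [s.study_id for s in summaries],
            "location": [s.location for s in summaries],
            "tea_type": [s.tea_type for s in summaries],
            "n_brands": [s.n_brands for s in summaries],
            "n_samples": [s.n_samples for s in summaries],
            "year": [s.year for s in summaries],
            "mean_mgL": [s.mean_conc for s in summaries],
            "min_mgL": [s.min_conc for s in summaries],
            "max_mgL": [s.max_conc for s in summaries],
            "sd_mgL": [s.sd_conc for s in summaries],
            "eval_conc_mgL": [s.eval_conc for s in summaries],
        }
    )
    df.to_csv(path, index=False)


def write_measurements(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def results_frame(results: Sequence[RiskResult], config: RiskConfig) -> pd.DataFrame:
    """Full-precision tidy results, one row per study x population."""
    return pd.DataFrame(
        {
            "study_id": [r.study_id for r in results],
            "population": [r.population_name for r in results],
            "eval_conc_mgL": [r.eval_conc for r in results],
            "cdi": [r.point_cdi for r in results],
            "thq": [r.point_hq for r in results],
            "cdi_p05": [r.cdi_percentiles.get(0.05) for r in results],
            "cdi_p50": [r.cdi_percentiles.get(0.50) for r in results],
            "cdi_p95": [r.cdi_percentiles.get(0.95) for r in results],
            "thq_p95": [r.hq_percentiles.get(0.95) for r in results],
            "prob_hq_gt_threshold": [r.prob_hq_exceeds for r in results],
        }
    )


def write_results(results: Sequence[RiskResult], config: RiskConfig, path) -> pd.DataFrame:
    df = results_frame(results, config)
    df.to_csv(path, index=False)
    return df


def write_ecdf(samples, path) -> pd.DataFrame:
    curve = cumulative_curve(samples)
    curve.to_csv(path, index=False)
    return curve


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-loadable flat key-value."""

    studies_path: str
    populations_path: str
    out_dir: str
    mode: str = "eq1"
    distribution_family: str = "auto"
    rfd: float = 0.06
    hazard_threshold: float = 1.0
    n_iterations: int = 10_000
    master_seed: int = 0
    percentiles: tuple[float, ...] = (0.05, 0.50, 0.95)
    output_digits: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("eq1", "as_published"):
            raise ValueError(f"mode must be 'eq1' or 'as_published', got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "percentiles" in raw:
            raw["percentiles"] = tuple(float(p) for p in raw["percentiles"])
        return cls(**raw)

    def risk_config(self) -> RiskConfig:
        return RiskConfig(rfd=self.rfd, hazard_threshold=self.hazard_threshold)

    def mc_settings(self) -> MonteCarloSettings:
        return MonteCarloSettings(
            n_iterations=self.n_iterations,
            master_seed=self.master_seed,
            percentiles=tuple(self.percentiles),
        )


def run_pipeline(config: RunConfig) -> Path:
    """Read inputs, simulate, and write all reports into the output directory.

    Inputs are read and the simulation completes before any output file is
    created, so a failing stage leaves no partial outputs. Returns the
    output directory. Writes: results.csv (full precision), report.csv
    (3-sig-fig table), ecdf_<study>.csv per study, run_metadata.json.
    """
    for p in (config.studies_path, config.populations_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    summaries = read_studies(config.studies_path)
    populations = read_populations(config.populations_path)
    risk_cfg = config.risk_config()
    settings = config.mc_settings()
    results = run_simulation(
        summaries, populations, settings, risk_cfg,
        mode=config.mode, family=config.distribution_family,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(results, risk_cfg, out / "results.csv")
    table = summarize_to_table(results, risk_cfg, digits=config.output_digits)
    table.to_csv(out / "report.csv", index=False)
    n_curves = 0
    seen = set()
    for r in results:
        if r.study_id in seen or r.conc_samples is None:
            continue
        seen.add(r.study_id)
        write_ecdf(r.conc_samples, out / f"ecdf_{r.study_id}.csv")
        n_curves += 1
    metadata = {
        "software_version": __version__,
        "mode": config.mode,
        "distribution_family": config.distribution_family,
        "rfd_mg_per_kg_day": config.rfd,
        "hazard_threshold": config.hazard_threshold,
        "n_iterations": config.n_iterations,
        "master_seed": config.master_seed,
        "percentiles": list(config.percentiles),
        "percentile_estimator": "inverted_cdf (order statistic)",
        "triangular_middle_parameter": "reported mean used as mode",
        "studies": [s.study_id for s in summaries],
        "populations": [p.name for p in populations],
        "inputs": {
            "studies": str(config.studies_path),
            "populations": str(config.populations_path),
        },
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2)
    logger.info(
        "pipeline complete: %d studies, %d populations, %d result rows, %d ECDF curves",
        len(summaries), len(populations), len(results), n_curves,
    )
    return out
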
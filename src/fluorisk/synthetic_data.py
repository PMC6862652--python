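"""Synthetic per-brand fluoride measurements.

Literature studies only print summary statistics, so end-to-end testing of
the fitting and simulation machinery needs raw measurements whose summaries
emulate such a study table. The generator draws i.i.d. concentrations from
any of the bounded families and tags each with a brand and replicate index;
brands carry no variance component by default (an optional between-brand
shift exists as an extension hook), because the source tables report brand
counts but no between/within-brand variance split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import ConcentrationDistribution
from .risk_model import ConcentrationSummary

__all__ = ["SyntheticStudySpec", "generate_measurements", "summarize_measurements"]


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Generating parameters for one synthetic study.

    ``true_mean``/``true_sd`` parameterize the family's location and scale;
    bounds are the truncation interval (mg/L). ``brand_shift_sd`` adds an
    optional per-brand normal offset (clipped back to the bounds); the
    default 0 keeps all values i.i.d.
    """

    study_id: str
    family: str
    true_mean: float
    true_sd: float
    bounds: tuple[float, float]
    n_brands: int = 5
    replicates_per_brand: int = 1
    seed: int = 0
    brand_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if lo > hi:
            raise ValueError(f"bounds must be ordered, got {self.bounds}")
        if self.n_brands < 1 or self.replicates_per_brand < 1:
            raise ValueError("n_brands and replicates_per_brand must be >= 1")
        if self.true_sd < 0:
            raise ValueError("true_sd must be nonnegative")
        if self.family == "point" and self.true_sd > 0:
            raise ValueError("point family cannot have a positive true_sd")


def _spec_distribution(spec: SyntheticStudySpec) -> ConcentrationDistribution:
    lo, hi = spec.bounds
    if spec.family == "point":
        return ConcentrationDistribution("point", spec.true_mean, spec.true_mean)
    if spec.family == "uniform":
        return ConcentrationDistribution("uniform", lo, hi)
    if spec.family == "triangular":
        return ConcentrationDistribution("triangular", lo, hi, location=spec.true_mean)
    return ConcentrationDistribution(
        spec.family, lo, hi, location=spec.true_mean, scale=spec.true_sd
    )


def generate_measurements(spec: SyntheticStudySpec) -> pd.DataFrame:
    """Draw n_brands x replicates_per_brand concentrations, seed-reproducible.

    Returns a tidy frame with columns study_id, brand_index,
    replicate_index, conc_mgL; every value lies inside the spec's bounds.
    """
    dist = _spec_distribution(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_brands * spec.replicates_per_brand
    values = dist.sample(n, rng=rng)
    if spec.brand_shift_sd > 0:
        shifts = rng.normal(0.0, spec.brand_shift_sd, size=spec.n_brands)
        values = values + np.repeat(shifts, spec.replicates_per_brand)
        lo, hi = spec.bounds
        if spec.family == "point":
            lo = hi = spec.true_mean
        values = np.clip(values, lo, hi)
    brands = np.repeat(np.arange(1, spec.n_brands + 1), spec.replicates_per_brand)
    reps = np.tile(np.arange(1, spec.replicates_per_brand + 1), spec.n_brands)
    return pd.DataFrame(
        {
            "study_id": spec.study_id,
            "brand_index": brands,
            "replicate_index": reps,
            "conc_mgL": values,
        }
    )


def summarize_measurements(records: pd.DataFrame) -> ConcentrationSummary:
    """Collapse raw measurements to the summary-table shape.

    Mean, min, max and the sample SD (ddof=1; absent for a single value)
    over all values; brands counted as distinct brand indices.
    """
    if records is None or len(records) == 0:
        raise ValueError("summarize_measurements requires at least one record")
    values = records["conc_mgL"].to_numpy(dtype=float)
    study_ids = records["study_id"].unique()
    if len(study_ids) > 1:
        raise ValueError(f"records mix study ids: {sorted(map(str, study_ids))}")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else None
    return ConcentrationSummary(
        study_id=str(study_ids[0]),
        mean_conc=float(np.mean(values)),
        min_conc=float(np.min(values)),
        max_conc=float(np.max(values)),
        sd_conc=sd,
        n_brands=int(records["brand_index"].nunique()),
        n_samples=int(values.size),
    )
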
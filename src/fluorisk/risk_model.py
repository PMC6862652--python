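"""Deterministic core of the fluoride exposure assessment.

Implements the USEPA ingestion-route model for a contaminant dissolved in a
beverage:

    CDI = (C · IR · EF · ED) / (BW · AT)      [mg/kg/day]
    HQ  = CDI / RfD                            [dimensionless]

where C is the fluoride concentration in the tea infusion (mg/L), IR the
daily intake volume (L/day), EF the exposure frequency (days/year), ED the
exposure duration (years), BW body weight (kg) and AT the averaging time in
days (ED x 365 for non-carcinogenic endpoints). An HQ above 1 flags a
potential non-carcinogenic hazard (here, fluorosis); HQ at or below 1 is
classified safe.

Two evaluation modes exist for multi-group tables:

``eq1``
    The literal model above, applied independently per population group.
``as_published``
    Reproduces a published results table whose second and later group
    columns follow a chained scaling — each group's CDI equals the previous
    group's CDI multiplied by its own IR/BW ratio — rather than the literal
    formula. See :func:`as_published_cdi`. The two modes agree on the first
    (men) group by construction.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "DataAnomalyWarning",
    "ConcentrationSummary",
    "ExposurePopulation",
    "RiskConfig",
    "RiskCategory",
    "PointRisk",
    "compute_cdi",
    "compute_hq",
    "classify_hq",
    "point_risk",
    "as_published_cdi",
    "rank_groups",
    "exceedance_fraction",
    "sd_consistent_with_range",
]


class DataAnomalyWarning(UserWarning):
    """A study summary is internally inconsistent but still usable."""


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class ConcentrationSummary:
    """Summary statistics of fluoride concentration for one literature study.

    Concentrations are mg/L in the brewed infusion. ``eval_conc`` is the
    single concentration used for point risk evaluation when a study table
    prints one; it is accepted as an input, never recomputed.
    """

    study_id: str
    mean_conc: float
    min_conc: float
    max_conc: float
    sd_conc: float | None = None
    eval_conc: float | None = None
    location: str = ""
    tea_type: str = ""
    n_brands: int = 0
    n_samples: int | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        self.study_id = str(self.study_id)
        if not 0 <= self.min_conc <= self.mean_conc <= self.max_conc:
            raise ValueError(
                f"study {self.study_id}: require 0 <= min <= mean <= max, got "
                f"min={self.min_conc}, mean={self.mean_conc}, max={self.max_conc}"
            )
        if self.n_brands < 0:
            raise ValueError(f"study {self.study_id}: n_brands must be nonnegative")
        if self.sd_conc is not None:
            if self.sd_conc < 0:
                raise ValueError(f"study {self.study_id}: sd_conc must be nonnegative")
            if not sd_consistent_with_range(self):
                warnings.warn(
                    f"study {self.study_id}: reported SD {self.sd_conc} is too small "
                    f"for range [{self.min_conc}, {self.max_conc}] at the reported "
                    "sample size (possibly a standard error or typo); kept as given",
                    DataAnomalyWarning,
                    stacklevel=2,
                )
        if self.eval_conc is not None and not (
            self.min_conc <= self.eval_conc <= self.max_conc
        ):
            warnings.warn(
                f"study {self.study_id}: evaluation concentration {self.eval_conc} "
                f"lies outside the reported range [{self.min_conc}, {self.max_conc}]",
                DataAnomalyWarning,
                stacklevel=2,
            )


def sd_consistent_with_range(summary: ConcentrationSummary) -> bool:
    """Check a reported sample SD against the reported range.

    For any sample of size n, range <= sd * sqrt(2n); an SD violating the
    bound cannot be the sample standard deviation of data spanning that
    range. With no sample size available the check degrades to sd less than
    the full range (true for any n >= 2).
    """
    if summary.sd_conc is None:
        return False
    if summary.sd_conc == 0:
        return summary.min_conc == summary.max_conc
    rng = summary.max_conc - summary.min_conc
    n = summary.n_samples or (summary.n_brands if summary.n_brands >= 2 else None)
    if n is None:
        return summary.sd_conc <= rng or rng == 0
    return rng <= summary.sd_conc * math.sqrt(2 * n)


@dataclass(frozen=True)
class ExposurePopulation:
    """Exposure parameters for one population group (a Table-2-style column)."""

    name: str
    ir: float  # ingestion rate, L/day
    ef: float  # exposure frequency, days/year
    ed: float  # exposure duration, years
    bw: float  # body weight, kg
    at: float  # averaging time, days

    def __post_init__(self) -> None:
        for fname in ("ir", "ef", "ed", "bw", "at"):
            _require_positive(f"population {self.name!r}: {fname}", getattr(self, fname))
        if not math.isclose(self.at, self.ed * 365, rel_tol=1e-9):
            warnings.warn(
                f"population {self.name!r}: averaging time {self.at} days differs "
                f"from ED x 365 = {self.ed * 365}",
                DataAnomalyWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class RiskConfig:
    """Reference dose and hazard threshold for the non-carcinogenic endpoint.

    The oral reference dose for fluoride is 0.06 mg/kg/day (USEPA); the
    conventional hazard threshold is 1.
    """

    rfd: float = 0.06
    hazard_threshold: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("rfd", self.rfd)
        _require_positive("hazard_threshold", self.hazard_threshold)


class RiskCategory(str, enum.Enum):
    SAFE = "safe"
    HAZARD = "hazard"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PointRisk:
    """Deterministic CDI/HQ for one study x population pair."""

    study_id: str
    population_name: str
    cdi: float
    hq: float
    category: RiskCategory


def compute_cdi(c: float, pop: ExposurePopulation) -> float:
    """Chronic daily intake, mg/kg/day, for concentration ``c`` (mg/L).

    When EF = 365 days/year and AT = ED x 365 the formula reduces
    algebraically to c * IR / BW, independent of ED.
    """
    if c < 0:
        raise ValueError(f"concentration c must be nonnegative, got {c!r}")
    return (c * pop.ir * pop.ef * pop.ed) / (pop.bw * pop.at)


def compute_hq(cdi: float, config: RiskConfig) -> float:
    """Hazard quotient: CDI divided by the reference dose."""
    if cdi < 0:
        raise ValueError(f"cdi must be nonnegative, got {cdi!r}")
    return cdi / config.rfd


def classify_hq(hq: float, config: RiskConfig) -> RiskCategory:
    """Classify an HQ: hazard iff strictly above the threshold.

    An HQ exactly at the threshold classifies safe — the hazard statement
    is the strict inequality HQ > threshold.
    """
    if hq < 0:
        raise ValueError(f"hq must be nonnegative, got {hq!r}")
    return RiskCategory.HAZARD if hq > config.hazard_threshold else RiskCategory.SAFE


def point_risk(
    c: float, pop: ExposurePopulation, config: RiskConfig, study_id: str = ""
) -> PointRisk:
    """Evaluate the deterministic model for one concentration and group."""
    cdi = compute_cdi(c, pop)
    hq = compute_hq(cdi, config)
    return PointRisk(str(study_id), pop.name, cdi, hq, classify_hq(hq, config))


def as_published_cdi(
    c: float,
    populations: Sequence[ExposurePopulation],
    config: RiskConfig,
    study_id: str = "",
) -> list[PointRisk]:
    """Chained table-reproduction arithmetic over an ordered group list.

    The first group's CDI is the literal formula; each subsequent group's
    CDI is the previous group's CDI multiplied by that group's own IR/BW
    ratio. This reproduces a published results table whose later columns do
    not follow the literal formula; it is not a physically meaningful intake
    model for those groups and exists only for table reproduction.
    """
    if not populations:
        raise ValueError("as_published_cdi requires at least one population")
    if c < 0:
        raise ValueError(f"concentration c must be nonnegative, got {c!r}")
    risks: list[PointRisk] = []
    cdi = compute_cdi(c, populations[0])
    for i, pop in enumerate(populations):
        if i > 0:
            cdi = cdi * (pop.ir / pop.bw)
        hq = compute_hq(cdi, config)
        risks.append(PointRisk(str(study_id), pop.name, cdi, hq, classify_hq(hq, config)))
    return risks


def rank_groups(risks: Sequence[PointRisk]) -> list[str]:
    """Population names for one study, in descending HQ order (stable)."""
    if not risks:
        raise ValueError("rank_groups requires at least one risk")
    study_ids = {r.study_id for r in risks}
    if len(study_ids) > 1:
        raise ValueError(f"rank_groups got mixed study ids: {sorted(study_ids)}")
    ordered = sorted(risks, key=lambda r: -r.hq)  # sorted() is stable: ties keep input order
    return [r.population_name for r in ordered]


def exceedance_fraction(
    risks: Sequence[PointRisk], population_name: str, config: RiskConfig
) -> float:
    """Fraction of a population's risks with HQ strictly above the threshold."""
    group = [r for r in risks if r.population_name == population_name]
    if not group:
        raise ValueError(f"no risks for population {population_name!r}")
    return sum(r.hq > config.hazard_threshold for r in group) / len(group)
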
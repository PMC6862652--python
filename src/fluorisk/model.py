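"""Model/Results facade over the risk pipeline.

``TeaFluorideRisk`` holds the data (study summaries, exposure populations)
and the assessment configuration; ``fit`` runs the deterministic evaluation
plus the Monte Carlo propagation and returns a ``TeaFluorideRiskResults``
carrying point estimates, percentile curves, exceedance probabilities and a
``summary()`` report.

Example
-------
>>> from fluorisk import TeaFluorideRisk
>>> model = TeaFluorideRisk.from_fixtures(mode="as_published")
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import datasets
from .io import read_populations, read_studies, results_frame
from .monte_carlo import (
    MonteCarloSettings,
    RiskResult,
    cumulative_curve,
    run_simulation,
    summarize_to_table,
)
from .risk_model import (
    ConcentrationSummary,
    ExposurePopulation,
    PointRisk,
    RiskConfig,
    classify_hq,
    exceedance_fraction,
    rank_groups,
)

__all__ = ["TeaFluorideRisk", "TeaFluorideRiskResults"]


class TeaFluorideRisk:
    """Non-carcinogenic fluoride risk model for a set of tea studies.

    Parameters
    ----------
    studies
        Concentration summaries, one per literature study.
    populations
        Exposure groups in evaluation order (the chained as-published mode
        depends on this order).
    config
        Reference dose and hazard threshold; defaults to the fluoride oral
        RfD of 0.06 mg/kg/day and threshold 1.
    mode
        ``"eq1"`` applies the intake formula independently per group;
        ``"as_published"`` reproduces the chained published-table arithmetic.
    family
        Concentration distribution family, or ``"auto"``.
    """

    def __init__(
        self,
        studies: Sequence[ConcentrationSummary],
        populations: Sequence[ExposurePopulation],
        config: RiskConfig | None = None,
        mode: str = "eq1",
        family: str = "auto",
    ) -> None:
        if not studies or not populations:
            raise ValueError("model needs at least one study and one population")
        if mode not in ("eq1", "as_published"):
            raise ValueError(f"mode must be 'eq1' or 'as_published', got {mode!r}")
        self.studies = list(studies)
        self.populations = list(populations)
        self.config = config or RiskConfig()
        self.mode = mode
        self.family = family

    @classmethod
    def from_csv(cls, studies_path, populations_path, **kwargs) -> "TeaFluorideRisk":
        return cls(read_studies(studies_path), read_populations(populations_path), **kwargs)

    @classmethod
    def from_fixtures(cls, **kwargs) -> "TeaFluorideRisk":
        """Model built from the packaged literature tables."""
        return cls(datasets.load_studies(), datasets.load_populations(), **kwargs)

    def fit(self, settings: MonteCarloSettings | None = None) -> "TeaFluorideRiskResults":
        """Run the point evaluation and Monte Carlo propagation."""
        settings = settings or MonteCarloSettings()
        results = run_simulation(
            self.studies, self.populations, settings, self.config,
            mode=self.mode, family=self.family,
        )
        return TeaFluorideRiskResults(self, settings, results)


class TeaFluorideRiskResults:
    """Fitted results: point risks, percentile curves, exceedance rates."""

    def __init__(
        self,
        model: TeaFluorideRisk,
        settings: MonteCarloSettings,
        results: list[RiskResult],
    ) -> None:
        self.model = model
        self.settings = settings
        self.results = results

    # -- accessors -------------------------------------------------------

    @property
    def point_risks(self) -> list[PointRisk]:
        cfg = self.model.config
        return [
            PointRisk(
                r.study_id, r.population_name, r.point_cdi, r.point_hq,
                classify_hq(r.point_hq, cfg),
            )
            for r in self.results
        ]

    def to_frame(self) -> pd.DataFrame:
        """Tidy full-precision results, one row per study x population."""
        return results_frame(self.results, self.model.config)

    def table(self, percentiles: Sequence[float] = (), formatted: bool = True) -> pd.DataFrame:
        """Report table, one row per study, 3-significant-figure cells."""
        return summarize_to_table(
            self.results, self.model.config, percentiles=percentiles, formatted=formatted
        )

    def rank(self, study_id: str) -> list[str]:
        """Population names in descending point-HQ order for one study."""
        risks = [r for r in self.point_risks if r.study_id == str(study_id)]
        return rank_groups(risks)

    def exceedance_fraction(self, population_name: str) -> float:
        """Across studies: fraction whose point HQ exceeds the threshold."""
        return exceedance_fraction(self.point_risks, population_name, self.model.config)

    def concentration_ecdf(self, study_id: str) -> pd.DataFrame:
        """ECDF of the simulated concentrations for one study."""
        for r in self.results:
            if r.study_id == str(study_id) and r.conc_samples is not None:
                return cumulative_curve(r.conc_samples)
        raise KeyError(f"no retained samples for study {study_id!r}")

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of the assessment."""
        cfg = self.model.config
        lines = [
            "Fluoride exposure from tea: non-carcinogenic risk assessment",
            "=" * 64,
            f"mode: {self.model.mode}    distribution family: {self.model.family}",
            f"RfD: {cfg.rfd} mg/kg/day    hazard threshold (HQ): {cfg.hazard_threshold}",
            f"Monte Carlo: {self.settings.n_iterations} iterations, seed {self.settings.master_seed}",
            "",
            self.table().to_string(index=False),
            "",
        ]
        for pop in self.model.populations:
            frac = self.exceedance_fraction(pop.name)
            lines.append(
                f"{pop.name}: point HQ > {cfg.hazard_threshold} in "
                f"{frac:.0%} of studies"
            )
        return "\n".join(lines)

    def plot_concentration_ecdf(self, ax=None):
        """Cumulative probability curves of concentration, one per study."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        seen = set()
        for r in self.results:
            if r.study_id in seen or r.conc_samples is None:
                continue
            seen.add(r.study_id)
            curve = cumulative_curve(r.conc_samples)
            ax.step(
                curve["value"], curve["cumulative_probability"],
                where="post", label=f"study {r.study_id}",
            )
        ax.set_xlabel("fluoride concentration (mg/L)")
        ax.set_ylabel("cumulative probability")
        ax.legend()
        return ax
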
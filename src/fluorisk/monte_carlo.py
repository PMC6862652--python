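"""Monte Carlo propagation of concentration uncertainty into CDI/HQ.

For each study x population pair, concentrations are drawn from the study's
fitted distribution and pushed through the intake model, yielding empirical
percentile curves of CDI and HQ over the 1-99% assurance range, plus the
probability that HQ exceeds the hazard threshold.

Because the intake model is linear in concentration, HQ is a monotone
transform of the concentration sample; percentiles are therefore estimated
with the order-statistic (inverted-CDF, no interpolation) estimator so the
identity hq_percentile(p) == cdi_percentile(p) / RfD holds exactly for the
same sample, not merely asymptotically.

Each pair gets an independent pseudo-random substream spawned from the
master seed, so adding or reordering scenarios never perturbs the draws of
another and identical settings reproduce bit-identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import ConcentrationDistribution, fit_distribution
from .risk_model import (
    ConcentrationSummary,
    DataAnomalyWarning,
    ExposurePopulation,
    RiskConfig,
)

__all__ = [
    "MonteCarloSettings",
    "RiskResult",
    "run_simulation",
    "cumulative_curve",
    "summarize_to_table",
    "round_sig",
    "format_sig",
]

logger = logging.getLogger("fluorisk")

DEFAULT_ASSURANCE_GRID = tuple(np.round(np.linspace(0.01, 0.99, 99), 2))


@dataclass(frozen=True)
class MonteCarloSettings:
    """Simulation controls: iteration count, seed, reporting grid."""

    n_iterations: int = 10_000
    master_seed: int = 0
    percentiles: tuple[float, ...] = (0.05, 0.50, 0.95)
    assurance_grid: tuple[float, ...] = DEFAULT_ASSURANCE_GRID

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if any(not 0 <= p <= 1 for p in self.percentiles):
            raise ValueError("every requested percentile must lie in [0, 1]")
        grid = np.asarray(self.assurance_grid, dtype=float)
        if grid.size and (
            np.any(np.diff(grid) <= 0) or grid[0] < 0.01 - 1e-12 or grid[-1] > 0.99 + 1e-12
        ):
            raise ValueError("assurance_grid must be strictly increasing within [0.01, 0.99]")


@dataclass
class RiskResult:
    """Point and probabilistic risk for one study x population pair."""

    study_id: str
    population_name: str
    eval_conc: float  # concentration used for the point evaluation, mg/L
    point_cdi: float
    point_hq: float
    cdi_percentiles: dict[float, float]
    hq_percentiles: dict[float, float]
    prob_hq_exceeds: float
    conc_samples: np.ndarray | None = None


def _cdi_factor(pop: ExposurePopulation) -> float:
    """Multiplier turning a concentration (mg/L) into a CDI (mg/kg/day)."""
    return (pop.ir * pop.ef * pop.ed) / (pop.bw * pop.at)


def _mode_factors(populations: Sequence[ExposurePopulation], mode: str) -> list[float]:
    if mode == "eq1":
        return [_cdi_factor(p) for p in populations]
    if mode == "as_published":
        factors = []
        f = _cdi_factor(populations[0])
        for i, pop in enumerate(populations):
            if i > 0:
                f = f * (pop.ir / pop.bw)
            factors.append(f)
        return factors
    raise ValueError(f"unknown mode {mode!r}; choose 'eq1' or 'as_published'")


def _empirical_quantile(x: np.ndarray, p) -> np.ndarray:
    # order-statistic estimator; keeps monotone transforms exact
    return np.quantile(x, p, method="inverted_cdf")


def run_simulation(
    summaries: Sequence[ConcentrationSummary],
    populations: Sequence[ExposurePopulation],
    settings: MonteCarloSettings,
    config: RiskConfig,
    mode: str = "eq1",
    family: str = "auto",
    keep_samples: bool = True,
) -> list[RiskResult]:
    """Simulate every study x population pair.

    The point CDI/HQ use the study's published evaluation concentration when
    present; otherwise the empirical 95th-percentile simulated concentration
    is substituted. A study lacking both an evaluation concentration and
    fit-able statistics is skipped with a warning.
    """
    if not summaries or not populations:
        raise ValueError("need at least one study and one population")
    factors = _mode_factors(populations, mode)
    ss = np.random.SeedSequence(settings.master_seed)
    children = ss.spawn(len(summaries) * len(populations))
    results: list[RiskResult] = []
    n = settings.n_iterations
    for si, summary in enumerate(summaries):
        try:
            dist = fit_distribution(summary, family)
        except ValueError as exc:
            if summary.eval_conc is None:
                msg = (
                    f"study {summary.study_id}: no evaluation concentration and "
                    f"no fit-able statistics ({exc}); skipped"
                )
                logger.warning(msg)
                warnings.warn(msg, DataAnomalyWarning, stacklevel=2)
                continue
            dist = ConcentrationDistribution(
                "point", summary.eval_conc, summary.eval_conc
            )
        for pi, (pop, f) in enumerate(zip(populations, factors)):
            rng = np.random.default_rng(children[si * len(populations) + pi])
            conc = dist.sample(n, rng=rng)
            cdi = conc * f
            hq = cdi / config.rfd
            ps = settings.percentiles
            cdi_p = {float(p): float(q) for p, q in zip(ps, _empirical_quantile(cdi, list(ps)))} if ps else {}
            hq_p = {p: q / config.rfd for p, q in cdi_p.items()}
            eval_c = (
                summary.eval_conc
                if summary.eval_conc is not None
                else float(_empirical_quantile(conc, 0.95))
            )
            point_cdi = eval_c * f
            results.append(
                RiskResult(
                    study_id=summary.study_id,
                    population_name=pop.name,
                    eval_conc=eval_c,
                    point_cdi=point_cdi,
                    point_hq=point_cdi / config.rfd,
                    cdi_percentiles=cdi_p,
                    hq_percentiles=hq_p,
                    prob_hq_exceeds=float(np.mean(hq > config.hazard_threshold)),
                    conc_samples=conc if keep_samples else None,
                )
            )
    logger.info(
        "simulated %d pairs (%d studies x %d populations, %d iterations, mode=%s)",
        len(results), len(summaries), len(populations), n, mode,
    )
    return results


def cumulative_curve(samples) -> pd.DataFrame:
    """ECDF of a sample: one (value, cumulative probability) row per draw.

    Probabilities climb from 1/n to 1 over the ascending order statistics —
    the step function behind a cumulative probability plot.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("cumulative_curve requires at least one sample")
    probs = np.arange(1, x.size + 1) / x.size
    return pd.DataFrame({"value": x, "cumulative_probability": probs})


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    return float(f"{x:.{digits}g}")


def format_sig(x: float, digits: int = 3) -> str:
    return f"{x:.{digits}g}"


def summarize_to_table(
    results: Sequence[RiskResult],
    config: RiskConfig,
    percentiles: Sequence[float] = (),
    formatted: bool = True,
    digits: int = 3,
) -> pd.DataFrame:
    """Pivot results into a report table, one row per study.

    Columns: the evaluation concentration, then CDI and THQ per population
    (point values), then any requested percentile columns. With
    ``formatted=True`` every cell is rendered to ``digits`` significant
    figures; ``formatted=False`` returns full-precision numbers.
    """
    if not results:
        raise ValueError("summarize_to_table requires at least one result")
    study_order: list[str] = []
    pop_order: list[str] = []
    for r in results:
        if r.study_id not in study_order:
            study_order.append(r.study_id)
        if r.population_name not in pop_order:
            pop_order.append(r.population_name)
    rows = {}
    for r in results:
        row = rows.setdefault(r.study_id, {"study_id": r.study_id, "eval_conc_mgL": r.eval_conc})
        row[f"cdi_{r.population_name}"] = r.point_cdi
        row[f"thq_{r.population_name}"] = r.point_hq
        for p in percentiles:
            if p in r.cdi_percentiles:
                row[f"cdi_p{int(round(p * 100)):02d}_{r.population_name}"] = r.cdi_percentiles[p]
                row[f"thq_p{int(round(p * 100)):02d}_{r.population_name}"] = r.hq_percentiles[p]
    cols = ["study_id", "eval_conc_mgL"]
    cols += [f"cdi_{p}" for p in pop_order] + [f"thq_{p}" for p in pop_order]
    for p in percentiles:
        tag = f"p{int(round(p * 100)):02d}"
        cols += [f"cdi_{tag}_{name}" for name in pop_order]
        cols += [f"thq_{tag}_{name}" for name in pop_order]
    table = pd.DataFrame([rows[s] for s in study_order])
    table = table[[c for c in cols if c in table.columns]]
    if formatted:
        num = table.columns.drop("study_id")
        table[num] = table[num].map(lambda v: format_sig(v, digits))
    return table
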
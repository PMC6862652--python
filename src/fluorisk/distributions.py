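"""Bounded concentration distributions built from summary statistics.

Literature studies report only (mean, min, max) and sometimes an SD, so the
concentration distribution must be reconstructed from summaries rather than
fitted to raw data. All supported families have bounded support equal to the
reported [min, max] range:

``point``
    Degenerate mass (min == max).
``uniform``
    Flat over [min, max]; uses no central statistic.
``triangular``
    (min, mean-as-mode, max). The default under the ``auto`` rule because it
    consumes exactly the three statistics every study reports. The reported
    mean stands in for the mode, a documented approximation.
``truncated_normal``
    Normal(mean, sd) truncated to [min, max]; chosen by ``auto`` only when
    the reported SD is arithmetically consistent with the reported range.
``lognormal_truncated``
    Lognormal with (mu, sigma) moment-matched to the arithmetic mean/SD,
    truncated to [min, max]; available on request.

Sampling is inverse-transform from a uniform stream, so any seeded
generator yields reproducible draws and every draw respects the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

from .risk_model import ConcentrationSummary, sd_consistent_with_range

__all__ = ["ConcentrationDistribution", "fit_distribution", "FAMILIES"]

FAMILIES = ("point", "uniform", "triangular", "truncated_normal", "lognormal_truncated")

ArrayLike = Union[float, np.ndarray]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match (mu, sigma) of ln X to an arithmetic mean and SD."""
    mu = np.log(mean**2 / np.sqrt(mean**2 + sd**2))
    sigma = np.sqrt(np.log(1.0 + (sd / mean) ** 2))
    return mu, sigma


@dataclass(frozen=True)
class ConcentrationDistribution:
    """A bounded probability distribution for fluoride concentration (mg/L).

    ``location`` is the mode (triangular) or mean (normal/lognormal
    families); ``scale`` is the SD-like parameter where the family needs
    one. Support is always [lower, upper].
    """

    family: str
    lower: float
    upper: float
    location: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")
        if self.family == "triangular":
            if self.location is None:
                raise ValueError("triangular needs a location (mode)")
            if not self.lower <= self.location <= self.upper:
                raise ValueError(
                    f"triangular mode {self.location} outside [{self.lower}, {self.upper}]"
                )
        if self.family in ("truncated_normal", "lognormal_truncated"):
            if self.location is None or self.scale is None:
                raise ValueError(f"{self.family} needs location and scale")
            if self.scale <= 0:
                raise ValueError("scale must be strictly positive")

    # -- scipy backend -------------------------------------------------

    def _frozen(self):
        """The underlying scipy frozen distribution (continuous families)."""
        a, b = self.lower, self.upper
        if self.family == "uniform":
            return stats.uniform(loc=a, scale=b - a)
        if self.family == "triangular":
            if b == a:
                return None
            return stats.triang(c=(self.location - a) / (b - a), loc=a, scale=b - a)
        if self.family == "truncated_normal":
            mu, sd = self.location, self.scale
            return stats.truncnorm((a - mu) / sd, (b - mu) / sd, loc=mu, scale=sd)
        if self.family == "lognormal_truncated":
            mu, sigma = _lognormal_params(self.location, self.scale)
            return stats.lognorm(s=sigma, scale=np.exp(mu))
        return None  # point

    def _parent_cdf_bounds(self, dist) -> tuple[float, float]:
        return float(dist.cdf(self.lower)), float(dist.cdf(self.upper))

    # -- public surface ------------------------------------------------

    def quantile(self, p: ArrayLike) -> ArrayLike:
        """Closed-form inverse CDF; monotone nondecreasing in p on [0, 1]."""
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("quantile probability must lie in [0, 1]")
        if self.family == "point" or self.lower == self.upper:
            out = np.full_like(p, self.lower, dtype=float)
            return float(out) if out.ndim == 0 else out
        dist = self._frozen()
        if self.family == "lognormal_truncated":
            fl, fu = self._parent_cdf_bounds(dist)
            out = dist.ppf(fl + p * (fu - fl))
        else:
            out = dist.ppf(p)
        out = np.clip(out, self.lower, self.upper)
        return float(out) if out.ndim == 0 else out

    def cdf(self, x: ArrayLike) -> ArrayLike:
        x = np.asarray(x, dtype=float)
        if self.family == "point" or self.lower == self.upper:
            out = (x >= self.lower).astype(float)
            return float(out) if out.ndim == 0 else out
        dist = self._frozen()
        if self.family == "lognormal_truncated":
            fl, fu = self._parent_cdf_bounds(dist)
            out = (np.clip(dist.cdf(x), fl, fu) - fl) / (fu - fl)
        else:
            out = dist.cdf(x)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def pdf(self, x: ArrayLike) -> ArrayLike:
        if self.family == "point" or self.lower == self.upper:
            raise ValueError("point mass has no density")
        x = np.asarray(x, dtype=float)
        dist = self._frozen()
        if self.family == "lognormal_truncated":
            fl, fu = self._parent_cdf_bounds(dist)
            out = np.where(
                (x >= self.lower) & (x <= self.upper), dist.pdf(x) / (fu - fl), 0.0
            )
        else:
            out = dist.pdf(x)
        return float(out) if out.ndim == 0 else out

    def mean(self) -> float:
        if self.family == "point" or self.lower == self.upper:
            return self.lower
        if self.family == "triangular":
            return (self.lower + self.location + self.upper) / 3.0
        dist = self._frozen()
        if self.family == "lognormal_truncated":
            # numeric mean of the truncated parent via quantile integration
            p = (np.arange(20001) + 0.5) / 20001
            return float(np.mean(self.quantile(p)))
        return float(dist.mean())

    def sample(
        self,
        n: int,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Draw ``n`` concentrations by inverse transform.

        Identical (seed, n) reproduce the identical sequence; every draw
        lies inside [lower, upper].
        """
        if n < 1:
            raise ValueError(f"sample size n must be >= 1, got {n}")
        if rng is None:
            rng = np.random.default_rng(seed)
        return np.asarray(self.quantile(rng.random(n)), dtype=float).reshape(n)


def fit_distribution(
    summary: ConcentrationSummary, family: str = "auto"
) -> ConcentrationDistribution:
    """Build a bounded distribution from a study's summary statistics.

    The ``auto`` rule: point if min == max; truncated normal if a reported
    SD is arithmetically plausible for the reported range and sample size;
    triangular(min, mean, max) otherwise. Explicit families raise when the
    summary lacks a statistic they need, naming the missing field.
    """
    lo, hi, mean, sd = summary.min_conc, summary.max_conc, summary.mean_conc, summary.sd_conc
    if family == "auto":
        if lo == hi:
            family = "point"
        elif sd is not None and sd > 0 and sd_consistent_with_range(summary):
            family = "truncated_normal"
        else:
            family = "triangular"
    if family == "point":
        if lo != hi:
            raise ValueError(
                f"study {summary.study_id}: point family requires min_conc == max_conc"
            )
        return ConcentrationDistribution("point", lo, hi, location=mean)
    if family == "uniform":
        return ConcentrationDistribution("uniform", lo, hi)
    if family == "triangular":
        return ConcentrationDistribution("triangular", lo, hi, location=mean)
    if family in ("truncated_normal", "lognormal_truncated"):
        if sd is None or sd <= 0:
            raise ValueError(
                f"study {summary.study_id}: {family} requires a positive sd_conc"
            )
        return ConcentrationDistribution(family, lo, hi, location=mean, scale=sd)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES} or 'auto'")
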
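"""Packaged fixture tables: the literature study summaries and the exposure
parameters of the three population groups (men, women, children)."""

from __future__ import annotations

from importlib import resources

from .io import read_studies, read_populations
from .risk_model import ConcentrationSummary, ExposurePopulation


def _data_path(name: str):
    return resources.files("fluorisk").joinpath("data", name)


def studies_csv_path():
    """Path-like handle to the packaged study-summary CSV."""
    return _data_path("studies.csv")


def populations_csv_path():
    """Path-like handle to the packaged population-parameter CSV."""
    return _data_path("populations.csv")


def load_studies() -> list[ConcentrationSummary]:
    """The five literature studies of fluoride in Iranian tea infusions."""
    with resources.as_file(studies_csv_path()) as p:
        return read_studies(p)


def load_populations() -> list[ExposurePopulation]:
    """Men, women and children exposure groups, in published order."""
    with resources.as_file(populations_csv_path()) as p:
        return read_populations(p)
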
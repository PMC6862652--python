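import pytest
from hypothesis import settings

from fluorisk import ExposurePopulation, RiskConfig, datasets

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

# Published results table, frozen at the printed 3-significant-figure
# precision: study -> (evaluation concentration, (CDI men, women, children),
# (THQ men, women, children)).
TABLE3 = {
    "23": (0.36, (9.23e-3, 2.84e-4, 1.96e-5), (0.154, 4.73e-3, 3.26e-4)),
    "26": (2.63, (6.74e-2, 2.07e-3, 1.43e-4), (1.12, 3.46e-2, 2.39e-3)),
    "27": (1.36, (3.49e-2, 1.07e-3, 7.40e-5), (0.581, 1.79e-2, 1.23e-3)),
    "28": (2.09, (5.36e-2, 1.65e-3, 1.14e-4), (0.893, 2.75e-2, 1.90e-3)),
    "17": (1.80, (4.62e-2, 1.42e-3, 9.79e-5), (0.769, 2.37e-2, 1.63e-3)),
}

GROUPS = ("men", "women", "children")


@pytest.fixture(scope="session")
def populations():
    return datasets.load_populations()


@pytest.fixture(scope="session")
def men(populations):
    return populations[0]


@pytest.fixture(scope="session")
def studies():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return datasets.load_studies()


@pytest.fixture(scope="session")
def config():
    return RiskConfig()
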
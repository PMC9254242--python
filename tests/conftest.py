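import warnings

import numpy as np
import pytest

from lipidcascade.cohort import GeneratorConfig, Stage, generate_cohort
from lipidcascade.pipeline import analysis_views as cohort_views  # noqa: F401


def small_config(seed: int = 0, **kw) -> GeneratorConfig:
    """Scaled-down cohort for fast unit tests: 60 lipids, 5 signals."""
    defaults = dict(
        n_discovery=120, n_validation=120, n_prospective=90, n_subcohort=40,
        n_lipids=60, signal_lipids=5,
        discovery_stage_counts={Stage.SG: 18, Stage.CAG: 30, Stage.IM: 36,
                                Stage.LGIN: 18, Stage.HGIN: 13, Stage.GC: 5},
        validation_stage_counts={Stage.SG: 16, Stage.CAG: 27, Stage.IM: 33,
                                 Stage.LGIN: 15, Stage.HGIN: 17, Stage.GC: 12},
        n_protein_subjects=60, seed=seed)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-size bundle shared across tests (study-scale cohorts)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort(small_config(seed=5))


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
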
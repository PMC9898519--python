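import numpy as np
import pytest

from contcls import (
    StudyConfig,
    SynthConfig,
    default_taxonomy,
    generate_cohort,
    run_study,
)
from contcls.datasets import select_cases


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def small_cohort(taxonomy):
    """120 synthetic cases with in-memory images, per-side selection applied."""
    cases = generate_cohort(SynthConfig(n_cases=120, seed=7), taxonomy)
    return select_cases(cases, taxonomy)


@pytest.fixture(scope="session")
def default_studies(taxonomy):
    """Ten runs of the default 6-stage study (seeds 0..9), shared across tests.

    This is the package's reference experiment: ~300 cases, 64x64 phantoms,
    default SGD backbone, 6 stages with trigger 30 / 20 rounds.
    """
    return [run_study(StudyConfig(seed=s)) for s in range(10)]
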
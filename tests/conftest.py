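import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from csfnet.simulate import (BatchDesign, CohortSpec, ModulePlantSpec,
                             generate_cohort, generate_tmt)

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec())


@pytest.fixture(scope="session")
def tmt(cohort):
    """Default synthetic TMT dataset: (AbundanceMatrix, GroundTruth)."""
    return generate_tmt(cohort, ModulePlantSpec(), BatchDesign(), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
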
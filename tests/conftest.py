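import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cnssig as cs

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def codeset() -> cs.CodeSet:
    return cs.default_codeset()


@pytest.fixture(scope="session")
def small_cohort(codeset):
    """A 17-sample supratentorial cohort with two planted entities."""
    config = cs.CohortConfig(
        compartment="supratentorial",
        background_diagnoses={"HGG": 6, "PNET": 5},
        planted_entities={"HGNET-BCOR": 3, "HGNET-MN1": 3},
        seed=7,
    )
    samples, truth = cs.generate_nanostring_cohort(config, codeset)
    return config, samples, truth


@pytest.fixture(scope="session")
def small_normalized(small_cohort, codeset):
    _, samples, truth = small_cohort
    return cs.normalize_cohort(samples, codeset), truth


@pytest.fixture(scope="session")
def supra_cohort(codeset):
    """The default 92-sample supratentorial cohort (all four entities)."""
    config = cs.default_supratentorial_config(seed=3)
    samples, truth = cs.generate_nanostring_cohort(config, codeset)
    norm = cs.normalize_cohort(samples, codeset)
    return config, truth, norm


def make_normalized(values: pd.DataFrame) -> cs.NormalizedMatrix:
    """Wrap a log2-scale DataFrame as a NormalizedMatrix (factors of 1)."""
    return cs.NormalizedMatrix(
        values=values,
        linear=2.0 ** values,
        tech_factors=pd.Series(1.0, index=values.columns),
        bio_factors=pd.Series(1.0, index=values.columns),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
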
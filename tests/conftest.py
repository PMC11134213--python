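import numpy as np
import pandas as pd
import pytest

from metadyad.cohort import ConcentrationMatrix
from metadyad.simulate import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240461)


@pytest.fixture
def small_matrix():
    """5 samples x 4 metabolites with one missing cell."""
    vals = pd.DataFrame(
        {
            "ala": [1.0, 2.0, 3.0, 4.0, 5.0],
            "gly": [10.0, 20.0, np.nan, 40.0, 50.0],
            "leu": [5.0, 5.5, 6.0, 6.5, 7.0],
            "val": [2.0, 1.0, 4.0, 3.0, 6.0],
        },
        index=[f"S{i}" for i in range(5)],
    )
    return ConcentrationMatrix("placenta", vals)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-dyad tri-compartment cohort with one placenta-cord factor."""
    cfg = SyntheticCohortConfig(
        n_dyads=60,
        p_per_block={"maternal_serum": 10, "placenta": 12, "cord_serum": 9},
        seed=11,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth
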
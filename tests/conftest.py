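import numpy as np
import pandas as pd
import pytest

from pneumotyper.containers import CountTable
from pneumotyper.simulate import simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (60 subjects, 300 taxa), seed 1."""
    sources, lungs, meta, truth = simulate_cohort(seed=1)
    return sources, lungs, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_table(rng):
    """5 samples x 8 taxa random count table."""
    counts = rng.integers(0, 200, size=(5, 8))
    counts[0, 0] += 1  # guard against an all-zero row
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(5)],
            columns=[f"t{j}" for j in range(8)],
        )
    )
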
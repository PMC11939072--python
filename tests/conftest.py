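import numpy as np
import pandas as pd
import pytest

from rbnsig import CohortSpec, generate_cohort
from rbnsig.io import ExpressionMatrix


def matrix_from(values, genes=None, samples=None, value_kind="zscore") -> ExpressionMatrix:
    """Build an ExpressionMatrix from a nested list / array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), value_kind)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (seed 1), shared across tests."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
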
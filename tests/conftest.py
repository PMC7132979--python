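import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from reograde import ExpressionMatrix, SimulationConfig, simulate_grade_cohort

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


def make_matrix(values, gene_ids=None, sample_ids=None, scale="log2") -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array-like."""
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-gene cohort with 10 perfect planted reversal pairs, 15/group."""
    config = SimulationConfig(
        n_genes=60, n_planted_pairs=10, n_hg1=15, n_hg3=15, fidelity=1.0, seed=11
    )
    return simulate_grade_cohort(config)


@pytest.fixture
def clinical_frame():
    """Hand-built clinical table for survival tests."""
    return pd.DataFrame(
        {
            "grade": ["pHG1"] * 3 + ["pHG3"] * 3,
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
        },
        index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
    )
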
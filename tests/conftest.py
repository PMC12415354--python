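import numpy as np
import pandas as pd
import pytest

from m6apattern.datatypes import ClinicalTable, ExpressionMatrix
from m6apattern.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-sample synthetic cohort with planted structure (delta=2)."""
    params = SimulationParams(n_samples=150, delta=2.0, hazard_beta=1.0,
                              censoring_rate=0.3, seed=42)
    expr, clinical, mutations, truth = simulate_cohort(params)
    return expr, clinical, mutations, truth, params


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 samples, simple numbers."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, unit="log2TPM1")


@pytest.fixture()
def toy_clinical():
    return ClinicalTable(pd.DataFrame(
        {"time": [10.0, 20.0, 30.0, 40.0], "event": [1, 1, 0, 1]},
        index=["s1", "s2", "s3", "s4"],
    ))
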
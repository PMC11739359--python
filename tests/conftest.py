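import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sepsisratio import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale default cohort (5000 genes, 180 samples), seed 42."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort configuration for fast multi-seed tests."""
    return CohortConfig(
        n_genes=800,
        n_up_stable=10,
        n_down_stable=2,
        n_d1_only_degs=12,
        n_d23_only_degs=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def toy_cohort(matrix: np.ndarray, outcomes, timepoints=None, batches=None):
    """Assemble a minimal ExpressionCohort around a raw matrix."""
    from sepsisratio import ExpressionCohort

    n = matrix.shape[1]
    timepoints = timepoints or ["D1"] * n
    batches = batches or ["B1"] * n
    sids = [f"S{i}_{tp}" for i, tp in enumerate(timepoints)]
    meta = pd.DataFrame(
        {
            "patient_id": [f"S{i}" for i in range(n)],
            "timepoint": timepoints,
            "batch": batches,
            "outcome": outcomes,
            "lactate": 1.0,
            "survival_time": 30.0,
            "event": False,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    return ExpressionCohort(pd.DataFrame(matrix, index=genes, columns=sids), meta)
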
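import numpy as np
import pandas as pd
import pytest

from dysbiome.coredata import CohortMetadata, CountTable
from dysbiome.synthcohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest family cohort with default disease effects and inflated IBD
    dispersion; shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11, n_families=40))


@pytest.fixture(scope="session")
def quiet_cohort():
    """Cohort with no disease effects and no dispersion inflation."""
    cfg = SimulationConfig(
        seed=12, n_families=40, disease_log2fc=np.zeros(120),
        dispersion_inflation_ibd=1.0)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_counts():
    """Tiny hand-checkable count table."""
    df = pd.DataFrame(
        [[1, 3, 9], [2, 6, 18], [10, 0, 5]],
        index=["s1", "s2", "s3"], columns=["t1", "t2", "t3"])
    return CountTable(df)


@pytest.fixture
def toy_metadata():
    rng = np.random.default_rng(3)
    n = 120
    return CohortMetadata(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "subject_id": [f"s{i}" for i in range(n)],
        "diagnosis": rng.choice(["Control", "CD", "UC"], n, p=[0.5, 0.3, 0.2]),
        "sex": rng.choice(["M", "F"], n),
        "age": rng.normal(45, 12, n).round(1),
        "bmi": rng.normal(25, 4, n).round(2),
    }))
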
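import numpy as np
import pandas as pd
import pytest

import matplotlib

matplotlib.use("Agg")

from cnarisk import (
    CNAMatrix,
    Cohort,
    SimulationConfig,
    SurvivalTable,
    run_pipeline,
    simulate_cohort,
)


@pytest.fixture
def toy_cna() -> CNAMatrix:
    """3 genes x 4 samples covering all five threshold calls."""
    values = pd.DataFrame(
        [[-2, 0, 1, 2], [0, -1, 0, 1], [2, 2, -1, 0]],
        index=pd.Index(["TP53", "MYC", "EGFR"], name="Gene Symbol"),
        columns=["S1", "S2", "S3", "S4"],
    )
    return CNAMatrix(values)


@pytest.fixture
def toy_surv() -> SurvivalTable:
    data = pd.DataFrame(
        {"time": [100.0, 250.0, 400.0, 900.0], "event": [1, 1, 0, 1],
         "stage": ["i", "ii", "ii", "i"]},
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample"),
    )
    return SurvivalTable(data)


def make_survival(n: int, seed: int, event_frac: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Null survival data with continuous times and mixed censoring."""
    rng = np.random.default_rng(seed)
    time = rng.exponential(1000.0, n)
    event = (rng.random(n) < event_frac).astype(int)
    return time, event


@pytest.fixture(scope="session")
def default_sim():
    """The reference planted scenario: n=300, 200 genes, five deep-amp
    high-risk genes (beta=1.5, 8% carriers), seed 0."""
    return simulate_cohort(SimulationConfig())


@pytest.fixture(scope="session")
def default_cohort(default_sim) -> Cohort:
    return default_sim.cohort()


@pytest.fixture(scope="session")
def default_pipeline(default_sim, default_cohort):
    """Full pipeline run on the reference planted scenario."""
    return run_pipeline(default_cohort)
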
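import numpy as np
import pandas as pd
import pytest

from adoptnet import SimulationConfig, generate_cohort
from adoptnet.config import DEFAULT_CONFOUNDER_SD


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_physicians=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A 400-physician cohort reused across read-only tests."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def confounded_cohort():
    """Mid-size cohort with the canonical peer-correlated confounder on."""
    cfg = SimulationConfig(n_physicians=1500, seed=42, confounder_sd=DEFAULT_CONFOUNDER_SD)
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_row_stochastic(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dense random row-stochastic matrix with zero diagonal."""
    w = rng.random((n, n))
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


@pytest.fixture()
def toy_prescribing() -> pd.DataFrame:
    """Four physicians with window totals 0, 6, 7, 13 for the new drug."""
    rows = []
    totals = {"A": 0, "B": 6, "C": 7, "D": 13}
    for pid, total in totals.items():
        for q in range(1, 6):
            share = total // 5 + (1 if q <= total % 5 else 0)
            rows.append((pid, "new_drug", q, share))
            rows.append((pid, "class_other", q, 2))
    return pd.DataFrame(rows, columns=["physician_id", "drug", "quarter", "n_prescriptions"])
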
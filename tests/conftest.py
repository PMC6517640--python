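import numpy as np
import pandas as pd
import pytest

from patternreg.synthetic import CohortConfig, cohort_to_table, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject cohort on a 6^3 grid with planted signal and dropout."""
    config = CohortConfig(
        n_distressed=10,
        n_healthy=10,
        grid_shape=(6, 6, 6),
        signal_snr=0.8,
        n_signal_voxels=20,
        scanner_split={"distressed": (6, 4), "healthy": (6, 4)},
        dropout_fraction=0.1,
        dropout_extent=0.05,
        seed=42,
    )
    records, truth = generate_cohort(config)
    return config, records, truth


@pytest.fixture(scope="session")
def study_table():
    """Subject table shaped like the real study: n=154, scanners 119/35."""
    config = CohortConfig(grid_shape=(2, 2, 2), n_signal_voxels=1, seed=7)
    records, _ = generate_cohort(config)
    return cohort_to_table(records)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_null_features(n: int, p: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).standard_normal((n, p))


@pytest.fixture
def simple_table():
    rng = np.random.default_rng(3)
    n = 40
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "scanner": ["A"] * 28 + ["B"] * 12,
            "gender": list(np.where(rng.random(n) < 0.6, "F", "M")),
            "age": rng.normal(21.6, 2.0, n),
            "stai_t": rng.normal(44, 15, n),
        }
    )
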
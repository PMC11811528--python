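import numpy as np
import pandas as pd
import pytest

from transdx import make_model


def make_participants(rows):
    """Build a participant table from (id, sex, age, motion, site, icd10) tuples."""
    return pd.DataFrame(rows, columns=["id", "sex", "age", "motion", "site", "icd10"])


@pytest.fixture
def fast_rf():
    """Random forest spec scaled for unit tests: single grid point, few trees."""
    return make_model(
        "random_forest",
        fixed_settings={"n_estimators": 50},
        tuning_grid={"pca_rank": [8], "max_depth": [None], "max_features": ["sqrt"]},
    )


@pytest.fixture
def fast_svc():
    return make_model("support_vector", tuning_grid={"pca_rank": [8], "C": [1.0], "kernel": ["linear"]})


@pytest.fixture
def fast_knn():
    return make_model("k_nearest_neighbors", tuning_grid={"pca_rank": [8], "n_neighbors": [15]})


def random_pool(n, seed, sites=3):
    """A rich healthy control pool with no diagnostic codes."""
    rng = np.random.default_rng(seed)
    return make_participants(
        [
            (
                f"C{i:05d}",
                "F" if rng.random() < 0.5 else "M",
                float(rng.uniform(40, 70)),
                float(rng.lognormal(np.log(0.15), 0.4)),
                int(rng.integers(0, sites)),
                "",
            )
            for i in range(n)
        ]
    )
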
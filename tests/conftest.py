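import numpy as np
import pandas as pd
import pytest

from enspec import (
    EnsembleTable,
    FitConfig,
    demo_truths,
    sample_ensemble,
)


@pytest.fixture
def toy_frame():
    """2 geometries x 3 states, hand-written."""
    return pd.DataFrame(
        {
            "geom_id": ["g1", "g1", "g1", "g2", "g2", "g2"],
            "state": [1, 2, 3, 1, 2, 3],
            "delta_E": [4.0, 5.0, 6.0, 4.2, 5.1, 6.3],
            "f": [0.10, 0.00, 0.30, 0.12, 0.05, 0.25],
        }
    )


@pytest.fixture
def toy_table(toy_frame):
    return EnsembleTable(toy_frame)


@pytest.fixture(scope="session")
def truths():
    return demo_truths()


@pytest.fixture(scope="session")
def demo_table(truths):
    return sample_ensemble(truths, 300, seed=42)


@pytest.fixture(scope="session")
def fast_config():
    """Restricted selection config keeping unit tests quick."""
    return FitConfig(k_range=(1, 2, 3), restarts=2, tol=1e-7, max_iter=300, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
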
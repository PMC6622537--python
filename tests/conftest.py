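import numpy as np
import pandas as pd
import pytest

from oncoforest.features import assemble_matrix
from oncoforest.synthetic import generate_dataset, smoke_preset


@pytest.fixture(scope="session")
def smoke_data():
    """Small synthetic screen (60 cells x 10 drugs) with known ground truth."""
    panel, drugs, sens, model = generate_dataset(smoke_preset(seed=1))
    return panel, drugs, sens, model


@pytest.fixture(scope="session")
def smoke_matrix(smoke_data):
    panel, drugs, sens, _ = smoke_data
    return assemble_matrix(panel, drugs, sens)


@pytest.fixture()
def random_panel_frame():
    """Seeded random 50x20 mutation table with sporadic missing entries."""
    rng = np.random.default_rng(42)
    vals = rng.choice([0.0, 1.0, np.nan], size=(50, 20), p=[0.55, 0.4, 0.05])
    return pd.DataFrame(
        vals,
        index=[f"cell_{i:03d}" for i in range(50)],
        columns=[f"gene_{j:03d}" for j in range(20)],
    )
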
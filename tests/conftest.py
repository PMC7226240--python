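import numpy as np
import pandas as pd
import pytest

from cementome.io import QuantMatrix
from cementome.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-protein dataset shared across read-only tests."""
    cfg = SyntheticConfig(n_proteins=60, seed=42)
    return generate_dataset(cfg)


@pytest.fixture()
def toy_matrix():
    """3 proteins x 6 runs (one tissue, 3 times x 2 tech reps)."""
    runs = pd.DataFrame(
        {
            "tissue": ["salivary_gland"] * 6,
            "extraction": ["native"] * 6,
            "time": ["T1", "T1", "T2", "T2", "T3", "T3"],
            "bio_rep": [1, 2, 1, 2, 1, 2],
            "tech_rep": [1, 1, 1, 1, 1, 1],
        },
        index=pd.Index([f"r{i}" for i in range(6)], name="run"),
    )
    values = pd.DataFrame(
        np.array([
            [10.0, 12.0, 11.0, 9.0, 10.0, 11.0],
            [5.0, 6.0, 20.0, 22.0, 5.0, 6.0],
            [1.0, 2.0, 1.5, 2.5, 8.0, 9.0],
        ]),
        index=pd.Index(["pA", "pB", "pC"], name="protein"),
        columns=runs.index,
    )
    return QuantMatrix(values, runs)
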
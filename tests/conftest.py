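import numpy as np
import pytest

from cogload.features import build_feature_table
from cogload.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-participant synthetic dataset plus its feature table (shared)."""
    cfg = SyntheticConfig(n_participants=6, seed=123)
    streams, participants = generate_dataset(cfg)
    table = build_feature_table(streams, participants)
    return {"config": cfg, "streams": streams, "participants": participants, "table": table}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
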
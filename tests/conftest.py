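import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from toxscreen import (  # noqa: E402
    ScreenSimConfig,
    simulate_library,
    simulate_screen_counts,
)


@pytest.fixture(scope="session")
def small_screen():
    """200-gene screen with planted effects, shared across read-only tests."""
    cfg = ScreenSimConfig(n_genes=200, seed=1)
    lib = simulate_library(cfg)
    cm, truth = simulate_screen_counts(lib, cfg)
    return cfg, lib, cm, truth


@pytest.fixture
def tiny_library():
    return pd.DataFrame(
        {
            "sgrna": ["g1_sg1", "g1_sg2", "g2_sg1", "g2_sg2"],
            "gene": ["g1", "g1", "g2", "g2"],
            "sequence": [
                "ACGTACGTACGTACGTACGT",
                "TTTTCCCCGGGGAAAATTTT",
                "GATTACAGATTACAGATTAC",
                "CCGGAATTCCGGAATTCCGG",
            ],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
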
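import numpy as np
import pandas as pd
import pytest

from ipdmix import (
    DGPParams,
    MCMCConfig,
    ScenarioConfig,
    draw_complete_ipd,
)


@pytest.fixture(scope="session")
def small_complete():
    """10 studies x 60, defaults; shared by sampler and pooling tests."""
    cfg = ScenarioConfig(10, 60, rho=0.2, phi=0.1, seed=101)
    return draw_complete_ipd(cfg)


@pytest.fixture(scope="session")
def small_fit(small_complete):
    """A short 2-chain fit of the joint model on the small complete table."""
    from ipdmix import JointLatentNormalModel

    model = JointLatentNormalModel(small_complete)
    return model.fit(MCMCConfig(2000, 800, 2, 1, seed=7))

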
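import numpy as np
import pytest

from fibrc.device import DeviceParams
from fibrc.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def params() -> DeviceParams:
    return DeviceParams()


@pytest.fixture(scope="session")
def stage3_run():
    """Full stage3 pipeline at the default study conditions (seed 7).

    Session-scoped: the reservoir encoding of 180 epochs dominates runtime
    and is shared across the tests that assert on it.
    """
    cfg = RunConfig(seed=7)
    cfg.readout.kind = "both"
    return run_pipeline(cfg, "stage3")


@pytest.fixture(scope="session")
def snore2_run():
    cfg = RunConfig(seed=7)
    cfg.readout.kind = "both"
    return run_pipeline(cfg, "snore2")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
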
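import numpy as np
import pytest

from nirsdive import MBLLTransformer, SimulationConfig, simulate_dive
from nirsdive.io import packaged_blood_gas


@pytest.fixture(scope="session")
def dive42():
    """One 42 m synthetic dive (seed 7) with ground truth."""
    return simulate_dive(SimulationConfig(seed=7, depth_m=42.0))


@pytest.fixture(scope="session")
def dive42_chromo(dive42):
    rec, _, _ = dive42
    return MBLLTransformer().fit(rec).transform(rec)


@pytest.fixture(scope="session")
def blood_gas():
    return packaged_blood_gas()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240906)
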
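import numpy as np
import pytest

from membind import TitrationProtocol
from membind.composition import NoiseModel


@pytest.fixture
def protocol() -> TitrationProtocol:
    """50 uM protein cell titrated with 25 x 10 uL of 1 mM ligand (c ~ 3.6)."""
    return TitrationProtocol.uniform(
        25, 10e-6, cell_volume_L=1.4e-3, cell_conc_M=50e-6,
        syringe_conc_M=1e-3, temperature_K=298.15)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def noise(sigma: float, seed: int = 0) -> NoiseModel:
    return NoiseModel(sigma=sigma, seed=seed)
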
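import numpy as np
import pytest

import bovisim as bv
from helpers import mini_config


@pytest.fixture(scope="session")
def mini_replicate():
    """One tiny end-to-end replicate: (population, trait)."""
    rng = np.random.default_rng(1234)
    return bv.simulate_replicate(mini_config(), rng)


@pytest.fixture(scope="session")
def desk_replicate():
    """One desk-scale replicate (5 chromosomes, 5,000 SNPs) shared by the
    structural and kinship tests."""
    rng = np.random.default_rng(99)
    return bv.simulate_replicate(bv.profile("desk"), rng)
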
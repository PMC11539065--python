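import warnings

import numpy as np
import pytest

from fabsolv.synth import build_toy_protein

# MDAnalysis emits benign format warnings on synthetic PDB fixtures
warnings.filterwarnings("ignore", module="MDAnalysis")


@pytest.fixture(scope="session")
def toy_protein():
    return build_toy_protein(20, "helix")


@pytest.fixture(scope="session")
def toy_extended():
    return build_toy_protein(6, "extended")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
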
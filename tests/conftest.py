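import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for dft_oracle

from rrmkit.catalog import load_catalog
from rrmkit.encoding import load_scale


@pytest.fixture(scope="session")
def protein_scale():
    return load_scale("eiip_protein")


@pytest.fixture(scope="session")
def dna_scale():
    return load_scale("eiip_dna")


@pytest.fixture(scope="session")
def catalog_records():
    return load_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
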
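import numpy as np
import pytest

from dynappi.pharmacophore import build_sxip_model
from dynappi.synthetic import make_sxip_peptide


@pytest.fixture(scope="session")
def sxip_peptide():
    return make_sxip_peptide()


@pytest.fixture(scope="session")
def sxip_model(sxip_peptide):
    return build_sxip_model(sxip_peptide)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
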
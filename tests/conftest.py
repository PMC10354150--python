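import numpy as np
import pytest

from deamscan.syndata import ReferenceGenome, generate_reference


@pytest.fixture(scope="session")
def small_ref() -> ReferenceGenome:
    """2 kb linear reference used by placement tests."""
    return generate_reference(2000, 0.5, seed=101, ref_id="small", circular=False)


@pytest.fixture(scope="session")
def circ_ref() -> ReferenceGenome:
    """5 kb circular reference used by pipeline-level tests."""
    return generate_reference(5000, 0.5, seed=102, ref_id="circ", circular=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
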
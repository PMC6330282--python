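import numpy as np
import pytest

from petmrac.phantom import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def micro_spec():
    return PhantomSpec.micro(seed=11)


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_case(PhantomSpec.micro(seed=11, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_case():
    return generate_case(PhantomSpec.micro(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
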
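import numpy as np
import pytest

from bowelperf.synthetic import make_template_bank


@pytest.fixture(scope="session")
def template_bank():
    return make_template_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
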
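import numpy as np
import pytest

import formica as fm
from formica.optimization import Stage1Genome


@pytest.fixture(scope="session")
def body():
    return fm.build_body()


@pytest.fixture(scope="session")
def reference_gait(body):
    return fm.generate_reference_gait(fm.GaitSpec(), n_cycles=1, body=body)


@pytest.fixture(scope="session")
def default_actuation():
    """(bias, muscles) expanded from the default stage-I genome."""
    return Stage1Genome.defaults().expand()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
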
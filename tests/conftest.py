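import numpy as np
import pytest

import spinegraph as sg


@pytest.fixture(scope="session")
def schema19():
    return sg.build_schema()


@pytest.fixture(scope="session")
def graph19():
    return sg.full_graph()


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic default-size phantom (volume, labelmap)."""
    return sg.generate_phantom(sg.PhantomSpec(), seed=11)


@pytest.fixture(scope="session")
def phantom_cfg():
    return sg.PreprocessConfig.phantom_scale()
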
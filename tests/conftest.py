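import numpy as np
import pytest

import fetalmn as f


@pytest.fixture(scope="session")
def wt_model():
    return f.build_canonical_mn("WT")


@pytest.fixture(scope="session")
def sod_model():
    return f.build_canonical_mn("SOD")


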
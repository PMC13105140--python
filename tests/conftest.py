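import numpy as np
import pytest

from precvax.synth import make_reference_lists
from precvax.tcr import build_reference_panel


@pytest.fixture(scope="session")
def reference_lists():
    """Well-separated synthetic spike/CEF reference CDR3 lists."""
    return make_reference_lists(seed=3)


@pytest.fixture(scope="session")
def reference_panel(reference_lists):
    return build_reference_panel(reference_lists["spike"], reference_lists["cef"])


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(12345))
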
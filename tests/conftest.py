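import io

import numpy as np
import pytest
from skbio import TreeNode

from denitcath.io import load_reference_periods


@pytest.fixture(scope="session")
def reference_periods():
    """The three packaged operating periods, keyed by period id."""
    return {p.period_id: p for p in load_reference_periods()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20131)


@pytest.fixture()
def balanced_four_tip_tree():
    return TreeNode.read(io.StringIO("((a:1.0,b:1.0):1.0,(c:1.0,d:1.0):1.0);"))
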
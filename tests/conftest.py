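import numpy as np
import pytest

import gliaquant as gq


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def default_stack():
    """One full-size default stack with its ground truth (shared, read-only)."""
    params = gq.StackSimParams(engulfed_fraction=0.2)
    return gq.generate_stack(params, 42)


@pytest.fixture(scope="session")
def default_segmentation(default_stack):
    stack, _ = default_stack
    return gq.segment_stack(stack)


@pytest.fixture(scope="session")
def tiny_base():
    """Small, fast stack parameters for cohort-shape tests."""
    return gq.StackSimParams(shape_zyx=(16, 64, 64))
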
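import numpy as np
import pytest

from microbeat import SplitSpec, make_dataset, split_dataset, train


@pytest.fixture(scope="session")
def default_task():
    """The default synthetic benchmark: 200 beats/class, full separation."""
    ds = make_dataset((200, 200, 200), separation=1.0, seed=0)
    return split_dataset(ds, SplitSpec(seed=0))


@pytest.fixture(scope="session")
def trained_default(default_task):
    """One fully trained ensemble on the default task (seed 0)."""
    tr, va, te = default_task
    model, log = train(tr, va, seed=0)
    return model, log, te


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
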
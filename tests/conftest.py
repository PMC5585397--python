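import numpy as np
import pytest

import cylcond as cc


@pytest.fixture(scope="session")
def small_chain():
    """A short but real chain on a 5-ion cell, shared across tests.

    resync is disabled so the cached energy accumulates pure move deltas,
    which the cached-consistency test relies on.
    """
    model = cc.CellModel.from_alpha(5, 1.5, 1.0, 6.0)
    run = cc.RunConfig(seed=7, n_equil=500, n_prod=10_000, sample_stride=10,
                       resync_every=0, store_positions=True)
    return model, run, cc.run_chain(model, run)


@pytest.fixture(scope="session")
def rng():
    return np.random.Generator(np.random.Philox(987654321))
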
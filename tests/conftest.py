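import numpy as np
import pytest

from poremsm import synthetic


@pytest.fixture(scope="session")
def coupled_spec():
    """Study-condition coupled chain: 75:1 Down pinched:open design."""
    return synthetic.default_coupled_chain_spec()


@pytest.fixture(scope="session")
def coupled_chain_1m(coupled_spec):
    """One long (10^6 step) realization shared across conditional tests."""
    return synthetic.gen_coupled_chain(coupled_spec, 1_000_000, seed=3)


@pytest.fixture(scope="session")
def coupled_chain_labels(coupled_spec, coupled_chain_1m):
    macro = np.asarray([coupled_spec.macro_labels[i]
                        for i in coupled_chain_1m.macro])
    sf = np.asarray([coupled_spec.sf_labels[i]
                     for i in coupled_chain_1m.sf])
    return macro, sf
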
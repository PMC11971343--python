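import numpy as np
import pytest

from dynacomplex.synth import make_tumbling_vectors


@pytest.fixture(scope="session")
def tumbling_5ns():
    """Isotropic-tumbling fixture: tau_c = 5 ns, dt = 100 ps (= tau_c/50,
    the coarsest step the generator allows), 500k steps = 10,000 tau_c."""
    return make_tumbling_vectors(tau_c=5.0, dt=100.0, n_steps=500_000,
                                 n_residues=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
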
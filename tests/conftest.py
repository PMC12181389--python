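import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, well-separated synthetic dataset shared by slower tests."""
    from qtremor import synthdata as sd

    return sd.generate_dataset(40, params=sd.SignalParams.well_separated(), seed=7)


def random_state(rng, n_qubits):
    """A random normalised statevector."""
    from qtremor.qcore import Statevector

    amps = rng.normal(size=2**n_qubits) + 1j * rng.normal(size=2**n_qubits)
    return Statevector(n_qubits, amps / np.linalg.norm(amps))
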
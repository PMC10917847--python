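import numpy as np
import pytest

from adexmf import ModelParams, default_transfer_functions, generate_synthetic_connectome
from adexmf.network import RateTimeSeries


@pytest.fixture(scope="session")
def tfs():
    return default_transfer_functions()


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_connectome():
    return generate_synthetic_connectome(6, density=1.0, seed=42)


def make_series(nu_e, dt=0.1, config=None):
    """RateTimeSeries from an (n_samples, n_nodes) excitatory-rate array."""
    nu_e = np.atleast_2d(np.asarray(nu_e, dtype=float))
    if nu_e.shape[0] < nu_e.shape[1] and nu_e.ndim == 2 and nu_e.shape[0] == 1:
        nu_e = nu_e.T
    n_samples, n_nodes = nu_e.shape
    zeros = np.zeros_like(nu_e)
    return RateTimeSeries(
        times=np.arange(1, n_samples + 1) * dt,
        nu_e=nu_e,
        nu_i=zeros.copy(),
        c_ee=zeros.copy(),
        c_ei=zeros.copy(),
        c_ii=zeros.copy(),
        W_e=zeros.copy(),
        W_i=zeros.copy(),
        dt=dt,
        config=config or {},
    )
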
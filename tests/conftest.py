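import numpy as np
import pytest

from imcoal.model import ModelParameters


@pytest.fixture(scope="session")
def canonical_params() -> ModelParameters:
    """The package's documented validation parameter set (~1 and ~3 Myr
    splits at 1e-9 substitutions/bp/year, N_e = 25,000 at 20 yr/gen,
    0.8 cM/Mb, moderate gene flow)."""
    return ModelParameters(tau1=0.001, tau2=0.003, coal_rate=1000.0, rec_rate=0.4, mig_rate=250.0)


@pytest.fixture(scope="session")
def short_epoch_params() -> ModelParameters:
    """A short, strong gene-flow window (used for Monte-Carlo oracles)."""
    return ModelParameters(tau1=0.0005, tau2=0.001, coal_rate=1000.0, rec_rate=0.4, mig_rate=250.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20241001)
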
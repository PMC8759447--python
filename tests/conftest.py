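import numpy as np
import pytest

from baskborrow import AnalysisConfig, MCMCSettings, SCENARIOS, generate_trial


@pytest.fixture(scope="session")
def reduced_config():
    """Short-chain MCMC profile shared across the suite."""
    return AnalysisConfig.reduced()


@pytest.fixture(scope="session")
def fast_config():
    """Very short chains for plumbing tests where accuracy is irrelevant."""
    return AnalysisConfig(mcmc=MCMCSettings(chains=2, iterations=800, burn_in=200))


@pytest.fixture(scope="session")
def null_trial():
    """One global-null basket trial (K=6, n = 10,10,14,16,20,20)."""
    return generate_trial(SCENARIOS[9], seed=20_200_507)


@pytest.fixture(scope="session")
def effect_trial():
    """One consistent-effect trial (all theta_k = 0.45)."""
    return generate_trial(SCENARIOS[5], seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
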
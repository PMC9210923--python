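import numpy as np
import pytest

from permfdr.core import EstimationConfig, PermutationEnsemble, PValueVector, ThresholdGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20220613)


@pytest.fixture
def grid():
    """The standard 41-point grid, -log10(p) = 2.0 ... 6.0 by 0.1."""
    return ThresholdGrid.from_neg_log10()


@pytest.fixture
def uniform_inputs(rng):
    """Observed and permutation p-values all drawn from the uniform null."""
    m, n_perm = 2000, 20
    obs = PValueVector(rng.uniform(size=m))
    ens = PermutationEnsemble.from_pvalues(rng.uniform(size=(n_perm, m)))
    return obs, ens


@pytest.fixture
def default_config():
    return EstimationConfig()
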
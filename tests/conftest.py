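import numpy as np
import pytest

from afcomb.core import PermutationDraws
from afcomb.scenarios import ScenarioConfig, generate_scenario


@pytest.fixture
def small_dataset():
    """A small scenario-2 dataset with a real effect, for permutation tests."""
    cfg = ScenarioConfig(scenario=2, n=120, K=8, maf=0.3, beta=0.4, seed=42)
    Y, x = generate_scenario(cfg)
    return Y, x


def manual_draws(Y, x, B, seed):
    """Permutation draws built by an explicit per-permutation loop.

    Independent of the vectorized chunked path in afcomb.core: each shuffle
    is a plain rng.permutation of the genotype index and each correlation a
    direct np.corrcoef call.
    """
    rng = np.random.default_rng(seed)
    n, K = Y.shape
    r_obs = np.array([np.corrcoef(Y[:, k], x)[0, 1] for k in range(K)])
    null_r = np.empty((B, K))
    for b in range(B):
        xp = x[rng.permutation(n)]
        null_r[b] = [np.corrcoef(Y[:, k], xp)[0, 1] for k in range(K)]
    return PermutationDraws(n=n, r_obs=r_obs, null_r=null_r, seed=seed)
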
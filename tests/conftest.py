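import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ratediv.synthetic_data import BGSGeneratorConfig, GeneratorConfig
from ratediv.tree_stats import two_way_poisson_loglik


@pytest.fixture(scope="session")
def small_tree_config():
    """Reduced-scale tree generator: enough genes/branches for recovery."""
    return GeneratorConfig(seed=5, n_genes=500, n_branches=50)


@pytest.fixture(scope="session")
def rates_14k():
    """Lognormal long-term rates at the study's gene-count scale."""
    rng = np.random.default_rng(99)
    return rng.lognormal(np.log(0.03), 0.7, 14000)


def numeric_two_way_mle(scaled_lengths: pd.DataFrame, lengths: dict, restarts: int = 6):
    """Independent oracle: constrained Poisson-likelihood maximization.

    Unconstrained reparameterization with the first gene/branch coordinates
    pinned (the normalizations make them redundant), Nelder-Mead with
    restarts until the optimum stops moving. Returns (alpha, beta, c) in the
    row/column order of the matrix.
    """
    N, M = scaled_lengths.shape
    Lv = np.array([float(lengths[g]) for g in scaled_lengths.index])

    def unpack(p):
        a = np.exp(np.concatenate([[0.0], p[: N - 1]]))
        a = a / (Lv * a).sum()
        b = np.exp(np.concatenate([[0.0], p[N - 1 : N + M - 2]]))
        b = b / b.sum()
        return a, b, float(np.exp(p[N + M - 2]))

    def negll(p):
        a, b, c = unpack(p)
        return -two_way_poisson_loglik(scaled_lengths, lengths, c, a, b)

    x = np.zeros(N + M - 1)
    f = np.inf
    for i in range(restarts):
        res = optimize.minimize(
            negll, x,
            method="Nelder-Mead",
            options={"maxiter": 20000, "maxfev": 20000, "xatol": 1e-13, "fatol": 1e-13},
        )
        if i > 0 and f - res.fun < 1e-12:
            x, f = res.x, res.fun
            break
        x, f = res.x, res.fun
    return unpack(x)
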
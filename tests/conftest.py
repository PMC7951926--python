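import warnings

import numpy as np
import pandas as pd
import pytest

import arealrisk as ar

# arviz emits a refactor FutureWarning on import/use; irrelevant here
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced study-scale scenario shared by slower tests."""
    lattice, cov, panel, truth = ar.paper_scale_scenario(seed=11, rows=4, cols=6)
    panel = ar.sir(ar.expected_counts(panel))
    return lattice, cov, panel, truth


@pytest.fixture
def path3():
    return ar.grid_lattice(1, 3)


def make_posterior(lp_draws, Y, E):
    """Posterior with fully controlled linear-predictor draws.

    ``lp_draws`` has shape (S, n, T); it is injected through the delta
    draws with everything else zeroed, so ``linear_predictor()``
    returns it exactly.  Used to unit-test summaries and criteria
    without running MCMC.
    """
    lp = np.asarray(lp_draws, dtype=float)
    S, n, T = lp.shape
    spec = ar.ModelSpec(spatial_family="none", interaction=True, covariates=())
    return ar.Posterior(
        draws={
            "alpha_c": np.zeros((1, S)),
            "beta": np.zeros((1, S, 0)),
            "phi": np.zeros((1, S, n)),
            "delta": lp[None, :, :, :],
        },
        area_ids=tuple(f"a{i}" for i in range(n)),
        years=tuple(2015 + t for t in range(T)),
        covariates=(),
        X=np.zeros((n, T, 0)),
        xbar=np.zeros(0),
        Y=np.asarray(Y, dtype=float).reshape(n, T),
        E=np.asarray(E, dtype=float).reshape(n, T),
        spec=spec,
        seed=0,
        chains=1,
    )


@pytest.fixture
def posterior_factory():
    return make_posterior
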
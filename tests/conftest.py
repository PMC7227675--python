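import numpy as np
import pytest

import garpselect as g


@pytest.fixture(scope="session")
def grid_small():
    """Small desk grid: 40x40 cells, 0.25 deg, same 10-degree-ish extent."""
    return g.GridSpec(n_rows=40, n_cols=40, resolution=0.25, origin_x=1.0, origin_y=1.0)


@pytest.fixture(scope="session")
def land_small(grid_small):
    """Six autocorrelated covariates on the small grid."""
    return g.simulate_landscape(grid_small, n_exponential=3, n_spherical=3, seed=5)


@pytest.fixture(scope="session")
def separable_species(land_small):
    """A toy species perfectly separable by one covariate envelope.

    Present exactly where cov01 lies between its 55th and 95th percentile
    on the landscape; 50 presence points sampled from the presence cells.
    """
    x = land_small["cov01"]
    lo, hi = np.quantile(x, 0.55), np.quantile(x, 0.95)
    realized = ((x >= lo) & (x <= hi)).astype(np.int8)
    presences = g.sample_presences(realized, land_small.grid, 50, seed=17)
    return {"realized": realized, "presences": presences, "lo": lo, "hi": hi,
            "variable": "cov01"}


@pytest.fixture(scope="session")
def separable_experiment(land_small, separable_species):
    """A small multi-model experiment on the separable toy species."""
    return g.run_experiment(
        separable_species["presences"], land_small,
        n_models=12, seed=3, max_iter=60,
    )


@pytest.fixture(scope="session")
def separable_best(separable_experiment):
    return g.best_subset(separable_experiment, n_low_omission=12, n_best=6)
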
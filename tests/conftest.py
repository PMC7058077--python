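import warnings

import numpy as np
import pytest

import trajde


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def bif_sim():
    """Small bifurcating data set with DE truth."""
    return trajde.simulate_trajectory(
        "bifurcating", n_cells=250, n_genes=80, prop_de=0.25, seed=11
    )


@pytest.fixture(scope="session")
def bif_model(bif_sim):
    data, _ = bif_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return trajde.NBSplineGAM(seed=3).fit(data)


@pytest.fixture(scope="session")
def flat_single():
    """Flat-truth single-lineage counts (null genes) and their fit."""
    rng = np.random.default_rng(0)
    n, G = 250, 120
    t = rng.uniform(0, 1, n)
    mu = 10.0 * np.ones((G, n))
    counts = rng.poisson(rng.gamma(2.0, mu * 0.5))
    data = trajde.validate_trajectory_data(counts, t[:, None], np.ones((n, 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = trajde.NBSplineGAM(seed=0).fit(data)
    return data, model
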
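import numpy as np
import pytest

import ioglmhmm as ig


@pytest.fixture(scope="session")
def feature_config():
    return ig.default_feature_config()


@pytest.fixture(scope="session")
def small_sim(feature_config):
    """A small 2-state simulated dataset shared across tests.

    10 sessions x 200 trials from the input-driven K=2 template.
    Returns (data, truth, designs, contrast_sd).
    """
    task = ig.generate_task(ig.TaskConfig(n_sessions=10, trials_per_session=200), seed=7)
    data, truth = ig.simulate_agent(task, ig.default_params(2), feature_config, seed=8)
    designs, sd = ig.prepare_designs(data, ig.FeatureConfig())
    return data, truth, designs, sd


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """One converged 2-state EM fit on the shared dataset."""
    _, _, designs, _ = small_sim
    return ig.fit_with_restarts(designs, 2, n_restarts=2, seed=3,
                                max_iters=150, tol=1e-3)


def random_instance(rng, T, K, D_ob=3, D_tr=2):
    """A random small model + data instance for oracle comparisons."""
    pi = rng.dirichlet(np.ones(K))
    params = ig.ModelParams(
        pi=pi,
        W_ob=rng.normal(size=(K, D_ob)),
        W_tr=rng.normal(size=(K, D_tr)),
        B=rng.normal(size=(K, K)),
    )
    X_ob = rng.normal(size=(T, D_ob))
    X_tr = rng.normal(size=(T, D_tr))
    y = rng.integers(0, 2, size=T)
    return params, X_ob, X_tr, y
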
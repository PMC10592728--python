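import warnings

import numpy as np
import pytest

from timeskip.io import make_fixtures
from timeskip.model import init_network
from timeskip.tasks import generate_trial


@pytest.fixture(scope="session")
def bundle():
    """Deterministic tiny fixture bundle (4-unit net, go trial, episode)."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_net():
    """8-unit contractive network with zero noise for exact checks."""
    return init_network(8, 65, 33, seed=42, sigma_noise=0.0)


@pytest.fixture(scope="session")
def desk_go_trial():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_trial(
            "go", 7, timing_overrides={"fix": 40, "stim": 60, "resp": 100}
        )


@pytest.fixture(scope="session")
def trained_go_cohort():
    """A small cohort actually trained on the desk go task.

    Session-scoped because training takes tens of seconds; reused by the
    training-invariant and discrepancy-analysis tests.
    """
    from timeskip.training import desk_preset, train_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = desk_preset(
            "go", "base", cohort_size=4, max_training_steps=800,
            eval_every=100, seed_base=11,
        )
        result = train_cohort(cfg)
    return cfg, result


def _pure_leak(n_units, tau, n_inputs, n_outputs):
    """Zero-weight, zero-bias network: dynamics reduce to the leak."""
    from timeskip.model import NetworkParams

    return NetworkParams(
        n_units=n_units,
        W_rec=np.zeros((n_units, n_units)),
        W_inp=np.zeros((n_units, n_inputs)),
        W_out=np.zeros((n_outputs, n_units)),
        b=np.zeros(n_units),
        tau=np.full(n_units, tau),
        sigma_noise=0.0,
    )


@pytest.fixture()
def leak_net():
    return _pure_leak(3, 100.0, 2, 2)
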
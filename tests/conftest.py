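import numpy as np
import pandas as pd
import pytest

from avci import ObserverParams, generate_design, simulate_participant


@pytest.fixture(scope="session")
def default_params():
    return ObserverParams(p_common=0.5, sigma_p=12.0, sigma_a=6.0, sigma_v=1.5)


@pytest.fixture(scope="session")
def small_trials():
    """One clean synthetic participant under BCI (648 trials)."""
    params = {
        "communicative": ObserverParams(p_common=0.7, sigma_p=12.0, sigma_a=4.0,
                                        sigma_v=2.5),
        "non-communicative": ObserverParams(p_common=0.4, sigma_p=12.0, sigma_a=5.0,
                                            sigma_v=2.5),
    }
    design = generate_design(seed=3)
    return simulate_participant(design, params, "bci", seed=4), params


def random_params(rng, architecture="bci"):
    """Random valid observer parameters for property tests."""
    return ObserverParams(
        p_common=float(rng.uniform(0.01, 0.99)),
        sigma_p=float(rng.uniform(1.0, 30.0)),
        sigma_a=float(rng.uniform(0.5, 15.0)),
        sigma_v=float(rng.uniform(0.5, 15.0)),
        k_c=float(rng.uniform(0.0, 20.0)),
        eta=float(rng.uniform(0.0, 1.0)),
    )
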
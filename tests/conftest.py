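import numpy as np
import pytest

from catlearn.simulate import SimConfig, simulate_behavior
from catlearn.stimuli import dense_grid, orientation_rule, sf_rule, standard_grid


@pytest.fixture(scope="session")
def grid36():
    return standard_grid()


@pytest.fixture(scope="session")
def grid49():
    return dense_grid()


@pytest.fixture(scope="session")
def ori_rule():
    return orientation_rule()


@pytest.fixture(scope="session")
def freq_rule():
    return sf_rule()


@pytest.fixture(scope="session")
def series():
    """A full simulated learning series T1-T8 with a rule switch."""
    from catlearn.simulate import default_learning_schedule, simulate_learning_series
    from catlearn.stimuli import sf_rule as _sf

    cfg = SimConfig(n_neurons=120, n_trials=250, seed=21)
    return simulate_learning_series(
        default_learning_schedule(orientation_rule(), _sf()), cfg
    )


@pytest.fixture(scope="session")
def trained_session(ori_rule):
    """A well-trained session on the full grid (d' 2.5, 400 trials)."""
    return simulate_behavior(ori_rule, 2.5, 400, seed=11)


def ideal_category_rates(rule, go_rate=1.0, nogo_rate=0.0):
    """Per-stimulus rates of an ideal category cell."""
    labels = rule.labels()
    return np.where(labels == "Go", go_rate, np.where(labels == "NoGo", nogo_rate, np.nan))
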
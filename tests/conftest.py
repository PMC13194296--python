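import numpy as np
import pytest

import therapyopt as t


@pytest.fixture
def fig_theta():
    """The single reference tumor used for illustration runs."""
    return t.ThetaTwoPop(1.5, 0.0, 0.66, 0.01, 0.5)


@pytest.fixture
def small_ensemble():
    return t.random_ensemble(3, seed=7, n0=0.5)


@pytest.fixture(scope="session")
def grid_ensembles():
    return {n0: t.prostate_grid_ensemble(n0) for n0 in (0.25, 0.50, 0.75)}


def random_admissible_control(rng, n_steps, step=t.DEFAULT_STEP):
    """Piecewise-constant admissible control with day-scale structure."""
    # draw a coarse profile and repeat it so the control is not pure noise
    coarse = rng.uniform(0.0, 1.0, size=max(1, n_steps // 8))
    values = np.repeat(coarse, 8)[:n_steps]
    if len(values) < n_steps:
        values = np.pad(values, (0, n_steps - len(values)), constant_values=values[-1])
    return t.ControlGrid.from_values(values, step)
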
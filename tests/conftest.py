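import numpy as np
import pytest

import stablegrid as sg


@pytest.fixture(scope="session")
def layout():
    return sg.default_farm_layout()


@pytest.fixture(scope="session")
def grid(layout):
    return sg.GridSpec.from_layout(layout)


@pytest.fixture(scope="session")
def label_grid(layout, grid):
    return sg.assign_label_grid(layout, grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210923)


@pytest.fixture(scope="session")
def small_sim(layout):
    """3 horses x 3 summer days with noise, spikes and dropouts."""
    cfg = sg.SimulationConfig(
        n_horses=3, n_days=3, summer_days=3, winter_days=0, n_newcomers=0,
        spike_prob=0.001, dropout_prob=0.02, rng_seed=101)
    metas = sg.make_herd(cfg)
    return sg.simulate_study(metas, layout, cfg), metas, cfg


@pytest.fixture(scope="session")
def small_filtered(small_sim, layout):
    result, metas, cfg = small_sim
    fixes, report = sg.apply_filter_cascade(result.fixes, layout)
    return fixes, report


@pytest.fixture(scope="session")
def spike_study(layout):
    """The spike-recovery dataset: 5 horses x 3 days, spike_prob 0.001."""
    cfg = sg.SimulationConfig(
        n_horses=5, n_days=3, summer_days=3, winter_days=0, n_newcomers=0,
        spike_prob=0.001, dropout_prob=0.0, rng_seed=42)
    metas = sg.make_herd(cfg)
    return sg.simulate_study(metas, layout, cfg), cfg
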
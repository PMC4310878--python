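"""Shared fixtures: country presets and pre-computed trajectories.

Simulations are deterministic, so expensive objects are session-scoped and
shared across test modules.
"""

import pytest

import bcscreen as bc
from bcscreen import presets


@pytest.fixture(scope="session")
def japan_params():
    return presets.natural_history_preset("japan")


@pytest.fixture(scope="session")
def japan_perf():
    return presets.performance_preset("japan")


@pytest.fixture(scope="session")
def us_params():
    return presets.natural_history_preset("us")


@pytest.fixture(scope="session")
def us_perf():
    return presets.performance_preset("us")


@pytest.fixture(scope="session")
def japan_baseline(japan_params, japan_perf):
    """No-screening Japan trajectory, 100 000 women."""
    return bc.simulate(japan_params, japan_perf, None)


@pytest.fixture(scope="session")
def japan_biennial_40_69(japan_params, japan_perf):
    strat = bc.ScreeningStrategy.make(40, 69, 2, 1.0)
    return bc.simulate(japan_params, japan_perf, strat)


@pytest.fixture(scope="session")
def japan_annual_40_69(japan_params, japan_perf):
    strat = bc.ScreeningStrategy.make(40, 69, 1, 1.0)
    return bc.simulate(japan_params, japan_perf, strat)


@pytest.fixture(scope="session")
def japan_small_grid(japan_params, japan_perf):
    """2 intervals x 2 starts x 3 stops grid on the Japan fixture."""
    spec = bc.GridSpec(params=japan_params, performance=japan_perf,
                       start_ages=(40, 50), stop_ages=(69, 74, 79),
                       intervals=(1, 2))
    return bc.run_grid(spec)
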
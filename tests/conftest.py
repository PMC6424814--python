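"""Shared fixtures: small synthetic stimuli and model populations."""

import numpy as np
import pytest

from dsmotion import (
    build_population,
    generate_smoothed_texture,
    generate_trajectory,
    simulate_motion_ln_cell,
    simulate_population,
)


@pytest.fixture(scope="session")
def trajectory_10min():
    return generate_trajectory(101, 18000)


@pytest.fixture(scope="session")
def trajectory_short():
    return generate_trajectory(102, 3000)


@pytest.fixture(scope="session")
def standard_texture():
    return generate_smoothed_texture(7, (3000.0, 3000.0))


@pytest.fixture(scope="session")
def exponential_cell():
    return build_population(1, nonlinearity_kind="exponential", seed=1)[0]


@pytest.fixture(scope="session")
def ushape_cell():
    return build_population(1, nonlinearity_kind="ushape", seed=1)[0]


@pytest.fixture(scope="session")
def exponential_counts(exponential_cell, trajectory_10min):
    sts = simulate_motion_ln_cell(exponential_cell, trajectory_10min, seed=11)
    return sts.counts[0, 0]


@pytest.fixture(scope="session")
def mixed_population(trajectory_10min):
    cells = build_population(3, nonlinearity_kind="exponential", seed=2)
    sts = simulate_population(cells, trajectory_10min, seed=12)
    return cells, sts.counts[:, 0, :]
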
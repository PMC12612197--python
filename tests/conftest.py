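import numpy as np
import pytest

from deepsdm import (ContaminationSpec, GridSpec, VirtualSpeciesSpec,
                     generate_effort_bias, generate_env_stack)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """A 30×30 grid inside the study window."""
    return GridSpec(30, 30, 60.0, 72.0, -30.0, 0.0)


@pytest.fixture(scope="session")
def small_world(small_grid):
    """Stack + bathymetry + effort bias + one centred virtual species."""
    stack, bathy = generate_env_stack(small_grid, 3, smoothness=4.0, seed=11)
    effort = generate_effort_bias(small_grid, seed=12)
    species = VirtualSpeciesSpec(
        "Testus virtualis",
        {c: 0.0 for c in stack.names},
        {c: 1.0 for c in stack.names},
    )
    return stack, bathy, effort, species


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
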
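import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bindkin as bk

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_mixed_params():
    """Linear mixed inhibition truth (CDNB-like assay scale)."""
    return bk.KineticParameters(Vmax=100.0, Km=100.0, Ki=3.67, Ki_prime=4.97, b=0.0)


@pytest.fixture
def partial_mixed_params():
    """Partial (hyperbolic) mixed inhibition truth."""
    return bk.KineticParameters(Vmax=100.0, Km=100.0, Ki=3.69, Ki_prime=1.45, b=0.3)


def noiseless_kinetics(params, substrate_grid=None, inhibitor_grid=None):
    spec_kwargs = dict(params=params, noise_cv=0.0, replicates=1, seed=0)
    if substrate_grid is not None:
        spec_kwargs["substrate_grid"] = substrate_grid
    if inhibitor_grid is not None:
        spec_kwargs["inhibitor_grid"] = inhibitor_grid
    return bk.gen_kinetic_data(bk.KineticGeneratorSpec(**spec_kwargs))


@pytest.fixture
def toy_trajectory_small():
    traj, manifest = bk.gen_toy_trajectory(
        bk.TrajectoryGeneratorSpec(sigma=0.1, p_hbond=1.0, frames=20, seed=7)
    )
    return traj, manifest
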
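import dataclasses

import numpy as np
import pytest

import lambold as lb


@pytest.fixture(scope="session")
def protocol7():
    return lb.make_default_protocol(7)


@pytest.fixture(scope="session")
def tissue7():
    return lb.make_default_tissue(7)


@pytest.fixture(scope="session")
def tissue7_v0(tissue7):
    """7 T tissue with the venous compartment removed (pure mono-exponential)."""
    return dataclasses.replace(tissue7, venous_fraction=tuple([0.0] * tissue7.depth_bins))


@pytest.fixture(scope="session")
def grid_small():
    return lb.make_default_grid(n_voxels=110)


@pytest.fixture(scope="session")
def noiseless_ts7(protocol7, tissue7_v0, grid_small):
    return lb.simulate_timeseries(protocol7, tissue7_v0, lb.NoiseParams(seed=0), grid_small)


@pytest.fixture(scope="session")
def same_depth_grid():
    """Grid with every voxel at the mid-cortex bin (shared-noise algebra tests)."""
    n = 80
    return lb.VoxelGrid(
        n_voxels=n,
        depth_bin=tuple([8] * n),
        in_v1=tuple([True] * n),
        in_activation_mask=tuple([True] * n),
    )


def analytic_weisskoff_curve(n, sigma_p, sigma_t, s_bar=1.0):
    """Noise curve of the mixed model sqrt(p^2 + t^2 / i) / s_bar."""
    i = np.arange(1, n + 1)
    return np.sqrt(sigma_p**2 + sigma_t**2 / i) / s_bar
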
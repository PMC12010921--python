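import numpy as np
import pytest

from slsc import (
    ChannelData,
    CoherenceParams,
    LesionSpec,
    NoiseSpec,
    ProbeConfig,
    make_coherence_fixture,
    make_phantom,
    simulate_channel_data,
)


@pytest.fixture(scope="session")
def probe():
    return ProbeConfig()


@pytest.fixture(scope="session")
def small_probe():
    """16 receive elements, 8 lines: cheap fixture for estimator tests."""
    return ProbeConfig(n_elements_total=32, n_receive=16, n_scanlines=8)


def aligned_from_array(x: np.ndarray, probe: ProbeConfig) -> ChannelData:
    """Wrap an (n_samples, n_elements, n_lines) array as aligned channel data."""
    depth = (np.arange(x.shape[0]) + 1) * probe.axial_sample_mm
    return ChannelData(
        rf=x, probe=probe, focus_depth_mm=float(depth[len(depth) // 2]),
        aligned=True, depth_grid_mm=depth,
    )


@pytest.fixture(scope="session")
def speckle_fixture(small_probe):
    """Bandlimited random speckle-like aligned data, 16 elements x 8 lines."""
    rng = np.random.default_rng(42)
    cols = []
    for line in range(small_probe.n_scanlines):
        fx = make_coherence_fixture(
            1.0 - np.arange(16) / 16.0, n_elements=16, n_samples=200,
            seed=100 + line, probe=small_probe,
        )
        cols.append(fx.rf[:, :, 0])
    return aligned_from_array(np.stack(cols, axis=2), small_probe)


@pytest.fixture(scope="session")
def lesion_acquisition(probe):
    """One fluid-lesion acquisition with default noise, shared across tests."""
    lesion = LesionSpec((0.0, 16.0), (3.0, 2.0), "fluid", 0.0)
    phantom = make_phantom(probe, [lesion], density=10, seed=7)
    data = simulate_channel_data(phantom, probe, 16.0, NoiseSpec(10.0, -14.0), seed=8)
    return lesion, data
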
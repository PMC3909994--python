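import numpy as np
import pytest

from neuroentropy.config import GeneratorConfig
from neuroentropy.io import RegionTimeSeries, VoxelTimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A light-weight generator configuration for fast unit tests."""
    return GeneratorConfig(
        n_networks=2, voxels_per_network=5, n_timepoints=120,
        infusion_onset=60, infusion_duration=10, seed=7,
    )


@pytest.fixture
def voxel_dataset(rng):
    """A small hand-constructed labeled voxel dataset."""
    data = rng.standard_normal((6, 80))
    labels = ["net-a"] * 3 + ["net-b"] * 3
    return VoxelTimeSeriesSet(data, np.array(labels), sampling_interval=2.0,
                              infusion_onset=40, infusion_duration=8)


@pytest.fixture
def region_series(rng):
    data = rng.standard_normal((4, 120))
    return RegionTimeSeries(
        region_names=["hip-l", "hip-r", "acc-l", "acc-r"], data=data,
        sampling_interval=3.0, infusion_onset=60, infusion_duration=10,
    )
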
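import numpy as np
import pytest

from fetadc import PhantomSpec, PipelineConfig, ScalarVolume


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture()
def noiseless_spec():
    """A quiet phantom: TBR 3.0 on SUV background 0.94, core ADC 1300."""
    return PhantomSpec(
        bg_suv_mean=0.94,
        bg_adc_mean=768.0,
        bg_suv_sd=0.0,
        bg_adc_sd=0.0,
        core_adc_sd=0.0,
        lesion_peak_suv=3.0 * 0.94,
        core_adc_mean=1300.0,
        seed=0,
    )


def make_volume(data, voxel_size=(1.0, 1.0, 1.0), modality="SUV", grid_id="test"):
    data = np.asarray(data, dtype=float)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    aff[:3, 3] = -(np.asarray(data.shape) - 1) / 2.0 * np.asarray(voxel_size)
    return ScalarVolume(data, aff, modality, grid_id=grid_id)


@pytest.fixture()
def blob_volume():
    """A single smooth hot blob (peak 10) on a constant background of 1."""
    shape = (24, 24, 16)
    idx = np.indices(shape, dtype=float)
    centre = np.array([12.0, 12.0, 8.0])
    r2 = sum((idx[a] - centre[a]) ** 2 for a in range(3))
    data = 1.0 + 9.0 * np.exp(-r2 / (2 * 3.0**2))
    return make_volume(data)
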
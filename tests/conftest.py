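import numpy as np
import pytest

from lightsweep.acquisition import CameraModel, ImagingGrid, OpticsModel, ScanWaveform
from lightsweep.phantom import (
    Box,
    CalciumEvent,
    DendriteConfig,
    FluorescenceField,
    make_dendrite,
)


@pytest.fixture(scope="session")
def small_optics():
    return OpticsModel(pixel_size=0.5)


@pytest.fixture(scope="session")
def small_camera():
    """Noiseless small-frame camera at the standard 20 ms / 50 Hz timing."""
    return CameraModel(
        exposure_ms=20.0, frame_shape=(40, 40), photon_scale=None,
        read_noise_sigma=0.0, substeps_per_exposure=8,
    )


@pytest.fixture(scope="session")
def meander_phantom():
    """40 µm-Z meandering dendrite, deeper than the 20 µm sweep."""
    cfg = DendriteConfig(length=50.0, z_span=40.0, radius=1.0, smoothness=8.0)
    return make_dendrite(cfg, seed=11)


@pytest.fixture(scope="session")
def flat_phantom():
    """Planar dendrite confined to z = 0."""
    cfg = DendriteConfig(length=30.0, z_span=0.0, radius=1.0, smoothness=8.0)
    return make_dendrite(cfg, seed=5)


@pytest.fixture(scope="session")
def one_event(meander_phantom):
    s0 = meander_phantom.total_length / 2.0
    return CalciumEvent(
        origin_arclength=s0, onset_time=1.0, peak_dff=0.8,
        rise_decay_c=8.0, spread_length=5.0, propagation_delay=0.005,
    )


@pytest.fixture(scope="session")
def event_field(meander_phantom, one_event):
    return FluorescenceField(meander_phantom, [one_event])


@pytest.fixture(scope="session")
def quiet_field(flat_phantom):
    return FluorescenceField(flat_phantom, [])


def make_sweep(depth_pp=20.0, frequency=50.0, center_z=0.0, phase=0.0):
    return ScanWaveform(frequency=frequency, amplitude=depth_pp / 2.0,
                        center_z=center_z, phase=phase)


@pytest.fixture(scope="session")
def sweep_waveform():
    return make_sweep()
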
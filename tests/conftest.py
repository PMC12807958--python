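import numpy as np
import pytest

from csmprage.phantom import (AcquisitionParams, apply_sampling_mask,
                              make_bias_field, make_coils, make_phantom,
                              noise_sd_for_target_snr, simulate_kspace)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom((64, 64, 64), 4, seed=1)


@pytest.fixture(scope="session")
def coils64(phantom64):
    return make_coils(phantom64.shape, 4, seed=2, width=0.35 * 64)


@pytest.fixture(scope="session")
def bias64(phantom64):
    return make_bias_field(phantom64.shape, 0.2, seed=3,
                           brain_mask=phantom64.brain_mask())


@pytest.fixture(scope="session")
def noisy_kspace64(phantom64, coils64, bias64):
    """Noisy multi-coil k-space at the default target WM SNR."""
    sd = noise_sd_for_target_snr(phantom64, 18.0)
    params = AcquisitionParams(matrix=phantom64.shape, noise_sd=sd,
                               turbo_factor=64, seed=11)
    return simulate_kspace(phantom64, coils64, bias64, params)


@pytest.fixture(scope="session")
def clean_kspace64(phantom64, coils64, bias64):
    params = AcquisitionParams(matrix=phantom64.shape, noise_sd=0.0,
                               turbo_factor=64, seed=11)
    return simulate_kspace(phantom64, coils64, bias64, params)
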
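import numpy as np
import pytest

from ppsfkit import synth


@pytest.fixture(scope="session")
def small_acq() -> synth.AcquisitionSpec:
    """Noiseless, small-frame acquisition for fast movie rendering."""
    return synth.AcquisitionSpec(
        frame_shape=(48, 48), photon_noise_scale=0.0, read_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def short_protocol() -> synth.StimProtocol:
    """Full 9-offset sweep with the minimum-compatible 4 s trial period."""
    return synth.StimProtocol(inter_trial=4.0)


@pytest.fixture(scope="session")
def centered_cell() -> synth.CellSpec:
    return synth.CellSpec(center=(30.0, 30.0, 0.0), diameter=15.0)


@pytest.fixture(scope="session")
def noiseless_experiment(small_acq, short_protocol, centered_cell):
    """One rendered noiseless experiment shared by the movie-level tests."""
    movie, sync, truth = synth.simulate_experiment(
        [centered_cell], short_protocol, small_acq, synth.LARGE_OPSF, seed=11
    )
    mask = synth.cell_masks([centered_cell], small_acq) == 1
    return movie, sync, truth, mask


def gaussian(z, fwhm):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * (np.asarray(z) / sigma) ** 2)
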
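import numpy as np
import pytest

from quantalglu import (
    ImagingModel,
    Kernel,
    ReleaseModel,
    make_stimulus,
    render_linescan,
    simulate_release,
)


@pytest.fixture(scope="session")
def kernel():
    return Kernel()  # tau_r 1 ms, tau_f 60 ms


@pytest.fixture(scope="session")
def protocol11():
    """Eleven equiprobable contrasts spanning C1/2 +/- 10% at 5 Hz."""
    return make_stimulus(np.linspace(40, 60, 11), frequency=5.0, repeats=10, seed=0)


@pytest.fixture(scope="session")
def mvr_model():
    return ReleaseModel(
        base_rate=2.0,
        rate_gain=0.05,
        quantal_amplitude=1.0,
        mvr_weights={1: 0.5, 2: 0.3, 3: 0.2},
        amplitude_cv=0.1,
    )


@pytest.fixture(scope="session")
def noisy_recording(protocol11, mvr_model, kernel):
    """A 22-s noisy, bleaching recording with attached ground truth."""
    truth = simulate_release(protocol11, mvr_model, seed=2, min_separation=0.18)
    imaging = ImagingModel(noise_sd=0.1, bleach_slope=0.005)
    return render_linescan(
        truth,
        kernel,
        imaging,
        duration=protocol11.duration,
        seed=3,
        release_model=mvr_model,
    )
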
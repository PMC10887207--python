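import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from pwvkit.synthwave import BeatKernel, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def kernel_argmax() -> float:
    """Continuous-time argmax of the default beat kernel (independent oracle)."""
    kernel = BeatKernel()
    res = minimize_scalar(
        lambda t: -float(kernel(np.array([t]))[0]),
        bounds=(0.05, 0.30),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


@pytest.fixture(scope="session")
def t1_bundle():
    """The 19 s contaminated recording used by the fidelity/spectral criteria.

    10 kHz reference plus the 250 Hz acquisition formed by taking every 40th
    sample of each channel.
    """
    from pwvkit.dspcore import TimeSeries

    config = SynthConfig(
        duration=19.0,
        heart_rate_bpm=75.0,
        ibi_jitter_sd=0.03,
        ptt_true=0.008,
        white_sd=0.02,
        mains_amps=(0.05,),
        seed=1,
    )
    reference = generate_recording(config, 10_000.0)
    acquired = {
        name: TimeSeries(ch.samples[::40], 250.0, ch.start_time)
        for name, ch in (("prox", reference.prox), ("dist", reference.dist))
    }
    return config, reference, acquired
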
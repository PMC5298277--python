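import numpy as np
import pytest
from hypothesis import settings

import casbdr as cb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

PIPELINE_RATE = 3125.0


@pytest.fixture(scope="session")
def rate():
    return PIPELINE_RATE


@pytest.fixture(scope="session")
def tone_phase(rate):
    """One inspiration-like segment with a known 500 Hz pure-tone CAS.

    Shared by detection/segmentation tests: (signal, flow, injected spec).
    """
    dur_ph = 1.4
    n = int(dur_ph * rate)
    t = np.arange(n) / rate
    flow = np.sin(np.pi * t / dur_ph) ** 2
    normal = cb.generate_normal_sound(flow, seed=2, rate_hz=rate)
    spec = cb.SynthCASSpec(onset_s=0.5, duration_s=0.4, pitch_hz=500.0,
                           snr_db=12.0)
    sig = cb.inject_cas(normal, spec, normal**2, rate_hz=rate,
                        harmonic_db=-np.inf)
    return sig, flow, spec


@pytest.fixture(scope="session")
def tone_modes(tone_phase, rate):
    """EEMD modes (with IF/IE) of the shared tone segment."""
    sig, _flow, _spec = tone_phase
    modes, residue = cb.eemd(sig, ensemble_size=30, seed=3)
    cb.attach_instantaneous(modes, rate)
    return modes, residue


@pytest.fixture(scope="session")
def tone_spectrum(tone_modes, rate):
    modes, _ = tone_modes
    return cb.build_spectrum(modes, rate)
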
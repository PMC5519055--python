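import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from usvdetect import Recording, SynthSpec, generate_recording

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def make_tone():
    """Factory for simple sinusoid (plus optional white noise) recordings."""

    def _make(
        freq_hz: float = 50_000.0,
        duration_s: float = 1.0,
        sample_rate: int = 300_000,
        amp: float = 0.1,
        noise_rms: float = 0.0,
        seed: int = 0,
    ) -> Recording:
        t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
        x = amp * np.sin(2 * np.pi * freq_hz * t)
        if noise_rms > 0:
            x = x + np.random.default_rng(seed).normal(0.0, noise_rms, t.size)
        return Recording(samples=np.clip(x, -1.0, 1.0), sample_rate=sample_rate)

    return _make


@pytest.fixture(scope="session")
def small_synth():
    """12-second synthetic recording with 10 syllables at 20 dB SNR.

    Ten syllables averaging ~60 ms in 12 s is a ~5% signal duty, typical of
    a steadily calling mouse and inside the detector's design envelope.
    """
    spec = SynthSpec(duration_s=12.0, n_syllables=10, snr_db=20.0, seed=42)
    return generate_recording(spec)
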
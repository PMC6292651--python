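import numpy as np
import pytest

from modmatch.audio import AudioSignal
from modmatch.presets import AnalysisConfig, desk_scale_analysis


@pytest.fixture(scope="session")
def desk_analysis() -> AnalysisConfig:
    return desk_scale_analysis()


@pytest.fixture(scope="session")
def tiny_analysis() -> AnalysisConfig:
    """A very small configuration for fast structural tests."""
    return AnalysisConfig(
        sample_rate=2000.0, n_filters=20, f_lo=20.0, f_hi=1000.0,
        env_sample_rate=50.0, cycles_per_octave=12.0,
        rates=(2.0, 4.0, 8.0), low_rates=(1.0,), scales=(1.0, 2.0),
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def broadband_signal(desk_analysis, rng) -> AudioSignal:
    """Two seconds of broadband noise restricted to the analysis band.

    White noise band-limited to 30-1900 Hz so that essentially all of its
    energy falls inside the cochlear filter bank's passband.
    """
    n = int(2.0 * desk_analysis.sample_rate)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / desk_analysis.sample_rate)
    spec[(freqs < 30) | (freqs > 1900)] = 0.0
    x = np.fft.irfft(spec, n=n)
    return AudioSignal(x / np.std(x), desk_analysis.sample_rate)
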
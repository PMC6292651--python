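"""Waveform container and WAV file I/O.

Sounds are represented as mono, dimensionless-amplitude vectors with an
explicit sample rate.  WAV files are read and written with
:mod:`scipy.io.wavfile`; integer PCM (16/24/32-bit) is rescaled to [-1, 1]
floats on read, and float32 is written by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """A mono sound waveform.

    Parameters
    ----------
    samples : ndarray
        1-D float array of dimensionless amplitudes.
    sample_rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D sample vector")
        if samples.size == 0:
            raise ValueError("AudioSignal requires a non-empty sample vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def scaled_to_rms(self, target_rms: float) -> "AudioSignal":
        """Return a copy rescaled to the given RMS amplitude."""
        current = self.rms()
        if current == 0:
            return self
        return AudioSignal(self.samples * (target_rms / current), self.sample_rate)


_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


def read_wav(path) -> AudioSignal:
    """Read a WAV file (PCM or float) into an :class:`AudioSignal`.

    Multi-channel files are averaged to mono.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype in _PCM_SCALE:
        if data.dtype == np.dtype("uint8"):
            data = (data.astype(float) - 128.0) / 128.0
        else:
            data = data.astype(float) / _PCM_SCALE[data.dtype]
    else:
        data = data.astype(float)
    return AudioSignal(data, float(rate))


def write_wav(path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write an :class:`AudioSignal` to a WAV file.

    ``subtype`` may be ``"float32"`` (default) or ``"pcm16"``.
    """
    if subtype == "float32":
        wavfile.write(path, int(round(signal.sample_rate)), signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        peak = np.max(np.abs(signal.samples))
        scale = 1.0 if peak <= 1.0 else peak
        pcm = np.round(signal.samples / scale * (2**15 - 1)).astype(np.int16)
        wavfile.write(path, int(round(signal.sample_rate)), pcm)
    else:  # pragma: no cover - defensive
        raise ValueError(f"unsupported WAV subtype: {subtype!r}")


def gaussian_noise(n_samples: int, sample_rate: float, rms: float, seed) -> AudioSignal:
    """White Gaussian noise of the given length, scaled to ``rms``."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    x *= rms / np.sqrt(np.mean(x**2))
    return AudioSignal(x, sample_rate)
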
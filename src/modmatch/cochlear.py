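"""Peripheral (cochlear) model: ERB filter bank, cochleagram analysis and
inversion.

The audio waveform is decomposed by a bank of bandpass filters whose
frequency responses are half-cycle cosines on the ERB_N scale (Glasberg &
Moore), spaced so that adjacent filters overlap by 87.5% (a 4x overcomplete
bank) and renormalized so that the squared gains tile the spectrum exactly.
Subband Hilbert envelopes are compressed with a static power law (exponent
0.3, mimicking cochlear compression), anti-alias filtered and downsampled to
the envelope rate.  The resulting time x frequency matrix (the cochleagram)
can be resampled from the ERB axis to a logarithmic frequency axis so that
spectral modulation can be expressed in cycles per octave.

The mapping is invertible: a (possibly modified) cochleagram is converted
back to a waveform by undoing the compression, reimposing per-subband phases
taken from a reference waveform, and refiltering with the same bank.  Because
the squared gains tile, analysis followed by synthesis with unmodified
envelopes reconstructs the input almost perfectly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal as sps
from scipy.fft import fft, ifft, irfft, rfft
from scipy.interpolate import CubicSpline

from .audio import AudioSignal

DEFAULT_COMPRESSION = 0.3
DEFAULT_ENV_RATE = 400.0
DEFAULT_LOG_RESOLUTION = 24.0


def erb_number(f):
    """Glasberg-Moore ERB_N number for frequency ``f`` in Hz."""
    return 21.4 * np.log10(0.00437 * np.asarray(f, dtype=float) + 1.0)


def erb_number_to_hz(n):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(n, dtype=float) / 21.4) - 1.0) / 0.00437


@dataclass
class ERBFilterbank:
    """Half-cosine ERB-spaced analysis/synthesis filter bank.

    ``center_frequencies`` holds the ``n_filters`` bandpass centers; lowpass
    and highpass completion filters are added internally at the band edges so
    that the summed squared gain is exactly 1 from DC to Nyquist (they carry
    edge energy but are not counted among the bandpass filters and do not
    produce cochleagram channels).
    """

    sample_rate: float
    n_filters: int = 120
    f_lo: float = 20.0
    f_hi: float = 10000.0
    overlap_fraction: float = 0.875
    center_frequencies: np.ndarray = field(init=False)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.n_filters < 2:
            raise ValueError("n_filters must be at least 2")
        if self.f_lo <= 0 or self.f_hi <= 0:
            raise ValueError("filter band edges must be positive frequencies")
        if self.f_lo >= self.f_hi:
            raise ValueError("f_lo must be below f_hi")
        if self.f_hi > self.sample_rate / 2 + 1e-9:
            raise ValueError(
                f"f_hi={self.f_hi} Hz exceeds Nyquist ({self.sample_rate / 2} Hz)"
            )
        if not (0 < self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must lie in (0, 1)")
        e_lo, e_hi = erb_number(self.f_lo), erb_number(self.f_hi)
        centers_erb = np.linspace(e_lo, e_hi, self.n_filters)
        self.center_frequencies = erb_number_to_hz(centers_erb)
        self._centers_erb = centers_erb
        self._spacing_erb = (e_hi - e_lo) / (self.n_filters - 1)
        # width of the half-cosine on the ERB axis; 87.5% overlap of adjacent
        # filters means the width is spacing / (1 - overlap)
        self._width_erb = self._spacing_erb / (1.0 - self.overlap_fraction)

    # ------------------------------------------------------------------
    def gains(self, n_fft: int) -> np.ndarray:
        """Bandpass gains, shape (n_filters, n_fft // 2 + 1).

        Normalized together with the edge completions so that the total
        squared gain is 1 at every FFT frequency.
        """
        return self._filters(n_fft)[0]

    def edge_completion_gains(self, n_fft: int) -> np.ndarray:
        """Lowpass/highpass completion gains, shape (2, n_fft // 2 + 1)."""
        return self._filters(n_fft)[1]

    def _filters(self, n_fft: int):
        if n_fft in self._cache:
            return self._cache[n_fft]
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / self.sample_rate)
        e = erb_number(freqs)
        u = (e[None, :] - self._centers_erb[:, None]) / self._width_erb
        gains = np.where(np.abs(u) <= 0.5, np.cos(np.pi * u), 0.0)
        # half-cosine tiling: sum of squares over the regular array is
        # width / (2 * spacing); normalize to a unit plateau
        plateau = self._width_erb / (2.0 * self._spacing_erb)
        gains /= np.sqrt(plateau)
        sumsq = np.sum(gains**2, axis=0)
        deficit = np.sqrt(np.clip(1.0 - sumsq, 0.0, None))
        mid_erb = 0.5 * (self._centers_erb[0] + self._centers_erb[-1])
        completions = np.zeros((2, freqs.size))
        low = e < mid_erb
        completions[0, low] = deficit[low]
        completions[1, ~low] = deficit[~low]
        self._cache[n_fft] = (gains, completions)
        return self._cache[n_fft]

    def analytic_subbands(self, x: np.ndarray) -> np.ndarray:
        """Complex analytic subbands, shape (n_filters, len(x)).

        The real part is the subband waveform, the magnitude its Hilbert
        envelope.
        """
        n = x.size
        spec = fft(x)
        analytic = np.zeros_like(spec)
        analytic[0] = spec[0]
        if n % 2 == 0:
            analytic[n // 2] = spec[n // 2]
            analytic[1 : n // 2] = 2.0 * spec[1 : n // 2]
        else:
            analytic[1 : (n + 1) // 2] = 2.0 * spec[1 : (n + 1) // 2]
        gains = self.gains(n)
        n_pos = n // 2 + 1
        sub_spec = np.zeros((self.n_filters, n), dtype=complex)
        sub_spec[:, :n_pos] = gains * analytic[None, :n_pos]
        return ifft(sub_spec, axis=1)

    def refilter_and_sum(self, subbands: np.ndarray) -> np.ndarray:
        """Apply each bandpass gain to its (real) subband and sum."""
        n = subbands.shape[1]
        spec = rfft(subbands, axis=1) * self.gains(n)
        return irfft(spec.sum(axis=0), n=n)


def build_erb_filterbank(
    sample_rate: float,
    n_filters: int = 120,
    f_lo: float = 20.0,
    f_hi: float = 10000.0,
    overlap_fraction: float = 0.875,
) -> ERBFilterbank:
    """Construct the half-cosine ERB-spaced filter bank."""
    return ERBFilterbank(
        sample_rate=sample_rate,
        n_filters=n_filters,
        f_lo=f_lo,
        f_hi=f_hi,
        overlap_fraction=overlap_fraction,
    )


# ----------------------------------------------------------------------
@dataclass
class Cochleagram:
    """Time x frequency matrix of compressed subband envelopes.

    ``values`` has shape (n_times, n_channels).  ``axis_kind`` is ``"erb"``
    directly after analysis and ``"log"`` after resampling the frequency axis
    to a logarithmic grid (``log_resolution`` channels per octave).
    """

    values: np.ndarray
    env_sample_rate: float
    freq_axis: np.ndarray
    axis_kind: str
    compression_exponent: float = DEFAULT_COMPRESSION
    log_resolution: float = DEFAULT_LOG_RESOLUTION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("cochleagram values must be 2-D (time x channel)")
        if self.values.shape[1] != self.freq_axis.size:
            raise ValueError("freq_axis length must match the channel count")
        if self.axis_kind not in ("erb", "log"):
            raise ValueError("axis_kind must be 'erb' or 'log'")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def global_mean(self) -> float:
        return float(self.values.mean())

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("values", data=self.values)
            d.attrs["env_sample_rate"] = self.env_sample_rate
            d.attrs["axis_kind"] = self.axis_kind
            d.attrs["compression_exponent"] = self.compression_exponent
            d.attrs["log_resolution"] = self.log_resolution
            f.create_dataset("freq_axis", data=self.freq_axis)

    @classmethod
    def load(cls, path) -> "Cochleagram":
        with h5py.File(path, "r") as f:
            d = f["values"]
            return cls(
                values=d[...],
                env_sample_rate=float(d.attrs["env_sample_rate"]),
                freq_axis=f["freq_axis"][...],
                axis_kind=str(d.attrs["axis_kind"]),
                compression_exponent=float(d.attrs["compression_exponent"]),
                log_resolution=float(d.attrs["log_resolution"]),
            )


def wav_to_cochleagram(
    signal: AudioSignal,
    bank: ERBFilterbank,
    compression_exponent: float = DEFAULT_COMPRESSION,
    env_sample_rate: float = DEFAULT_ENV_RATE,
) -> Cochleagram:
    """Analyze a waveform into an ERB-axis cochleagram.

    Per channel: Hilbert envelope of the subband, compressed by the power
    law, anti-alias filtered and downsampled to ``env_sample_rate`` (a
    linear-phase polyphase FIR resampler with cutoff at the envelope Nyquist;
    the group delay is compensated so the operation is effectively
    zero-phase).
    """
    if abs(signal.sample_rate - bank.sample_rate) > 1e-9:
        raise ValueError(
            f"signal rate {signal.sample_rate} Hz does not match the bank design "
            f"rate {bank.sample_rate} Hz"
        )
    up, down = _resample_fraction(env_sample_rate, signal.sample_rate)
    env = np.abs(bank.analytic_subbands(signal.samples))
    env **= compression_exponent
    values = sps.resample_poly(env, up, down, axis=1).T
    np.clip(values, 0.0, None, out=values)
    return Cochleagram(
        values=values,
        env_sample_rate=env_sample_rate,
        freq_axis=bank.center_frequencies.copy(),
        axis_kind="erb",
        compression_exponent=compression_exponent,
    )


def _resample_fraction(rate_out: float, rate_in: float):
    from math import gcd

    a, b = int(round(rate_out)), int(round(rate_in))
    if abs(rate_out - a) > 1e-9 or abs(rate_in - b) > 1e-9:
        raise ValueError("sample rates must be integer-valued Hz")
    g = gcd(a, b)
    return a // g, b // g


def log_frequency_grid(f_lo: float, f_hi: float, cycles_per_octave: float) -> np.ndarray:
    """Logarithmic grid from ``f_lo`` upward in steps of ``2**(1/res)``,
    extended to the smallest grid point >= ``f_hi`` (inclusive)."""
    n_steps = int(np.ceil(cycles_per_octave * np.log2(f_hi / f_lo) - 1e-9))
    return f_lo * 2.0 ** (np.arange(n_steps + 1) / cycles_per_octave)


def _interp_axis(values, x_from, x_to, clip_at_zero):
    # cubic interpolation in log2-frequency, clamped at the source edges
    spline = CubicSpline(x_from, values, axis=1)
    out = spline(np.clip(x_to, x_from[0], x_from[-1]))
    if clip_at_zero:
        np.clip(out, 0.0, None, out=out)
    return out


def to_log_frequency(coch: Cochleagram, cycles_per_octave: float = DEFAULT_LOG_RESOLUTION,
                     f_hi: float | None = None) -> Cochleagram:
    """Resample the frequency axis from ERB spacing to a logarithmic grid."""
    if coch.axis_kind != "erb":
        raise ValueError("to_log_frequency expects an erb-axis cochleagram")
    if cycles_per_octave <= 0:
        raise ValueError("cycles_per_octave must be positive")
    f_lo = coch.freq_axis[0]
    if f_hi is None:
        f_hi = coch.freq_axis[-1]
    grid = log_frequency_grid(f_lo, f_hi, cycles_per_octave)
    values = _interp_axis(
        coch.values, np.log2(coch.freq_axis), np.log2(grid),
        clip_at_zero=bool(coch.values.min() >= 0),
    )
    return replace(coch, values=values, freq_axis=grid, axis_kind="log",
                   log_resolution=cycles_per_octave)


def to_erb_frequency(coch: Cochleagram, erb_freq_axis: np.ndarray) -> Cochleagram:
    """Resample a log-axis cochleagram back onto the given ERB-spaced centers."""
    if coch.axis_kind != "log":
        raise ValueError("to_erb_frequency expects a log-axis cochleagram")
    values = _interp_axis(
        coch.values, np.log2(coch.freq_axis), np.log2(erb_freq_axis),
        clip_at_zero=bool(coch.values.min() >= 0),
    )
    return replace(coch, values=values, freq_axis=np.asarray(erb_freq_axis, float),
                   axis_kind="erb")


def cochleagram_to_wav(
    coch: Cochleagram,
    phase_reference: AudioSignal,
    bank: ERBFilterbank,
) -> AudioSignal:
    """Invert an ERB-axis cochleagram to a waveform.

    Envelopes are un-compressed (power ``1/compression_exponent``), upsampled
    to the audio rate, multiplied by the unit-magnitude analytic phases of the
    reference waveform's subbands, refiltered and summed.  Negative values
    (possible after modulation-domain edits) are clipped to zero first.
    """
    if coch.axis_kind != "erb":
        raise ValueError("convert the cochleagram to the erb axis before inversion")
    if coch.n_channels != bank.n_filters:
        raise ValueError("cochleagram channel count does not match the bank")
    values = coch.values
    if values.min() < 0:
        warnings.warn("clipping negative cochleagram values to 0 before inversion")
        values = np.clip(values, 0.0, None)
    env = values.T ** (1.0 / coch.compression_exponent)
    up, down = _resample_fraction(phase_reference.sample_rate, coch.env_sample_rate)
    env_up = sps.resample_poly(env, up, down, axis=1)
    n = phase_reference.n_samples
    if env_up.shape[1] < n:
        env_up = np.pad(env_up, ((0, 0), (0, n - env_up.shape[1])))
    env_up = env_up[:, :n]
    np.clip(env_up, 0.0, None, out=env_up)
    analytic = bank.analytic_subbands(phase_reference.samples)
    mag = np.abs(analytic)
    # only the cosine of the analytic phase is needed: Re(a / |a|)
    cos_phase = analytic.real / np.where(mag > 0, mag, 1.0)
    cos_phase[mag == 0] = 1.0
    subbands = env_up * cos_phase
    samples = bank.refilter_and_sum(subbands)
    return AudioSignal(samples, phase_reference.sample_rate)
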
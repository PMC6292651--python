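"""Temporal, spectral and oriented spectrotemporal modulation filters.

Second stage of the auditory model: filters tuned to fluctuations of the
(log-frequency-axis) cochleagram over time (temporal rate, Hz), over
frequency (spectral scale, cycles/octave), or both.  Temporal filters are
causal gammatones

    psi(t; b_r, lambda_t) = (lambda_t b_r t)^2 exp(-3.5 lambda_t b_r t)
                            sin(2 pi b_r t)

with best rate ``b_r`` (the standard bank uses lambda_t = 1; lambda_t = 0.5
halves the bandwidth while leaving the carrier unchanged).  Spectral filters
are Mexican-hat wavelets, instantiated directly in the spectral-modulation
Fourier domain as

    Phi(omega; b_s) = omega^2 exp(-(omega / b_s)^2)

with best scale ``b_s``; the variable-bandwidth variant is a Morlet wavelet
phi(f) = exp(-(2 lambda_s b_s f)^2) cos(2 pi b_s f).  2-D spectrotemporal
filters are outer products of the 1-D transfer functions, "oriented" to
upward- or downward-sweeping modulation by zeroing a quadrant pair of the 2-D
frequency plane (DC and Nyquist lines are never zeroed).  Because each
quadrant pair is symmetric under joint frequency negation, the oriented
transfers stay Hermitian and the filtered cochleagrams are real.

Filtering happens in the 2-D FFT domain after padding the cochleagram in
time and frequency with its global mean value (to suppress circular
wraparound); the padding amounts are derived from the filter periods: twice
the period of the coarsest spectral filter and three times the period of the
slowest temporal filter.  Cochleagrams are reconstructed from a filtered set
by summing the conjugate-filtered stacks and dividing by the summed filter
power, which is an exact inverse wherever the summed power is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.fft import fft, irfft, irfft2, next_fast_len, rfft, rfft2

from .cochlear import Cochleagram

DEFAULT_RATES = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
DEFAULT_LOW_RATES = (0.125, 0.25)
DEFAULT_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
MODEL_KINDS = ("cochlear", "temporal", "spectral", "spectrotemporal")
VARIANTS = ("standard", "phase_randomized", "half_bandwidth", "random")


# ----------------------------------------------------------------------
# filter specs
@dataclass(frozen=True)
class TemporalFilterSpec:
    best_rate: float = 0.0  # Hz; ignored when is_dc
    bandwidth_factor: float = 1.0
    is_dc: bool = False
    phase_randomized: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.is_dc and self.best_rate <= 0:
            raise ValueError("best_rate must be positive for a bandpass filter")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")


@dataclass(frozen=True)
class SpectralFilterSpec:
    best_scale: float = 0.0  # cycles/octave; ignored when is_dc
    bandwidth_factor: float = 1.0  # 1 -> Mexican hat, otherwise Morlet
    is_dc: bool = False
    phase_randomized: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.is_dc and self.best_scale <= 0:
            raise ValueError("best_scale must be positive for a bandpass filter")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")


@dataclass(frozen=True)
class SpectroTemporalFilter:
    """One filter of the bank.

    ``temporal is None`` means all-pass in time; ``spectral is None`` means
    all-pass in frequency (so a filter with both ``None`` passes the
    unfiltered cochleagram).  ``orientation`` is ``"up"``, ``"down"`` or
    ``"none"``; only genuinely 2-D bandpass filters are oriented.
    """

    temporal: Optional[TemporalFilterSpec]
    spectral: Optional[SpectralFilterSpec]
    orientation: str = "none"

    def __post_init__(self):
        if self.orientation not in ("up", "down", "none"):
            raise ValueError("orientation must be 'up', 'down' or 'none'")
        if self.orientation != "none":
            for part in (self.temporal, self.spectral):
                if part is None or part.is_dc:
                    raise ValueError("only 2-D bandpass filters can be oriented")

    @property
    def is_cochlear_passthrough(self) -> bool:
        return self.temporal is None and self.spectral is None

    def label(self) -> str:
        t = ("dc" if self.temporal.is_dc else f"{self.temporal.best_rate:g}Hz") if self.temporal else "all"
        s = ("dc" if self.spectral.is_dc else f"{self.spectral.best_scale:g}cpo") if self.spectral else "all"
        return f"t={t}|s={s}|{self.orientation}"


# ----------------------------------------------------------------------
# 1-D transfer functions
def temporal_impulse_response(spec: TemporalFilterSpec, t: np.ndarray) -> np.ndarray:
    """Causal gammatone impulse response evaluated at times ``t`` (seconds).

    Strictly zero for t < 0.
    """
    if spec.is_dc:
        raise ValueError("the DC filter has no bandpass impulse response")
    t = np.asarray(t, dtype=float)
    lam_b = spec.bandwidth_factor * spec.best_rate
    h = (lam_b * t) ** 2 * np.exp(-3.5 * lam_b * t) * np.sin(2 * np.pi * spec.best_rate * t)
    return np.where(t >= 0, h, 0.0)


def temporal_transfer_function(
    spec: TemporalFilterSpec, env_sample_rate: float, n_samples: int
) -> np.ndarray:
    """Complex gain over the full FFT frequency grid (length ``n_samples``).

    Peak gain magnitude is normalized to 1.
    """
    if spec.is_dc:
        H = np.zeros(n_samples, dtype=complex)
        H[0] = 1.0
        return H
    min_n = int(np.ceil(3.0 / spec.best_rate * env_sample_rate))
    if n_samples < min_n:
        raise ValueError(
            f"n_samples={n_samples} covers fewer than 3 periods of "
            f"{spec.best_rate} Hz at {env_sample_rate} Hz; need >= {min_n}"
        )
    t = np.arange(n_samples) / env_sample_rate
    h = temporal_impulse_response(spec, t)
    if spec.phase_randomized:
        h = _phase_randomize(h, int(round(2.0 / spec.best_rate * env_sample_rate)), spec.seed)
    H = fft(h)
    H[0] = 0.0  # bandpass by construction: only the DC filter passes 0 Hz
    return H / np.max(np.abs(H))


def spectral_transfer_function(
    spec: SpectralFilterSpec, cycles_per_octave: float, n_channels: int, half: bool = False
) -> np.ndarray:
    """Gain over the spectral-modulation frequency grid.

    Returns the full FFT grid (length ``n_channels``) or, with ``half=True``,
    the nonnegative-frequency half used by real 2-D FFTs.  Peak gain 1.
    """
    if spec.is_dc:
        H = np.zeros(n_channels, dtype=complex)
        H[0] = 1.0
        return H[: n_channels // 2 + 1] if half else H
    min_n = int(np.ceil(2.0 / spec.best_scale * cycles_per_octave))
    if n_channels < min_n:
        raise ValueError(
            f"n_channels={n_channels} covers fewer than 2 periods of "
            f"{spec.best_scale} cyc/oct at {cycles_per_octave} ch/oct; need >= {min_n}"
        )
    if spec.phase_randomized:
        n_win = int(round(2.0 / spec.best_scale * cycles_per_octave))
        f = (np.arange(n_win) - n_win // 2) / cycles_per_octave
        kernel = _spectral_kernel(spec, f)
        kernel = _phase_randomize(kernel, n_win, spec.seed)
        H = fft(kernel, n=n_channels)
        H[0] = 0.0
        H = H / np.max(np.abs(H))
    else:
        omega = np.abs(np.fft.fftfreq(n_channels, d=1.0 / cycles_per_octave))
        if spec.bandwidth_factor == 1.0:
            H = omega**2 * np.exp(-((omega / spec.best_scale) ** 2))
        else:
            # closed-form Fourier transform of the Morlet kernel
            a = 2.0 * spec.bandwidth_factor * spec.best_scale
            H = np.exp(-(np.pi * (omega - spec.best_scale) / a) ** 2) + np.exp(
                -(np.pi * (omega + spec.best_scale) / a) ** 2
            )
        H[0] = 0.0  # bandpass: no DC leakage
        H = (H / np.max(np.abs(H))).astype(complex)
    return H[: n_channels // 2 + 1] if half else H


def _spectral_kernel(spec: SpectralFilterSpec, f: np.ndarray) -> np.ndarray:
    """Signal-domain spectral kernel (f in octaves)."""
    if spec.bandwidth_factor == 1.0:
        u = spec.best_scale * np.pi * f
        return (1.0 - 2.0 * u**2) * np.exp(-(u**2))
    a = 2.0 * spec.bandwidth_factor * spec.best_scale
    return np.exp(-((a * f) ** 2)) * np.cos(2 * np.pi * spec.best_scale * f)


def _phase_randomize(kernel: np.ndarray, n_win: int, seed) -> np.ndarray:
    """Randomize the Fourier phases of ``kernel[:n_win]``, keep magnitudes,
    return a real kernel zero-padded back to the original length."""
    n_win = min(n_win, kernel.size)
    rng = np.random.default_rng(seed)
    spec = rfft(kernel[:n_win])
    phases = np.exp(1j * rng.uniform(0, 2 * np.pi, spec.size))
    phases[0] = 1.0
    if n_win % 2 == 0:
        phases[-1] = 1.0  # Nyquist bin must stay real
    windowed = irfft(np.abs(spec) * phases, n=n_win)
    out = np.zeros_like(kernel)
    out[:n_win] = windowed
    return out


# ----------------------------------------------------------------------
# bank enumeration
@dataclass
class FilterBankSpec:
    model_kind: str
    filters: list  # ordered list of SpectroTemporalFilter
    rates: tuple = DEFAULT_RATES
    low_rates: tuple = DEFAULT_LOW_RATES
    scales: tuple = DEFAULT_SCALES
    include_unfiltered_cochleagram: bool = True
    variant: str = "standard"
    random_kernels: Optional[list] = None  # only for variant="random"

    @property
    def n_filters(self) -> int:
        return len(self.filters)

    def oriented_filters(self):
        return [f for f in self.filters if f.orientation != "none"]

    def time_padding_seconds(self) -> float:
        """Three times the period of the slowest temporal filter."""
        rates = [
            f.temporal.best_rate
            for f in self.filters
            if f.temporal is not None and not f.temporal.is_dc
        ]
        return 3.0 / min(rates) if rates else 0.0

    def freq_padding_octaves(self) -> float:
        """Twice the period of the coarsest spectral filter."""
        scales = [
            f.spectral.best_scale
            for f in self.filters
            if f.spectral is not None and not f.spectral.is_dc
        ]
        return 2.0 / min(scales) if scales else 0.0


def build_filterbank(
    model_kind: str,
    variant: str = "standard",
    rates: tuple = DEFAULT_RATES,
    scales: tuple = DEFAULT_SCALES,
    low_rates: tuple = DEFAULT_LOW_RATES,
    seed: int = 0,
) -> FilterBankSpec:
    """Enumerate the model's filter set.

    * ``spectrotemporal``: every (rate, scale) crossed with both orientations,
      plus single-orientation crossings with the temporal and spectral DC
      filters, plus all temporal-only filters (including the very low rates
      and the temporal DC) and all spectral-only filters (including the
      spectral DC), plus the unfiltered cochleagram.
    * ``temporal`` / ``spectral``: the corresponding 1-D filters (+ DC) plus
      the unfiltered cochleagram.
    * ``cochlear``: no modulation filters, unfiltered cochleagram only.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}; expected one of {MODEL_KINDS}")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "random":
        raise ValueError("use random_filterbank() for the random variant")
    if list(rates) != sorted(rates) or any(r <= 0 for r in rates):
        raise ValueError("rates must be positive and sorted")
    if list(scales) != sorted(scales) or any(s <= 0 for s in scales):
        raise ValueError("scales must be positive and sorted")

    lam = 0.5 if variant == "half_bandwidth" else 1.0
    randomized = variant == "phase_randomized"
    counter = [0]

    def tspec(rate, dc=False):
        counter[0] += 1
        return TemporalFilterSpec(
            best_rate=0.0 if dc else rate, bandwidth_factor=lam, is_dc=dc,
            phase_randomized=randomized and not dc, seed=seed * 100003 + counter[0],
        )

    def sspec(scale, dc=False):
        counter[0] += 1
        return SpectralFilterSpec(
            best_scale=0.0 if dc else scale, bandwidth_factor=lam, is_dc=dc,
            phase_randomized=randomized and not dc, seed=seed * 100003 + counter[0],
        )

    filters: list[SpectroTemporalFilter] = []
    if model_kind == "spectrotemporal":
        for r in rates:
            for s in scales:
                for orientation in ("up", "down"):
                    filters.append(SpectroTemporalFilter(tspec(r), sspec(s), orientation))
        for r in rates:  # crossed with the spectral DC: one orientation
            filters.append(SpectroTemporalFilter(tspec(r), sspec(0, dc=True)))
        for s in scales:  # crossed with the temporal DC: one orientation
            filters.append(SpectroTemporalFilter(tspec(0, dc=True), sspec(s)))
    if model_kind in ("temporal", "spectrotemporal"):
        for r in list(low_rates) + list(rates):
            filters.append(SpectroTemporalFilter(tspec(r), None))
        filters.append(SpectroTemporalFilter(tspec(0, dc=True), None))
    if model_kind in ("spectral", "spectrotemporal"):
        for s in scales:
            filters.append(SpectroTemporalFilter(None, sspec(s)))
        filters.append(SpectroTemporalFilter(None, sspec(0, dc=True)))
    filters.append(SpectroTemporalFilter(None, None))  # unfiltered cochleagram

    return FilterBankSpec(
        model_kind=model_kind, filters=filters, rates=tuple(rates),
        low_rates=tuple(low_rates) if model_kind in ("temporal", "spectrotemporal") else (),
        scales=tuple(scales), variant=variant,
    )


def random_filterbank(
    seed: int,
    n_filters: int,
    time_extent_range: tuple = (0.125, 2.0),  # seconds
    freq_extent_range: tuple = (0.25, 4.0),  # octaves
) -> FilterBankSpec:
    """Gaussian-weight 2-D kernels of variable temporal/spectral extent.

    The extents are drawn log-uniformly within the configured ranges to mimic
    the spread of integration windows in the structured model.  Kernels are
    materialized lazily onto each cochleagram grid (``random_kernels`` stores
    (weights, time_extent_s, freq_extent_oct) triples; weights are iid
    standard normal on a fixed 16 x 16 lattice that is resampled to the
    requested extent).
    """
    if n_filters <= 0:
        raise ValueError("n_filters must be positive")
    rng = np.random.default_rng(seed)
    kernels = []
    for _ in range(n_filters):
        w = rng.standard_normal((16, 16))
        te = np.exp(rng.uniform(np.log(time_extent_range[0]), np.log(time_extent_range[1])))
        fe = np.exp(rng.uniform(np.log(freq_extent_range[0]), np.log(freq_extent_range[1])))
        kernels.append((w, float(te), float(fe)))
    # placeholder filter objects (one per kernel) so counting/enumeration works
    filters = [SpectroTemporalFilter(None, None) for _ in range(n_filters)]
    return FilterBankSpec(
        model_kind="spectrotemporal", filters=filters, variant="random",
        random_kernels=kernels, include_unfiltered_cochleagram=False,
        rates=(), low_rates=(), scales=(),
    )


# ----------------------------------------------------------------------
# transfer materialization and application
def filter_transfer_2d(
    filt: SpectroTemporalFilter,
    n_times: int,
    n_channels: int,
    env_sample_rate: float,
    cycles_per_octave: float,
) -> np.ndarray:
    """Complex transfer on the real-2D-FFT grid, shape (n_times, n_channels//2 + 1).

    The temporal axis carries the full (signed) FFT frequencies; the spectral
    axis carries the nonnegative half (the negative half is implied by
    Hermitian symmetry, which all filters here respect).
    """
    n_half = n_channels // 2 + 1
    T = (
        temporal_transfer_function(filt.temporal, env_sample_rate, n_times)
        if filt.temporal is not None
        else np.ones(n_times, dtype=complex)
    )
    S = (
        spectral_transfer_function(filt.spectral, cycles_per_octave, n_channels, half=True)
        if filt.spectral is not None
        else np.ones(n_half, dtype=complex)
    )
    H = np.outer(T, S)
    if filt.orientation != "none":
        wt = np.fft.fftfreq(n_times, d=1.0 / env_sample_rate)
        wf = np.fft.rfftfreq(n_channels, d=1.0 / cycles_per_octave)
        nyq_f = cycles_per_octave / 2.0
        interior_f = (wf > 0) & ((n_channels % 2 == 1) | (wf < nyq_f - 1e-12))
        # wt > 0 excludes DC; the temporal Nyquist of an even grid appears as
        # a negative frequency in fftfreq, so it is excluded from both masks
        if filt.orientation == "up":
            rows = wt > 0
        else:
            nyq_t = env_sample_rate / 2.0
            rows = (wt < 0) & ((n_times % 2 == 1) | (wt > -nyq_t + 1e-12))
        H[np.ix_(rows, interior_f)] = 0.0
    peak = np.max(np.abs(H))
    if peak > 0:
        H /= peak
    return H


def _random_kernel_transfer(kernel, n_times, n_channels, env_sample_rate, cycles_per_octave):
    from scipy.ndimage import zoom

    w, te, fe = kernel
    nt = max(2, int(round(te * env_sample_rate)))
    nf = max(2, int(round(fe * cycles_per_octave)))
    k = zoom(w, (nt / w.shape[0], nf / w.shape[1]), order=1)
    full = np.zeros((n_times, n_channels))
    full[:nt, :nf] = k[:n_times, :n_channels]
    H = rfft2(full)
    peak = np.max(np.abs(H))
    return H / peak if peak > 0 else H


def bank_transfers(bank: FilterBankSpec, n_times: int, n_channels: int,
                   env_sample_rate: float, cycles_per_octave: float) -> list:
    """Materialize every filter's 2-D transfer for the given padded grid."""
    if bank.variant == "random":
        return [
            _random_kernel_transfer(k, n_times, n_channels, env_sample_rate, cycles_per_octave)
            for k in bank.random_kernels
        ]
    return [
        filter_transfer_2d(f, n_times, n_channels, env_sample_rate, cycles_per_octave)
        for f in bank.filters
    ]


@dataclass
class FilteredCochleagrams:
    """Stack of filtered cochleagrams (one per filter), kept on the padded grid.

    ``stacks`` has shape (n_filters, n_times_padded, n_channels_padded); the
    original (unpadded) region is ``[time_slice, freq_slice]``.
    """

    stacks: np.ndarray
    bank: FilterBankSpec
    time_slice: slice
    freq_slice: slice
    env_sample_rate: float
    freq_axis: np.ndarray
    log_resolution: float
    compression_exponent: float
    padding_used: tuple  # (seconds, octaves)

    @property
    def n_filters(self) -> int:
        return self.stacks.shape[0]

    def unpadded(self) -> np.ndarray:
        """View of the stacks restricted to the original cochleagram extent."""
        return self.stacks[:, self.time_slice, self.freq_slice]

    def unpadded_cochleagram(self, index: int) -> Cochleagram:
        return Cochleagram(
            values=self.stacks[index, self.time_slice, self.freq_slice].copy(),
            env_sample_rate=self.env_sample_rate,
            freq_axis=self.freq_axis,
            axis_kind="log",
            compression_exponent=self.compression_exponent,
            log_resolution=self.log_resolution,
        )


def padded_grid(coch: Cochleagram, bank: FilterBankSpec):
    """Padded array sizes and unpadding slices for this cochleagram/bank pair."""
    pad_t = int(round(bank.time_padding_seconds() * coch.env_sample_rate))
    pad_f = int(round(bank.freq_padding_octaves() * coch.log_resolution))
    n_t = next_fast_len(coch.n_times + pad_t)
    n_f = next_fast_len(coch.n_channels + pad_f)
    return n_t, n_f, slice(0, coch.n_times), slice(0, coch.n_channels)


def pad_cochleagram(coch: Cochleagram, bank: FilterBankSpec, pad_value: float | None = None):
    """Embed the cochleagram in the padded grid, filling with its global mean."""
    n_t, n_f, ts, fs = padded_grid(coch, bank)
    if pad_value is None:
        pad_value = coch.global_mean()
    padded = np.full((n_t, n_f), pad_value, dtype=float)
    padded[ts, fs] = coch.values
    return padded, ts, fs


def apply_filterbank(coch: Cochleagram, bank: FilterBankSpec) -> FilteredCochleagrams:
    """Filter a log-axis cochleagram with every filter of the bank."""
    if coch.axis_kind != "log":
        raise ValueError(
            "apply_filterbank expects a log-frequency cochleagram; "
            "convert with to_log_frequency first"
        )
    padded, ts, fs = pad_cochleagram(coch, bank)
    n_t, n_f = padded.shape
    X = rfft2(padded)
    transfers = bank_transfers(bank, n_t, n_f, coch.env_sample_rate, coch.log_resolution)
    stacks = np.empty((len(transfers), n_t, n_f))
    for k, H in enumerate(transfers):
        stacks[k] = irfft2(H * X, s=(n_t, n_f))
    return FilteredCochleagrams(
        stacks=stacks, bank=bank, time_slice=ts, freq_slice=fs,
        env_sample_rate=coch.env_sample_rate, freq_axis=coch.freq_axis.copy(),
        log_resolution=coch.log_resolution, compression_exponent=coch.compression_exponent,
        padding_used=(bank.time_padding_seconds(), bank.freq_padding_octaves()),
    )


POWER_FLOOR_REL = 1e-10


def summed_power(bank: FilterBankSpec, n_times: int, n_channels: int,
                 env_sample_rate: float, cycles_per_octave: float) -> np.ndarray:
    transfers = bank_transfers(bank, n_times, n_channels, env_sample_rate, cycles_per_octave)
    P = np.zeros((n_times, n_channels // 2 + 1))
    for H in transfers:
        P += np.abs(H) ** 2
    return P


def reconstruct_cochleagram(filtered: FilteredCochleagrams) -> Cochleagram:
    """Invert :func:`apply_filterbank`: conjugate-filter, sum, divide by power."""
    n_t, n_f = filtered.stacks.shape[1:]
    transfers = bank_transfers(
        filtered.bank, n_t, n_f, filtered.env_sample_rate, filtered.log_resolution
    )
    acc = np.zeros((n_t, n_f // 2 + 1), dtype=complex)
    P = np.zeros((n_t, n_f // 2 + 1))
    for H, stack in zip(transfers, filtered.stacks):
        acc += np.conj(H) * rfft2(stack)
        P += np.abs(H) ** 2
    floor = POWER_FLOOR_REL * P.max()
    good = P > floor
    acc[good] /= P[good]
    acc[~good] = 0.0
    padded = irfft2(acc, s=(n_t, n_f))
    return Cochleagram(
        values=padded[filtered.time_slice, filtered.freq_slice].copy(),
        env_sample_rate=filtered.env_sample_rate,
        freq_axis=filtered.freq_axis,
        axis_kind="log",
        compression_exponent=filtered.compression_exponent,
        log_resolution=filtered.log_resolution,
    )
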
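"""Bundled analysis settings: audio band, cochleagram and filter-bank layout.

``default_analysis()`` is the full-scale model: 20 kHz audio, 120 ERB
channels between 20 Hz and 10 kHz, 400 Hz envelope rate, 24 channels/octave
log axis (217 channels), temporal rates 0.5-128 Hz plus 0.125/0.25 Hz low
rates, spectral scales 0.25-8 cycles/octave.

``desk_scale_analysis()`` is a reduced configuration with the same structure
for demonstration and continuous-integration runs on a single CPU: 4 kHz
audio over 20 Hz-2 kHz (40 ERB channels), 100 Hz envelope rate, rates
1-32 Hz plus 0.25/0.5 Hz low rates, scales 0.5-8 cycles/octave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .audio import AudioSignal
from .cochlear import (
    Cochleagram,
    ERBFilterbank,
    build_erb_filterbank,
    cochleagram_to_wav,
    to_erb_frequency,
    to_log_frequency,
    wav_to_cochleagram,
)
from .modulation import FilterBankSpec, build_filterbank


@dataclass
class AnalysisConfig:
    sample_rate: float = 20000.0
    n_filters: int = 120
    f_lo: float = 20.0
    f_hi: float = 10000.0
    env_sample_rate: float = 400.0
    compression_exponent: float = 0.3
    cycles_per_octave: float = 24.0
    rates: tuple = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
    low_rates: tuple = (0.125, 0.25)
    scales: tuple = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    _bank: ERBFilterbank = field(default=None, repr=False, compare=False)

    def erb_bank(self) -> ERBFilterbank:
        if self._bank is None:
            self._bank = build_erb_filterbank(
                self.sample_rate, self.n_filters, self.f_lo, self.f_hi
            )
        return self._bank

    def build_modulation_bank(
        self, model_kind: str, variant: str = "standard", seed: int = 0
    ) -> FilterBankSpec:
        return build_filterbank(
            model_kind, variant=variant, rates=self.rates, scales=self.scales,
            low_rates=self.low_rates, seed=seed,
        )

    def analyze(self, signal: AudioSignal, log_axis: bool = True) -> Cochleagram:
        coch = wav_to_cochleagram(
            signal, self.erb_bank(), self.compression_exponent, self.env_sample_rate
        )
        if log_axis:
            coch = to_log_frequency(coch, self.cycles_per_octave, f_hi=self.f_hi)
        return coch

    def invert(self, coch: Cochleagram, phase_reference: AudioSignal) -> AudioSignal:
        if coch.axis_kind == "log":
            coch = to_erb_frequency(coch, self.erb_bank().center_frequencies)
        return cochleagram_to_wav(coch, phase_reference, self.erb_bank())


def default_analysis() -> AnalysisConfig:
    return AnalysisConfig()


def desk_scale_analysis() -> AnalysisConfig:
    return AnalysisConfig(
        sample_rate=4000.0, n_filters=40, f_lo=20.0, f_hi=2000.0,
        env_sample_rate=100.0, cycles_per_octave=24.0,
        rates=(2.0, 4.0, 8.0, 16.0, 32.0), low_rates=(0.5, 1.0),
        scales=(0.5, 1.0, 2.0, 4.0, 8.0),
    )
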
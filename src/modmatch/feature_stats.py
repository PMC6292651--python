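"""Time-averaged feature amplitudes and match-quality evaluation.

Each frequency channel of each filtered cochleagram is one model feature.
Its amplitude for a sound is the time-mean of the envelope for cochlear
features (the unfiltered cochleagram), and the standard deviation across
time for modulation-tuned features.  Match quality between a natural sound
and its model-matched counterpart is the squared Pearson correlation of the
two amplitude vectors across all features, optionally computed under a
filter bank other than the one used for matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cochlear import Cochleagram
from .modulation import FilteredCochleagrams

log = logging.getLogger(__name__)


@dataclass
class FeatureStatistics:
    """Per-feature time-averaged amplitudes for one sound."""

    sound_id: str
    model_kind: str
    amplitudes: np.ndarray
    index: pd.DataFrame  # columns: feature_kind, filter_label, channel, frequency

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1 or len(self.index) != self.amplitudes.size:
            raise ValueError("amplitudes must be 1-D and match the index length")

    def to_frame(self) -> pd.DataFrame:
        out = self.index.copy()
        out.insert(0, "sound_id", self.sound_id)
        out["amplitude"] = self.amplitudes
        return out


def time_averaged_stats(
    source: FilteredCochleagrams | Cochleagram,
    model_kind: str | None = None,
    sound_id: str = "",
) -> FeatureStatistics:
    """Mean (cochlear) / SD (modulation) amplitude of every feature.

    Statistics are taken over the unpadded region only.
    """
    if isinstance(source, Cochleagram):
        values = source.values
        if values.size == 0:
            raise ValueError("empty cochleagram")
        amps = values.mean(axis=0)
        index = pd.DataFrame(
            {
                "feature_kind": "cochlear",
                "filter_label": "cochleagram",
                "channel": np.arange(values.shape[1]),
                "frequency": source.freq_axis,
            }
        )
        return FeatureStatistics(sound_id, model_kind or "cochlear", amps, index)

    stacks = source.unpadded()
    if stacks.size == 0:
        raise ValueError("empty filtered-cochleagram stack")
    amp_blocks, idx_blocks = [], []
    if source.bank.variant == "random":
        labels = [f"random{k}" for k in range(source.n_filters)]
        cochlear_mask = [False] * source.n_filters
    else:
        labels = [f.label() for f in source.bank.filters]
        cochlear_mask = [f.is_cochlear_passthrough for f in source.bank.filters]
    for k in range(source.n_filters):
        block = stacks[k]
        if cochlear_mask[k]:
            amps = block.mean(axis=0)
            kind = "cochlear"
        else:
            amps = block.std(axis=0)
            kind = "modulation"
        amp_blocks.append(amps)
        idx_blocks.append(
            pd.DataFrame(
                {
                    "feature_kind": kind,
                    "filter_label": labels[k],
                    "channel": np.arange(block.shape[1]),
                    "frequency": source.freq_axis,
                }
            )
        )
    return FeatureStatistics(
        sound_id,
        model_kind or source.bank.model_kind,
        np.concatenate(amp_blocks),
        pd.concat(idx_blocks, ignore_index=True),
    )


def match_quality(
    natural_stats: FeatureStatistics, matched_stats: FeatureStatistics
) -> float:
    """Squared Pearson correlation of the two amplitude vectors.

    Features whose amplitude is zero in both sounds (e.g. the constant output
    of a temporal-DC filter) carry no information and are dropped with a
    logged count.  Raises if either remaining vector has zero variance.
    """
    a = natural_stats.amplitudes
    b = matched_stats.amplitudes
    if a.size != b.size:
        raise ValueError("feature enumerations differ between the two sounds")
    both_zero = (a == 0) & (b == 0)
    if both_zero.any():
        log.info("dropping %d features with zero amplitude in both sounds", both_zero.sum())
        a, b = a[~both_zero], b[~both_zero]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: a feature-amplitude vector has zero variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)
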
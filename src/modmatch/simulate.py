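"""Synthetic data generators.

Two kinds of fixtures:

* Simulated voxel responses used to validate the NSE noise correction.
  Each voxel has a true signal pair (s_x, s_y) and three noisy measurements
  x1 = s_x b + n_x1 (1 - b), x2 = s_x b + n_x2 (1 - b), y1 = s_y b +
  n_y1 (1 - b), with the SNR weight b ~ Uniform(0, 1) and iid standard-normal
  noise.  In Simulation 1 the signals share a common component, s_x = g c +
  u_x (1 - c) and s_y = g c + u_y (1 - c) with c ~ Uniform(0, 1); in
  Simulation 2 one signal is a scaled copy of the other, s_x = g, s_y = g c.

* Synthetic structured sounds (harmonic complexes with amplitude modulation,
  noise bursts, chirped textures) with documented modulation content, so the
  synthesis and feature machinery can be exercised without external audio.
  These sound families are package inventions that stand in for recorded
  natural sounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .nse import nse

SIM_KINDS = ("sim1", "sim2")
SOUND_KINDS = ("am_harmonic", "noise_burst", "chirped_texture", "silence")


@dataclass
class SimulatedVoxelSet:
    x1: np.ndarray
    x2: np.ndarray
    y1: np.ndarray
    s_x: np.ndarray
    s_y: np.ndarray
    b: np.ndarray
    c: np.ndarray
    sim_kind: str
    seed: int

    @property
    def n_voxels(self) -> int:
        return self.x1.shape[0]

    @property
    def n_items(self) -> int:
        return self.x1.shape[1]


def simulate_voxels(
    sim_kind: str,
    n_voxels: int = 100_000,
    n_items: int = 36,
    seed: int = 0,
    noise: str = "normal",
    b: np.ndarray | None = None,
    c: np.ndarray | None = None,
) -> SimulatedVoxelSet:
    """Simulate noisy voxel responses to two sound sets.

    ``b`` and ``c`` may be supplied (per voxel) to force particular SNR /
    similarity levels; by default both are Uniform(0, 1).  ``noise`` selects
    the noise distribution (``normal`` or ``laplace``; both zero-mean,
    unit-variance).
    """
    if sim_kind not in SIM_KINDS:
        raise ValueError(f"sim_kind must be one of {SIM_KINDS}")
    if n_voxels <= 0 or n_items <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    b = rng.uniform(0, 1, n_voxels) if b is None else np.broadcast_to(b, (n_voxels,)).copy()
    c = rng.uniform(0, 1, n_voxels) if c is None else np.broadcast_to(c, (n_voxels,)).copy()
    bc = b[:, None]
    cc = c[:, None]
    g = rng.standard_normal((n_voxels, n_items))
    if sim_kind == "sim1":
        u_x = rng.standard_normal((n_voxels, n_items))
        u_y = rng.standard_normal((n_voxels, n_items))
        s_x = g * cc + u_x * (1 - cc)
        s_y = g * cc + u_y * (1 - cc)
    else:
        s_x = g
        s_y = g * cc
    if noise == "normal":
        draw = rng.standard_normal
    elif noise == "laplace":
        def draw(shape):
            return rng.laplace(scale=1 / np.sqrt(2), size=shape)
    else:
        raise ValueError("noise must be 'normal' or 'laplace'")
    x1 = s_x * bc + draw((n_voxels, n_items)) * (1 - bc)
    x2 = s_x * bc + draw((n_voxels, n_items)) * (1 - bc)
    y1 = s_y * bc + draw((n_voxels, n_items)) * (1 - bc)
    return SimulatedVoxelSet(x1, x2, y1, s_x, s_y, b, c, sim_kind, seed)


def voxel_statistics(vox: SimulatedVoxelSet) -> pd.DataFrame:
    """The four per-voxel statistics: noisy, true, corrected and test-retest NSE."""
    noisy = nse(vox.x1, vox.y1)
    true = nse(vox.s_x, vox.s_y)
    trt = nse(vox.x1, vox.x2)
    # vectorized equal-noise correction from (x1, x2, y1)
    mu = lambda a: a.mean(axis=-1)
    mu_sx = 0.5 * (mu(vox.x1) + mu(vox.x2))
    mu_sy = mu(vox.y1)
    mu_sxsy = 0.5 * (mu(vox.x1 * vox.y1) + mu(vox.x2 * vox.y1))
    noise_pow = 0.5 * mu((vox.x1 - vox.x2) ** 2)
    mu_sx2 = 0.5 * (mu(vox.x1**2) + mu(vox.x2**2)) - noise_pow
    mu_sy2 = mu(vox.y1**2) - noise_pow
    num = mu_sx2 + mu_sy2 - 2 * mu_sxsy
    den = mu_sx2 + mu_sy2 - 2 * mu_sx * mu_sy
    corrected = np.full(num.shape, np.nan)
    ok = den != 0
    corrected[ok] = num[ok] / den[ok]
    return pd.DataFrame(
        {"noisy_nse": noisy, "true_nse": true, "corrected_nse": corrected,
         "test_retest_nse": trt}
    )


@dataclass
class CorrectionEvaluation:
    """Binned medians and central-68% bands of the four NSE statistics."""

    table: pd.DataFrame  # one row per reliability bin
    bin_edges: np.ndarray


def evaluate_noise_correction(
    vox: SimulatedVoxelSet, reliability_bins: np.ndarray | None = None
) -> CorrectionEvaluation:
    """Group voxels by test-retest NSE and summarize each statistic per bin.

    Empty bins are reported as rows of NaNs rather than raised.
    """
    if reliability_bins is None:
        reliability_bins = np.arange(0.0, 1.0001, 0.1)
    stats = voxel_statistics(vox)
    edges = np.asarray(reliability_bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = stats[(stats.test_retest_nse >= lo) & (stats.test_retest_nse < hi)]
        row = {"bin_lo": lo, "bin_hi": hi, "n_voxels": len(sel)}
        for col in ("noisy_nse", "corrected_nse", "true_nse", "test_retest_nse"):
            if len(sel):
                vals = sel[col].dropna().to_numpy()
                row[f"{col}_median"] = float(np.median(vals)) if vals.size else np.nan
                row[f"{col}_lo68"] = float(np.percentile(vals, 16)) if vals.size else np.nan
                row[f"{col}_hi68"] = float(np.percentile(vals, 84)) if vals.size else np.nan
            else:
                row[f"{col}_median"] = row[f"{col}_lo68"] = row[f"{col}_hi68"] = np.nan
        rows.append(row)
    return CorrectionEvaluation(pd.DataFrame(rows), edges)


# ----------------------------------------------------------------------
def generate_synthetic_sound(
    kind: str,
    duration: float,
    seed: int = 0,
    sample_rate: float = 4000.0,
    am_rate: float = 4.0,
    f0: float = 300.0,
    burst_rate: float = 3.0,
) -> AudioSignal:
    """Deterministic structured test sounds.

    * ``am_harmonic``: harmonic complex on ``f0`` with 1/h harmonic rolloff,
      sinusoidally amplitude-modulated at ``am_rate`` Hz (dominant temporal
      modulation) on top of a slow random level contour, with a regular
      spectral-line spacing that provides spectral-modulation content.
    * ``noise_burst``: broadband noise gated by raised-cosine bursts at
      ``burst_rate`` Hz with jittered amplitudes.
    * ``chirped_texture``: a sparse sum of log-frequency chirps plus a weak
      noise floor (joint spectrotemporal, i.e. oriented, modulation).
    * ``silence``: all zeros.
    """
    if kind not in SOUND_KINDS:
        raise ValueError(f"kind must be one of {SOUND_KINDS}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if kind == "silence":
        return AudioSignal(np.zeros(n), sample_rate)
    if kind == "am_harmonic":
        nyq = sample_rate / 2
        x = np.zeros(n)
        h = 1
        while h * f0 < 0.95 * nyq:
            x += np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi)) / h
            h += 1
        am = 1.0 + 0.8 * np.sin(2 * np.pi * am_rate * t + rng.uniform(0, 2 * np.pi))
        # slow (sub-Hz) level contour so the low-rate filters see structure
        slow = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
        x *= am * slow
        x += 0.01 * rng.standard_normal(n)
    elif kind == "noise_burst":
        x = rng.standard_normal(n)
        phase = (t * burst_rate) % 1.0
        gate = 0.5 * (1 - np.cos(2 * np.pi * np.clip(phase / 0.4, 0, 1)))
        n_bursts = int(np.ceil(duration * burst_rate))
        amps = rng.uniform(0.3, 1.0, n_bursts)
        gate *= amps[np.minimum((t * burst_rate).astype(int), n_bursts - 1)]
        x *= gate
    else:  # chirped_texture
        x = 0.05 * rng.standard_normal(n)
        n_chirps = max(4, int(duration * 3))
        for _ in range(n_chirps):
            t0 = rng.uniform(0, duration * 0.9)
            dur = rng.uniform(0.2, 0.8)
            sel = (t >= t0) & (t < t0 + dur)
            if not sel.any():
                continue
            tt = t[sel] - t0
            f_start = rng.uniform(100, sample_rate / 8)
            octaves_per_s = rng.choice([-2.0, -1.0, 1.0, 2.0])
            phase = 2 * np.pi * f_start * (2 ** (octaves_per_s * tt) - 1) / (
                octaves_per_s * np.log(2)
            )
            env = np.sin(np.pi * tt / dur) ** 2
            x[sel] += env * np.sin(phase)
    x = x / np.sqrt(np.mean(x**2))
    return AudioSignal(x, sample_rate)
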
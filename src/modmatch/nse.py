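"""Normalized squared error (NSE) and its noise-corrected relatives.

The NSE between two response vectors is the mean squared error divided by an
estimate of its expected value under independence:

    NSE(x, y) = mu((x - y)^2) / (mu(x^2) + mu(y^2) - 2 mu(x) mu(y))

It is 0 when the responses are identical and has expectation ~1 for
independent responses, and is invariant to a joint affine rescaling.

Measured responses are modeled as signal plus zero-mean noise that is
independent across repetitions.  The cross-product and means of the signal
are unbiased by noise and are estimated directly from the data (averaging
the available repetition pairings); the signal powers are biased upward by
the noise power, which is estimated as half the power of the residual
between two repetitions and subtracted off.  Two noise models are supported:
``separate`` (each condition has >= 2 repetitions and its own noise
estimate) and ``equal_from_x`` (condition y was measured once; its noise
power is assumed equal to x's and taken from x's residual).

All estimators accept 1-D vectors or 2-D arrays (units x items, statistics
taken along the last axis) so that large simulated voxel sets can be
processed vectorized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

NOISE_MODELS = ("equal_from_x", "separate")


def _mu(a):
    return np.mean(a, axis=-1)


def nse(x, y):
    """Raw normalized squared error between two equal-length responses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("nse requires equally shaped inputs")
    if x.shape[-1] < 2:
        raise ValueError("nse requires at least 2 items")
    num = _mu((x - y) ** 2)
    den = _mu(x**2) + _mu(y**2) - 2 * _mu(x) * _mu(y)
    if np.ndim(den) == 0:
        if den == 0:
            raise ValueError("NSE undefined: both inputs are constant")
        return float(num / den)
    out = np.full(den.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


@dataclass
class PairedRepeatedResponses:
    """Responses of measurement units to two sound sets with repetitions.

    ``x_reps`` / ``y_reps`` are lists of response arrays; each array has the
    items (sounds) on its last axis.  With more than two repetitions, the
    repetitions are averaged into two interleaved (odd/even) splits before
    noise correction.
    """

    x_reps: list
    y_reps: list

    def __post_init__(self):
        self.x_reps = [np.asarray(r, dtype=float) for r in self.x_reps]
        self.y_reps = [np.asarray(r, dtype=float) for r in self.y_reps]
        if not self.x_reps or not self.y_reps:
            raise ValueError("each condition needs at least one repetition")
        shapes = {r.shape for r in self.x_reps} | {r.shape for r in self.y_reps}
        if len(shapes) != 1:
            raise ValueError("all repetition arrays must share one shape")

    @property
    def n_items(self) -> int:
        return self.x_reps[0].shape[-1]

    @staticmethod
    def _two_splits(reps):
        if len(reps) <= 2:
            return list(reps)
        stack = np.stack(reps)
        return [stack[0::2].mean(axis=0), stack[1::2].mean(axis=0)]

    def x_splits(self):
        return self._two_splits(self.x_reps)

    def y_splits(self):
        return self._two_splits(self.y_reps)


@dataclass
class _CorrectedMoments:
    mu_sx: np.ndarray
    mu_sy: np.ndarray
    mu_sx2: np.ndarray
    mu_sy2: np.ndarray
    mu_sxsy: np.ndarray

    @property
    def var_sx(self):
        return self.mu_sx2 - self.mu_sx**2

    @property
    def var_sy(self):
        return self.mu_sy2 - self.mu_sy**2

    @property
    def cov(self):
        return self.mu_sxsy - self.mu_sx * self.mu_sy


def _corrected_moments(reps: PairedRepeatedResponses, noise_model: str) -> _CorrectedMoments:
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
    xs = reps.x_splits()
    ys = reps.y_splits()
    if len(xs) < 2:
        raise ValueError("noise correction requires >= 2 repetitions of condition x")
    if noise_model == "separate" and len(ys) < 2:
        raise ValueError("noise_model='separate' requires >= 2 repetitions of condition y")
    x1, x2 = xs
    mu_sx = 0.5 * (_mu(x1) + _mu(x2))
    mu_sy = np.mean([_mu(y) for y in ys], axis=0)
    mu_sxsy = np.mean([_mu(xi * yj) for xi in xs for yj in ys], axis=0)
    noise_x = 0.5 * _mu((x1 - x2) ** 2)  # estimate of E[n_x^2]
    mu_sx2 = 0.5 * (_mu(x1**2) + _mu(x2**2)) - noise_x
    if noise_model == "separate":
        y1, y2 = ys
        mu_sy2 = 0.5 * (_mu(y1**2) + _mu(y2**2)) - 0.5 * _mu((y1 - y2) ** 2)
    else:
        mu_sy2 = np.mean([_mu(y**2) for y in ys], axis=0) - noise_x
    return _CorrectedMoments(mu_sx, mu_sy, mu_sx2, mu_sy2, mu_sxsy)


def noise_corrected_nse(reps: PairedRepeatedResponses, noise_model: str = "equal_from_x"):
    """NSE of the underlying signals, corrected for measurement noise.

    May leave [0, 1] in small samples.  A nonpositive corrected denominator
    makes the estimate unreliable; the value is still returned, with a
    warning.
    """
    m = _corrected_moments(reps, noise_model)
    num = m.mu_sx2 + m.mu_sy2 - 2 * m.mu_sxsy
    den = m.mu_sx2 + m.mu_sy2 - 2 * m.mu_sx * m.mu_sy
    if np.ndim(den) == 0:
        if den <= 0:
            warnings.warn("corrected NSE denominator <= 0; estimate is unreliable")
            if den == 0:
                return float("nan")
        return float(num / den)
    out = np.full(np.shape(den), np.nan)
    ok = den != 0
    out[ok] = np.asarray(num)[ok] / np.asarray(den)[ok]
    return out


def corrected_correlation(reps: PairedRepeatedResponses, noise_model: str = "equal_from_x"):
    """Pearson correlation of the underlying signals.

    Unbiased covariance divided by the square roots of the noise-corrected
    variances.  Raises when a corrected variance is nonpositive.
    """
    m = _corrected_moments(reps, noise_model)
    var_sx, var_sy = m.var_sx, m.var_sy
    if np.ndim(var_sx) == 0:
        if var_sx <= 0 or var_sy <= 0:
            raise ValueError("corrected correlation undefined: nonpositive corrected variance")
        return float(m.cov / np.sqrt(var_sx * var_sy))
    out = np.full(np.shape(var_sx), np.nan)
    ok = (var_sx > 0) & (var_sy > 0)
    out[ok] = np.asarray(m.cov)[ok] / np.sqrt(var_sx[ok] * var_sy[ok])
    return out


def corrected_sd_ratio(reps: PairedRepeatedResponses, noise_model: str = "equal_from_x"):
    """sd(signal_y) / sd(signal_x) after noise-correcting both variances."""
    m = _corrected_moments(reps, noise_model)
    var_sx, var_sy = m.var_sx, m.var_sy
    if np.ndim(var_sx) == 0:
        if var_sx <= 0 or var_sy < 0:
            raise ValueError("corrected SD ratio undefined: nonpositive corrected variance")
        return float(np.sqrt(var_sy / var_sx))
    out = np.full(np.shape(var_sx), np.nan)
    ok = (var_sx > 0) & (var_sy >= 0)
    out[ok] = np.sqrt(np.asarray(var_sy)[ok] / np.asarray(var_sx)[ok])
    return out


def test_retest_nse(reps_list):
    """Raw NSE between two repetitions (or odd/even splits) of one condition."""
    splits = PairedRepeatedResponses._two_splits([np.asarray(r, float) for r in reps_list])
    if len(splits) < 2:
        raise ValueError("test-retest NSE requires >= 2 repetitions")
    return nse(splits[0], splits[1])


@dataclass
class SimilarityReport:
    nse_raw: float
    nse_corrected: float
    corrected_correlation: float
    corrected_sd_ratio: float
    test_retest_nse_x: float
    test_retest_nse_y: float
    reliability_pass: bool
    clipped: bool = False


def similarity_report(
    reps: PairedRepeatedResponses,
    noise_model: str = "equal_from_x",
    reliability_threshold: float = 0.4,
    clip_unit_interval: bool = False,
) -> SimilarityReport:
    """Per-unit summary of the raw and noise-corrected similarity measures.

    ``reliability_pass`` flags units whose test-retest NSE is below the
    threshold (0.4 by default), the regime in which correction is
    well-behaved.  Corrected values are reported unclipped unless
    ``clip_unit_interval`` is set.
    """
    xs = reps.x_splits()
    ys = reps.y_splits()
    raw = nse(np.mean(xs, axis=0), np.mean(ys, axis=0))
    corrected = noise_corrected_nse(reps, noise_model)
    try:
        corr = corrected_correlation(reps, noise_model)
    except ValueError:
        corr = float("nan")
    try:
        sd_ratio = corrected_sd_ratio(reps, noise_model)
    except ValueError:
        sd_ratio = float("nan")
    trt_x = nse(xs[0], xs[1]) if len(xs) >= 2 else float("nan")
    trt_y = nse(ys[0], ys[1]) if len(ys) >= 2 else float("nan")
    reliability = trt_x if np.isnan(trt_y) else max(trt_x, trt_y)
    clipped = False
    if clip_unit_interval and np.isfinite(corrected):
        new = float(np.clip(corrected, 0.0, 1.0))
        clipped = new != corrected
        corrected = new
    return SimilarityReport(
        nse_raw=raw,
        nse_corrected=corrected,
        corrected_correlation=corr,
        corrected_sd_ratio=sd_ratio,
        test_retest_nse_x=trt_x,
        test_retest_nse_y=trt_y,
        reliability_pass=bool(reliability < reliability_threshold),
        clipped=clipped,
    )
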
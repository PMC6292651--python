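# Methods

This note documents the models and procedures implemented in `modmatch`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Two-stage auditory model

**Cochlear stage.** The waveform is decomposed by bandpass filters whose
frequency responses are half-cycle cosines on the ERB_N scale, with centers
equally spaced between `f_lo` and `f_hi` (defaults 20 Hz and 10 kHz, 120
filters) and adjacent filters overlapping by 87.5%. The ERB_N scale is
realized with the Glasberg–Moore map `E(f) = 21.4 log10(0.00437 f + 1)`. An
87.5% overlap means each half-cosine spans eight center spacings on the ERB
axis, i.e. a 4x-overcomplete bank; the gains are renormalized so that the
squared gains sum to one (the normalization constant is `sqrt(width / (2
spacing)) = 2`). Lowpass and highpass *completion* filters are added at the
band edges so that the squared-gain tiling holds exactly from DC to Nyquist;
they carry edge energy during reconstruction but are not counted among the
bandpass filters and produce no cochleagram channels. The audio sample rate
default is 20 kHz, the minimal rate whose Nyquist reaches the 10 kHz upper
band edge.

Per channel, the Hilbert envelope of the subband is raised to the power 0.3
(static compressive nonlinearity) and downsampled to the envelope rate
(default 400 Hz) with `scipy.signal.resample_poly` — a linear-phase polyphase
Kaiser-window FIR lowpass with cutoff at the envelope Nyquist (200 Hz at the
default rate) whose group delay is compensated, so the operation is
effectively zero-phase; residual negative ringing is clipped to zero. The
cochleagram is then interpolated from the ERB axis to a logarithmic frequency
axis at 24 channels/octave so spectral modulation can be expressed in
cycles/octave. The log grid starts at `f_lo`, steps by `2^(1/24)`, and ends
at the smallest grid point at or above `f_hi`; with the defaults this gives
217 channels. Interpolation is cubic in log2-frequency per time slice,
clamped at the source band edges and clipped at zero for nonnegative inputs.

**Inversion.** A (possibly modified) cochleagram is mapped back to a waveform
by clipping negatives to zero, undoing the compression (power `1/0.3`),
upsampling the envelopes to the audio rate, multiplying by the cosine of each
subband's analytic phase taken from a reference waveform (the previous
iteration's output during synthesis), refiltering each subband with its
half-cosine gain, and summing. Because the squared gains tile, the unmodified
round trip is nearly exact for signals whose subband envelopes are
representable at the envelope rate: harmonic complexes and chirp textures
round-trip with waveform correlation above 0.99. For stationary broadband
noise the top-channel envelopes fluctuate faster than the envelope Nyquist
and the round trip saturates near r ≈ 0.98 — a property of the envelope-rate
representation itself, not of the implementation, and the reason the
fidelity tests use spectrally dense structured sounds.

**Modulation stage.** Second-stage filters act on the log-axis cochleagram:

* temporal filters — causal gammatones `(λ_t b_r t)^2 e^{-3.5 λ_t b_r t}
  sin(2π b_r t)` with best rates 0.5–128 Hz in octave steps (λ_t = 1;
  λ_t = 0.5 gives the half-bandwidth variant), applied along time;
* spectral filters — Mexican-hat wavelets defined directly in the
  spectral-modulation Fourier domain as `ω² e^{-(ω/b_s)²}`, best scales
  0.25–8 cycles/octave (the variable-bandwidth variant is a Morlet
  `e^{-(2 λ_s b_s f)²} cos(2π b_s f)`, instantiated from its closed-form
  transform), applied along frequency;
* oriented spectrotemporal filters — outer products of the 1-D transfers on
  the 2-D FFT grid, with one quadrant pair zeroed: upward-selective filters
  zero the quadrants where temporal and spectral modulation frequencies share
  a sign, downward-selective the other pair (the labeling of the two
  quadrant pairs as up/down is conventional; the mirror choice only relabels
  them). DC and Nyquist lines are never zeroed. Each quadrant pair is
  symmetric under joint frequency negation, so the masked transfers remain
  Hermitian and all filtered cochleagrams are real.

The standard full bank comprises 108 oriented filters (9 rates x 6 scales x
2 orientations), 15 single-orientation crossings with the temporal/spectral
DC filters, all temporal-only filters (including two very low best rates,
0.125 and 0.25 Hz, which prevent the synthesis from clumping energy in time)
and all spectral-only filters, the two DC filters, and the unfiltered
cochleagram. Every transfer is normalized to unit peak gain so that best
rate/scale sensitivity is equal across the bank, and the DC bin of every
bandpass transfer is set exactly to zero (the sampled gammatone otherwise
leaks a small DC gain, and exact conjugate-division reconstruction would
resurrect the channel means through that leakage, defeating the purpose of
the dedicated DC filters).

Filtering is circular in the 2-D FFT domain after padding the cochleagram
with its global mean value by three periods of the slowest temporal filter
in time (24 s for the full bank) and two periods of the coarsest spectral
filter in frequency (8 octaves). Padded grid sizes are rounded up to
FFT-efficient lengths, with the extra samples carrying the same padding
value; unpadding slices are recorded exactly. Reconstruction multiplies each
filtered cochleagram's spectrum by the conjugate transfer, sums, and divides
by the summed filter power, which is an exact inverse wherever the summed
power is nonzero; bins below `1e-10 x max` summed power (unreachable for
standard banks, a guard for random variants) are zeroed.

## Model-matching synthesis

Synthesis starts from Gaussian white noise with the natural sound's RMS and
duration, and iterates: analyze → filter → histogram-match every frequency
channel of every filtered cochleagram to the natural sound's channels →
reconstruct a cochleagram → histogram-match its channels → invert to a
waveform using the previous iteration's subband phases. Histogram matching
reassigns the target's sorted values to the source's rank positions, so it
imposes the target's full value distribution — and therefore every
time-averaged point-wise statistic — exactly at the step where it is
applied; overlap between filters partially undoes the match on reanalysis,
and 100 iterations give good convergence. Matching is applied twice per
feature, first over the entire padded extent and then over just the
unpadded portion, so the stimulus region ends up well matched; on the first
iteration the cochleagram histograms are additionally matched before the
modulation-domain matching so each channel starts with roughly the right
variance. Target histograms are computed once from the natural sound.

Numerical choices: ties in histogram matching are broken stably by original
index (ties occur in the envelope domain after clipping and in the constant
padding); for the continuous-valued filtered stacks inside the loop, where
ties have measure zero, the faster non-stable sort is used — the result is
deterministic and sorted equality is exact either way. The modulation-domain
loop runs in single precision (matching permutes stored values exactly at
any precision); cochlear analysis and inversion stay in double precision.
Convergence is monitored as the mean absolute difference between the sorted
current and target values per feature (the 1-Wasserstein distance for
equal-length vectors), reported for the padded and unpadded regions.

Match quality is scored by the per-feature time-averaged amplitudes: the
time mean for cochlear features (envelope outputs) and the standard
deviation across time for modulation features. The squared Pearson
correlation of the natural and matched amplitude vectors across all
features, optionally under a bank other than the matching bank
(phase-randomized: per-filter Fourier phases of the windowed impulse
response randomized under a fixed seed, Hermitian symmetry enforced;
half-bandwidth: λ = 0.5), is the r² statistic reported by the workflows.
Features with zero amplitude in both sounds (e.g. the constant temporal-DC
outputs) are dropped from the correlation with a logged count.

## NSE and noise correction

The normalized squared error between response vectors is
`μ((x−y)²) / (μ(x²) + μ(y²) − 2 μ(x) μ(y))`: zero for identical responses,
expectation ≈ 1 for independent ones, invariant to joint affine rescaling.
Measured responses are modeled as signal plus zero-mean noise independent
across repetitions. Signal means and the signal cross-product are unbiased
and estimated by averaging the available repetition pairings; signal powers
are corrected by subtracting half the mean squared residual between two
repetitions. With `separate` noise estimation both conditions need two
repetitions; with `equal_from_x` the second condition's noise power is
assumed equal to the first's and taken from its residual (the design where
only one condition was repeated). Corrected values can leave [0, 1] in small
samples and are reported unclipped (an optional clip flag exists for
map-style summaries); a nonpositive corrected denominator flags the estimate
as unreliable rather than raising. More than two repetitions are averaged
into interleaved odd/even splits before correction. The corrected Pearson
correlation divides the unbiased covariance by the square roots of the
noise-corrected variances (equivalent, in the large-sample limit, to
dividing by the square root of the test-retest correlation), and the
corrected SD ratio is the square root of the corrected variance ratio; both
raise on nonpositive corrected variances. Units are conventionally gated at
test-retest NSE < 0.4 (and test-retest r > 0.4 for correlations), the regime
in which correction is well behaved; both thresholds are exposed parameters.

## Simulations

The voxel simulator draws, per voxel, an SNR weight `b ~ Uniform(0, 1)` and
three measurements `x1 = s_x b + n (1−b)` etc., with iid standard-normal
noise (Laplace optional). Simulation 1 builds the signal pair from a shared
component, `s_x = g c + u_x (1−c)`, `s_y = g c + u_y (1−c)` with
`c ~ Uniform(0, 1)`; Simulation 2 scales one signal, `s_x = g`, `s_y = g c`.
Defaults are 100,000 voxels and 36 items. The evaluation bins voxels by
test-retest NSE (0.1-wide bins over [0, 1] by default; edges were not
prescribed) and reports the median and central 68% of the noisy, corrected,
true and test-retest NSE per bin. The validity criterion is the per-voxel
median residual `corrected − true` within ±0.05 in every bin below
test-retest NSE 0.4, together with monotone growth of the uncorrected bias
across bins.

The synthetic sound families (`am_harmonic`, `noise_burst`,
`chirped_texture`, `silence`) are package inventions that stand in for
recorded natural sounds so the full pipeline is testable without external
audio. They have documented modulation content (a dominant AM rate, a burst
rate, oriented chirps) so filter-level assertions are possible, but they are
stationary, noise-free, and far simpler than natural recordings: passing
tests demonstrate the algorithmic contracts (exact matching, convergence,
bias removal), not perceptual adequacy on real-world audio.

## Encoding evaluation

Voxel responses are modeled as weighted sums of the time-averaged feature
amplitudes. The design matrix z-scores features across sounds, rescales the
cochlear and modulation blocks to equal Frobenius norm, and appends an
unpenalized bias column; the temporal-DC filter (zero variance across time)
and, for the full model, the 1-D temporal-only/spectral-only features are
excluded as predictors. With the full enumerations this gives 27,559 /
2,170 / 1,736 / 217 predictors for the spectrotemporal / temporal /
spectral / cochlear models. Ridge regression is solved from the SVD of the
train-centered design (the filter-factor form, identical to kernel ridge
when features outnumber sounds). Evaluation uses 4 outer folds (9 test
sounds each of 36) and, within each 27-sound training set, 4 inner folds of
7/7/7/6 sounds that select the penalty from the octave-spaced grid 2^-100 …
2^100 (201 values) by the noise-corrected NSE of the inner predictions,
each inner fold weighted equally; predictions fit separately from each
response repetition supply the two prediction samples the correction needs.
All standardization statistics come from training folds only, and fold
assignment is deterministic under a recorded seed. Cross-prediction reuses
the same protocol with weights learned on one stimulus set and evaluated on
the other. Reconstruction weights mapping voxel responses to component
response profiles are learned by ridge with 5-fold CV over the same grid
(selection by prediction NSE on left-out sounds); a temporal-SNR > 30 voxel
inclusion rule is exposed as a parameter.

## Problem sizes used in the bundled runs

The demonstration/acceptance workflow runs the synthesis at a reduced
configuration chosen once as the package's desk scale: 4 kHz audio over
20 Hz–2 kHz (40 ERB channels), 100 Hz envelope rate, 24 channels/octave log
axis (161 channels), rates 2–32 Hz plus low rates 0.5/1 Hz, scales 0.5–8
cycles/octave, three 4-s fixture sounds, 100 iterations. The bank structure
(oriented pairs, DC crossings, 1-D filters, two low rates, unfiltered
cochleagram — 75 filters) mirrors the full model; padding follows the same
period rules (6 s, 4 octaves). Filter-count and padding checks always use
the full-scale enumeration. Simulation checks use the full 100,000-voxel
size; encoding checks use planted linear voxels on reduced feature sets
(tens of features), where recovery is exact up to regularization.

## Known limitations

* No middle-ear transfer, adaptation, dynamic compression, binaural
  processing, or phase-locked fine-structure modulation analysis.
* The envelope-rate representation bounds reconstruction fidelity for
  stationary broadband noise (see above).
* The envelope-of-filter-output matching variant and perceptual evaluation
  of synthesized sounds are out of scope, as are all spatial/surface
  analyses of real neural data.
* Corrected similarity estimates are undefined or unstable for units with
  nonpositive corrected variance; they are flagged, not silently dropped.
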
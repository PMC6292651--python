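"""Modulation filters: transfer functions, bank enumeration, apply/reconstruct."""

import numpy as np
import pytest
from scipy.fft import fft, ifft2, irfft2, rfft2

from modmatch.cochlear import Cochleagram
from modmatch.modulation import (
    SpectralFilterSpec,
    SpectroTemporalFilter,
    TemporalFilterSpec,
    apply_filterbank,
    bank_transfers,
    build_filterbank,
    filter_transfer_2d,
    random_filterbank,
    reconstruct_cochleagram,
    spectral_transfer_function,
    temporal_impulse_response,
    temporal_transfer_function,
)


def _log_coch(values, env_rate=100.0, cyc_per_oct=24.0, f0=20.0):
    n_ch = values.shape[1]
    freqs = f0 * 2 ** (np.arange(n_ch) / cyc_per_oct)
    return Cochleagram(values, env_rate, freqs, "log", log_resolution=cyc_per_oct)


class TestTemporalFilters:
    def test_peak_gain_at_best_rate(self):
        env_rate, n = 100.0, 4000
        for br in (2.0, 4.0, 8.0):
            H = temporal_transfer_function(TemporalFilterSpec(best_rate=br), env_rate, n)
            freqs = np.fft.fftfreq(n, 1 / env_rate)
            peak = abs(freqs[np.argmax(np.abs(H))])
            assert peak == pytest.approx(br, abs=2 * env_rate / n)

    def test_impulse_response_is_causal(self):
        t = np.linspace(-2, 2, 401)
        h = temporal_impulse_response(TemporalFilterSpec(best_rate=4.0), t)
        assert np.all(h[t < 0] == 0)
        assert np.any(h[t > 0] != 0)

    def test_half_bandwidth_variant_is_narrower(self):
        """-3 dB bandwidth measured numerically on densely sampled FFT
        magnitudes: the lambda_t = 0.5 filter is narrower than lambda_t = 1."""
        env_rate, n = 100.0, 2**14

        def bw(lam):
            H = np.abs(
                temporal_transfer_function(
                    TemporalFilterSpec(best_rate=4.0, bandwidth_factor=lam), env_rate, n
                )
            )
            freqs = np.fft.fftfreq(n, 1 / env_rate)
            pos = freqs >= 0
            above = pos & (H >= np.max(H[pos]) / np.sqrt(2))
            f_above = freqs[above]
            return f_above.max() - f_above.min()

        assert bw(0.5) < bw(1.0)

    def test_dc_filter_passes_only_dc(self):
        H = temporal_transfer_function(TemporalFilterSpec(is_dc=True), 100.0, 64)
        assert H[0] == 1.0
        assert np.all(H[1:] == 0)

    def test_too_few_samples_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="need >="):
            temporal_transfer_function(TemporalFilterSpec(best_rate=0.5), 100.0, 100)


class TestSpectralFilters:
    def test_mexican_hat_peaks_at_best_scale(self):
        """Calculus oracle: d/dw [w^2 exp(-(w/b)^2)] = 0 at w = b."""
        n, res = 4096, 24.0
        for bs in (1.0, 2.0, 4.0):
            H = np.abs(spectral_transfer_function(SpectralFilterSpec(best_scale=bs), res, n))
            omega = np.abs(np.fft.fftfreq(n, 1 / res))
            assert omega[np.argmax(H)] == pytest.approx(bs, abs=2 * res / n)

    def test_no_dc_leakage(self):
        H = spectral_transfer_function(SpectralFilterSpec(best_scale=2.0), 24.0, 512)
        assert H[0] == 0

    def test_signal_domain_kernel_transforms_to_stated_gain(self):
        """The FFT of the sampled Mexican-hat kernel matches the closed-form
        frequency response up to a global normalization."""
        bs, res, n = 1.0, 256.0, 2**14  # fine sampling over many octaves
        f = (np.arange(n) - n // 2) / res
        u = bs * np.pi * f
        kernel = (1 - 2 * u**2) * np.exp(-(u**2))
        dft = np.abs(fft(kernel))
        omega = np.abs(np.fft.fftfreq(n, 1 / res))
        analytic = omega**2 * np.exp(-((omega / bs) ** 2))
        dft /= dft.max()
        analytic /= analytic.max()
        keep = analytic > 1e-6
        assert np.max(np.abs(dft[keep] - analytic[keep]) / analytic[keep]) < 1e-3

    def test_morlet_variant_is_narrower_at_half_bandwidth(self):
        n, res = 4096, 24.0
        H1 = np.abs(spectral_transfer_function(
            SpectralFilterSpec(best_scale=2.0, bandwidth_factor=0.5), res, n))
        omega = np.abs(np.fft.fftfreq(n, 1 / res))
        # narrower: less relative gain one octave away from the best scale
        at_best = H1[np.argmin(np.abs(omega - 2.0))]
        at_octave = H1[np.argmin(np.abs(omega - 4.0))]
        assert at_octave / at_best < 0.5


class TestBankEnumeration:
    def test_printed_filter_counts(self):
        bank = build_filterbank("spectrotemporal")
        assert len(bank.oriented_filters()) == 108  # 9 rates x 6 scales x 2
        dc_crossed = [
            f for f in bank.filters
            if f.orientation == "none" and f.temporal is not None and f.spectral is not None
        ]
        assert len(dc_crossed) == 15  # 9 rate x spectral-DC + 6 temporal-DC x scale

    def test_low_rates_present_in_temporal_banks(self):
        for kind in ("temporal", "spectrotemporal"):
            bank = build_filterbank(kind)
            rates = {
                f.temporal.best_rate
                for f in bank.filters
                if f.temporal is not None and not f.temporal.is_dc and f.spectral is None
            }
            assert {0.125, 0.25} <= rates

    def test_cochlear_kind_has_no_modulation_filters(self):
        bank = build_filterbank("cochlear")
        assert bank.n_filters == 1
        assert bank.filters[0].is_cochlear_passthrough
        assert bank.include_unfiltered_cochleagram

    def test_padding_follows_filter_periods(self):
        bank = build_filterbank("spectrotemporal")
        assert bank.time_padding_seconds() == 24.0  # 3 x 1/0.125 Hz
        assert bank.freq_padding_octaves() == 8.0  # 2 x 1/0.25 cyc/oct

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="model_kind"):
            build_filterbank("wavelet")


class TestOrientation:
    @pytest.fixture(scope="class")
    def oriented_pair(self):
        kw = dict(n_times=200, n_channels=96, env_sample_rate=100.0, cycles_per_octave=24.0)
        t = TemporalFilterSpec(best_rate=8.0)
        s = SpectralFilterSpec(best_scale=2.0)
        up = filter_transfer_2d(SpectroTemporalFilter(t, s, "up"), **kw)
        down = filter_transfer_2d(SpectroTemporalFilter(t, s, "down"), **kw)
        unoriented = filter_transfer_2d(SpectroTemporalFilter(t, s, "none"), **kw)
        return up, down, unoriented

    def test_up_down_are_mirror_images(self, oriented_pair):
        up, down, _ = oriented_pair
        # negating the temporal frequency axis (rows 1..n reversed) swaps the
        # orientations on the half spectral grid
        flipped = np.abs(down[np.r_[0, np.arange(down.shape[0] - 1, 0, -1)]])
        np.testing.assert_allclose(np.abs(up), flipped, atol=1e-12)

    def test_power_partition_off_axes(self, oriented_pair):
        up, down, unoriented = oriented_pair
        power_sum = np.abs(up) ** 2 + np.abs(down) ** 2
        target = np.abs(unoriented) ** 2
        interior = np.ones_like(target, dtype=bool)
        interior[0, :] = False  # temporal DC row
        interior[100, :] = False  # temporal Nyquist row (n_times even)
        interior[:, 0] = False  # spectral DC column
        interior[:, -1] = False  # spectral Nyquist column
        np.testing.assert_allclose(power_sum[interior], target[interior], atol=1e-12)

    def test_dc_and_nyquist_never_zeroed(self, oriented_pair):
        up, down, unoriented = oriented_pair
        for H in (up, down):
            assert np.array_equal(H[0, :] == 0, unoriented[0, :] == 0)
            assert np.array_equal(H[:, 0] == 0, unoriented[:, 0] == 0)
            assert np.array_equal(H[:, -1] == 0, unoriented[:, -1] == 0)


def test_peak_gain_equal_across_bank(tiny_analysis):
    bank = tiny_analysis.build_modulation_bank("spectrotemporal")
    transfers = bank_transfers(bank, 512, 128, 50.0, 12.0)
    peaks = np.array([np.max(np.abs(H)) for H in transfers])
    np.testing.assert_allclose(peaks, 1.0, atol=1e-6)


class TestApplyReconstruct:
    @pytest.fixture(scope="class")
    def small_coch(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.1, 1.0, (120, 60)) + np.sin(
            np.linspace(0, 8 * np.pi, 120)
        )[:, None] ** 2
        return _log_coch(values, env_rate=50.0, cyc_per_oct=12.0)

    @pytest.fixture(scope="class")
    def small_bank(self, tiny_analysis):
        return tiny_analysis.build_modulation_bank("spectrotemporal")

    def test_erb_axis_input_rejected(self, small_coch, small_bank):
        erb = Cochleagram(small_coch.values, 50.0, small_coch.freq_axis, "erb")
        with pytest.raises(ValueError, match="log"):
            apply_filterbank(erb, small_bank)

    def test_temporal_dc_output_constant_and_equal_to_mean(self, small_coch, small_bank):
        stacks = apply_filterbank(small_coch, small_bank)
        idx = next(
            i for i, f in enumerate(small_bank.filters)
            if f.temporal is not None and f.temporal.is_dc and f.spectral is None
        )
        dc_stack = stacks.stacks[idx]
        np.testing.assert_allclose(
            dc_stack, np.broadcast_to(dc_stack[0], dc_stack.shape), atol=1e-9
        )
        # each channel's DC output equals that padded channel's mean
        padded_mean_first_channel = dc_stack[0, 0]
        assert padded_mean_first_channel == pytest.approx(
            np.mean(
                np.concatenate([
                    small_coch.values[:, 0],
                    np.full(stacks.stacks.shape[1] - small_coch.n_times,
                            small_coch.global_mean()),
                ])
            ),
            rel=1e-9,
        )

    def test_impulse_response_matches_direct_convolution(self):
        """Convolution oracle: filtering an impulse cochleagram reproduces
        the circular convolution with the filter's space-domain kernel."""
        n_t, n_f = 128, 64
        values = np.zeros((n_t, n_f))
        coch = _log_coch(values, env_rate=50.0, cyc_per_oct=12.0)
        bank = build_filterbank(
            "spectrotemporal", rates=(4.0,), scales=(2.0,), low_rates=(4.0,)
        )
        padded_shape = None
        stacks = apply_filterbank(coch, bank)
        padded_shape = stacks.stacks.shape[1:]
        impulse = np.zeros(padded_shape)
        impulse[10, 5] = 1.0
        # impulse applied directly on the padded grid
        transfers = bank_transfers(bank, *padded_shape, 50.0, 12.0)
        for H in transfers:
            via_fft = irfft2(H * rfft2(impulse), s=padded_shape)
            # oracle: kernel from the full transfer, circularly shifted
            H_full = np.zeros(padded_shape, dtype=complex)
            H_full[:, : H.shape[1]] = H
            for j in range(1, padded_shape[1] // 2 + (padded_shape[1] % 2)):
                H_full[:, -j] = np.conj(np.roll(H[:, j][::-1], 1))
            kernel = ifft2(H_full).real
            direct = np.roll(np.roll(kernel, 10, axis=0), 5, axis=1)
            np.testing.assert_allclose(via_fft, direct, atol=1e-10)

    def test_apply_then_reconstruct_is_identity(self, small_coch, small_bank):
        stacks = apply_filterbank(small_coch, small_bank)
        rec = reconstruct_cochleagram(stacks)
        scale = np.max(np.abs(small_coch.values))
        assert np.max(np.abs(rec.values - small_coch.values)) / scale < 1e-8

    @pytest.mark.parametrize("kind", ["temporal", "spectral", "cochlear"])
    def test_identity_holds_for_all_model_kinds(self, small_coch, tiny_analysis, kind):
        bank = tiny_analysis.build_modulation_bank(kind)
        rec = reconstruct_cochleagram(apply_filterbank(small_coch, bank))
        scale = np.max(np.abs(small_coch.values))
        assert np.max(np.abs(rec.values - small_coch.values)) / scale < 1e-8

    def test_reconstruction_is_linear(self, small_coch, small_bank):
        stacks = apply_filterbank(small_coch, small_bank)
        rec1 = reconstruct_cochleagram(stacks)
        stacks.stacks *= 2.0
        rec2 = reconstruct_cochleagram(stacks)
        np.testing.assert_allclose(rec2.values, 2 * rec1.values, atol=1e-10)

    def test_removing_dc_filters_loses_the_mean(self, small_coch, small_bank):
        """Without the DC filters the reconstructed global mean collapses
        toward zero, which is why they are required for reconstruction."""
        stacks = apply_filterbank(small_coch, small_bank)
        keep = [
            i for i, f in enumerate(small_bank.filters)
            if not (
                (f.temporal is not None and f.temporal.is_dc)
                or (f.spectral is not None and f.spectral.is_dc)
                or f.is_cochlear_passthrough
            )
        ]
        stacks.stacks = stacks.stacks[keep]
        stacks.bank = build_filterbank(
            "spectrotemporal", rates=small_bank.rates, scales=small_bank.scales,
            low_rates=small_bank.low_rates,
        )
        stacks.bank.filters = [small_bank.filters[i] for i in keep]
        rec = reconstruct_cochleagram(stacks)
        assert abs(rec.values.mean()) < 0.05 * abs(small_coch.values.mean())


class TestRandomBank:
    def test_same_seed_reproduces_kernels(self):
        b1 = random_filterbank(seed=3, n_filters=5)
        b2 = random_filterbank(seed=3, n_filters=5)
        for (w1, t1, f1), (w2, t2, f2) in zip(b1.random_kernels, b2.random_kernels):
            np.testing.assert_array_equal(w1, w2)
            assert (t1, f1) == (t2, f2)

    def test_kernel_weights_are_gaussian(self):
        bank = random_filterbank(seed=11, n_filters=400)
        from scipy import stats

        all_w = np.concatenate([w.ravel() for w, _, _ in bank.random_kernels])
        # standardize and test normality on a large sample
        stat, p = stats.kstest(all_w, "norm")
        assert p > 0.01

    def test_extents_within_configured_ranges(self):
        bank = random_filterbank(
            seed=2, n_filters=50, time_extent_range=(0.2, 1.0), freq_extent_range=(0.5, 2.0)
        )
        tes = [t for _, t, _ in bank.random_kernels]
        fes = [f for _, _, f in bank.random_kernels]
        assert min(tes) >= 0.2 and max(tes) <= 1.0
        assert min(fes) >= 0.5 and max(fes) <= 2.0
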
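"""Tensorization: STFT oracle equivalence, canonical-grid interpolation,
stacking, input forms and physical calibration."""

import numpy as np
import pytest
from scipy.signal import get_window

from eegauth import represent, synth
from eegauth.model import KernelSpec
from eegauth.represent import (Calibration, canonical_grid,
                               kernel_physical_extent, stack_tensor,
                               stft_spectrogram, to_input_form)


def dft_oracle(x, nperseg=64, noverlap=57, nfft=256, n_freq=31):
    """Brute-force windowed DFT power: no FFT, direct complex sums."""
    win = get_window("hamming", nperseg)
    hop = nperseg - noverlap
    frames = (len(x) - nperseg) // hop + 1
    out = np.empty((frames, n_freq))
    n = np.arange(nperseg)
    for t in range(frames):
        seg = x[t * hop: t * hop + nperseg] * win
        for f in range(n_freq):
            out[t, f] = np.abs(np.sum(
                seg * np.exp(-2j * np.pi * f * n / nfft))) ** 2
    return out


class TestSTFT:
    def test_matches_direct_dft_oracle(self, rng):
        """Spectrogram equals the brute-force windowed-DFT power to 1e-6
        relative tolerance on random signals."""
        for _ in range(20):
            x = rng.normal(size=205)
            m = stft_spectrogram(x)
            ref = dft_oracle(x)
            np.testing.assert_allclose(m.values, ref, rtol=1e-6,
                                       atol=1e-9 * ref.max())

    def test_zero_input_zero_map(self):
        m = stft_spectrogram(np.zeros(205))
        assert np.all(m.values == 0)

    def test_hop_is_seven(self):
        m = stft_spectrogram(np.ones(205))
        # frame count for hop = 64 - 57 = 7
        assert m.values.shape[0] == (205 - 64) // 7 + 1
        dt = np.diff(m.time_axis)
        np.testing.assert_allclose(dt, 7 / 256 * 1000)

    def test_pure_sine_peak_bin(self):
        t = np.arange(205) / 256
        m = stft_spectrogram(np.sin(2 * np.pi * 8 * t))
        peak_freqs = m.freq_axis[np.argmax(m.values, axis=1)]
        assert np.all(peak_freqs == 8.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            stft_spectrogram(np.zeros(63))


class TestCanonicalGrid:
    def test_output_shape(self, rng):
        m = stft_spectrogram(rng.normal(size=205))
        g = canonical_grid(m)
        assert g.values.shape == (94, 60)

    def test_constant_stays_constant(self):
        raw = represent.TFMap(np.full((21, 31), 3.5),
                              np.linspace(100, 700, 21),
                              np.linspace(0, 30, 31))
        g = canonical_grid(raw)
        np.testing.assert_allclose(g.values, 3.5)

    def test_canonical_input_identity(self):
        t = (np.arange(94) + 0.5) * (800 / 94)
        f = (np.arange(60) + 0.5) * 0.5
        vals = np.random.default_rng(1).random((94, 60))
        g = canonical_grid(represent.TFMap(vals, t, f))
        np.testing.assert_array_equal(g.values, vals)

    def test_insufficient_coverage_raises(self):
        raw = represent.TFMap(np.ones((5, 31)), np.linspace(300, 500, 5),
                              np.linspace(0, 30, 31))
        with pytest.raises(ValueError, match="coverage"):
            canonical_grid(raw)


class TestStackTensor:
    def test_shapes_and_channel_independence(self, small_epochs):
        ts = stack_tensor(small_epochs)
        n = small_epochs.n_trials
        assert ts.values.shape == (n, 16, 94, 60)
        # layer c equals the independent single-channel pipeline
        seg = small_epochs.data[0, 3, small_epochs.times >= 0]
        solo = canonical_grid(stft_spectrogram(seg, small_epochs.fs)).values
        np.testing.assert_allclose(ts.values[0, 3], solo, rtol=1e-5)

    def test_zero_trial_zero_tensor(self):
        times = (np.arange(256) - 51) / 256 * 1000
        ep = synth.EpochSet(np.zeros((1, 16, 256)),
                            np.array(["blank"], dtype=object), times, 256.0)
        ts = stack_tensor(ep)
        assert np.all(ts.values == 0)

    def test_channel_permutation_permutes_layers(self, small_epochs):
        perm = np.random.default_rng(2).permutation(16)
        permuted = synth.EpochSet(small_epochs.data[:, perm],
                                  small_epochs.labels, small_epochs.times,
                                  small_epochs.fs,
                                  tuple(np.array(small_epochs.channels)[perm]))
        a = stack_tensor(small_epochs).values
        b = stack_tensor(permuted).values
        np.testing.assert_allclose(b, a[:, perm], rtol=1e-6)

    def test_energy_scales_quadratically(self, small_epochs):
        """Scaling a trial by a > 0 scales tensor values by a^2."""
        scaled = synth.EpochSet(small_epochs.data * 3.0, small_epochs.labels,
                                small_epochs.times, small_epochs.fs,
                                small_epochs.channels)
        a = stack_tensor(small_epochs).values
        b = stack_tensor(scaled).values
        np.testing.assert_allclose(b, 9.0 * a, rtol=1e-4)

    def test_wrong_channel_count(self, small_epochs):
        times = small_epochs.times
        ep = synth.EpochSet(small_epochs.data[:, :8],
                            small_epochs.labels, times, 256.0,
                            small_epochs.channels[:8])
        with pytest.raises(ValueError, match="16"):
            stack_tensor(ep)


class TestInputForms:
    def test_3d_preserves_shape(self, rng):
        v = rng.random((3, 16, 94, 60))
        out, meta = to_input_form(v, "3d")
        assert out.shape == (3, 16, 94, 60) and meta["form"] == "3d"

    def test_2d_is_channel_mean(self, rng):
        v = rng.random((2, 16, 94, 60))
        out, _ = to_input_form(v, "2d")
        np.testing.assert_allclose(out, v.mean(axis=1))

    def test_1d_of_zero_is_zero(self):
        out, _ = to_input_form(np.zeros((2, 16, 94, 60)), "1d")
        assert out.shape == (2, 16 * 94) and np.all(out == 0)

    def test_unknown_form(self, rng):
        with pytest.raises(ValueError):
            to_input_form(np.zeros((1, 16, 94, 60)), "4d")


class TestCalibration:
    def test_exact_axis_products(self):
        cal = Calibration()
        assert cal.ms_per_pixel * 94 == 800.0
        assert cal.hz_per_pixel * 60 == 30.0

    def test_reported_pixel_scale(self):
        assert Calibration().reported == (8.5, 0.5)

    @pytest.mark.parametrize("kernel,expected", [
        ((3, 3), (25.5, 1.5)),
        ((1, 1), (8.5, 0.5)),
        ((9, 9), (76.5, 4.5)),
        ((5, 3), (42.5, 1.5)),
    ])
    def test_kernel_extents(self, kernel, expected):
        t, f = kernel
        assert kernel_physical_extent(KernelSpec(t, f)) == expected


class TestTensorizer:
    def test_transform_matches_functions(self, small_epochs):
        tf = represent.SpectrogramTensorizer(form="2d")
        out = tf.fit_transform(small_epochs)
        ref, _ = to_input_form(stack_tensor(small_epochs).values, "2d")
        np.testing.assert_allclose(out, ref)
        assert tf.get_params() == {"form": "2d"}
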
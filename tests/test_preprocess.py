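"""Preprocessing chain: filter contracts, re-referencing, epoching,
rejection, blank subtraction and ICA ocular removal."""

import numpy as np
import pytest

from eegauth import preprocess, synth
from eegauth.core import CHANNELS_16, EpochSet, RawRecording


def sine_raw(freq, fs, seconds=8.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (16, 1))
    return RawRecording(data=data, fs=fs)


class TestFilters:
    def test_lowpass_stopband_attenuation(self):
        lp, _ = preprocess.design_filters(256.0)
        assert lp.response_db([40.0])[0] <= -5.0

    def test_lowpass_dc_gain(self):
        lp, _ = preprocess.design_filters(256.0)
        assert abs(lp.response_db([1e-3])[0]) <= 0.5

    def test_passband_ripple_bound(self):
        lp, _ = preprocess.design_filters(256.0)
        freqs = np.linspace(0.1, 20.0, 200)
        assert np.all(lp.response_db(freqs) >= -0.51)
        assert np.all(lp.response_db(freqs) <= 0.01)

    def test_highpass_deep_stop(self):
        _, hp = preprocess.design_filters(256.0)
        assert hp.response_db([0.01])[0] <= -10.0

    def test_stability(self):
        for f in preprocess.design_filters(1024.0):
            assert f.is_stable()

    def test_unmeetable_spec_raises(self):
        with pytest.raises(ValueError):
            preprocess.design_filters(60.0)

    def test_sine_amplitudes(self):
        """A 10 Hz sinusoid survives the zero-phase band-pass (each
        section's 0.5 dB passband deviation doubles forward-backward, so
        the cascade bound is 2 dB); 45 Hz is attenuated >= 5 dB
        (RMS-ratio oracle on filtered sinusoids)."""
        for freq, check in ((10.0, lambda db: abs(db) <= 2.0),
                            (45.0, lambda db: db <= -5.0)):
            raw = sine_raw(freq, 1024.0)
            out = preprocess.bandpass_and_resample(raw)
            mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
            ratio = (np.sqrt(np.mean(out.data[0, mid] ** 2)) /
                     np.sqrt(0.5))           # RMS of unit sine
            assert check(20 * np.log10(ratio))


class TestBandpassResample:
    def test_dc_removed(self):
        raw = RawRecording(data=np.full((16, 4096), 7.0), fs=512.0)
        out = preprocess.bandpass_and_resample(raw)
        assert np.abs(out.data).max() < 0.5

    def test_identity_rate_keeps_samples(self):
        raw = sine_raw(8.0, 256.0, seconds=4.0)
        out = preprocess.bandpass_and_resample(raw)
        assert out.fs == 256.0 and out.n_samples == raw.n_samples

    def test_downsample_preserves_sine(self):
        """8 Hz at 1024 Hz in -> 8 Hz at 256 Hz out within 0.5 dB
        (sine-fit oracle)."""
        raw = sine_raw(8.0, 1024.0)
        out = preprocess.bandpass_and_resample(raw)
        assert out.fs == 256.0
        t = np.arange(out.n_samples) / out.fs
        design = np.column_stack([np.sin(2 * np.pi * 8 * t),
                                  np.cos(2 * np.pi * 8 * t)])
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        coef, *_ = np.linalg.lstsq(design[mid], out.data[0, mid], rcond=None)
        amp_db = 20 * np.log10(np.hypot(*coef))
        assert abs(amp_db) <= 2.0   # zero-phase cascade bound (2 x ripple)

    def test_zero_phase(self):
        """Cross-correlation peak lag between a clean bump and its
        filtered version is 0 samples."""
        fs = 256.0
        t = np.arange(int(4 * fs)) / fs
        bump = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)
        raw = RawRecording(data=np.tile(bump, (16, 1)), fs=fs)
        out = preprocess.bandpass_and_resample(raw)
        xc = np.correlate(out.data[0], bump, mode="full")
        lag = int(np.argmax(xc)) - (len(bump) - 1)
        assert lag == 0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess.bandpass_and_resample(sine_raw(5.0, 128.0))


class TestRereference:
    def test_average_zero_mean(self, rng):
        raw = RawRecording(data=rng.normal(size=(16, 100)), fs=256.0)
        out = preprocess.rereference(raw, "average")
        np.testing.assert_allclose(out.data.mean(axis=0), 0, atol=1e-12)

    def test_idempotent(self, rng):
        raw = RawRecording(data=rng.normal(size=(16, 50)), fs=256.0)
        once = preprocess.rereference(raw, "average")
        twice = preprocess.rereference(once, "average")
        np.testing.assert_allclose(once.data, twice.data)

    def test_none_identity(self, rng):
        raw = RawRecording(data=rng.normal(size=(16, 50)), fs=256.0)
        assert preprocess.rereference(raw, "none") is raw

    def test_unknown_scheme(self, rng):
        raw = RawRecording(data=rng.normal(size=(16, 50)), fs=256.0)
        with pytest.raises(ValueError):
            preprocess.rereference(raw, "laplacian")

    def test_rest_needs_lead_field(self, rng):
        raw = RawRecording(data=rng.normal(size=(16, 50)), fs=256.0)
        with pytest.raises(ValueError, match="lead_field"):
            preprocess.rereference(raw, "rest")


class TestEpoching:
    def test_constant_signal_zero_epochs(self):
        raw = RawRecording(data=np.full((16, 2048), 3.0), fs=256.0,
                           marker_samples=np.array([600, 1200]),
                           marker_labels=("self", "blank"))
        ep = preprocess.epoch_and_baseline(raw)
        np.testing.assert_allclose(ep.data, 0, atol=1e-12)

    def test_baseline_mean_zero(self, rng):
        raw = RawRecording(data=rng.normal(size=(16, 4096)), fs=256.0,
                           marker_samples=np.array([500, 1500, 2500]),
                           marker_labels=("self", "familiar", "stranger"))
        ep = preprocess.epoch_and_baseline(raw)
        base = ep.data[:, :, ep.times < 0]
        np.testing.assert_allclose(base.mean(axis=2), 0, atol=1e-10)

    def test_edge_marker_dropped(self, rng):
        raw = RawRecording(data=rng.normal(size=(16, 2048)), fs=256.0,
                           marker_samples=np.array([10, 1000]),
                           marker_labels=("self", "stranger"))
        with pytest.warns(UserWarning, match="dropped 1"):
            ep = preprocess.epoch_and_baseline(raw)
        assert ep.n_trials == 1 and ep.labels[0] == "stranger"


class TestRejection:
    def make_epochs(self, peaks):
        times = (np.arange(256) - 51) / 256 * 1000
        data = np.zeros((len(peaks), 16, 256))
        for i, p in enumerate(peaks):
            data[i, 0, 100] = p
        return EpochSet(data, np.array(["self"] * len(peaks), dtype=object),
                        times, 256.0)

    def test_threshold(self):
        ep = self.make_epochs([50, 150, 99])
        kept, mask = preprocess.reject_high_amplitude(ep)
        assert mask.tolist() == [True, False, True]
        assert kept.n_trials == 2

    def test_infinite_threshold_identity(self):
        ep = self.make_epochs([50, 150, 99])
        kept, mask = preprocess.reject_high_amplitude(ep, np.inf)
        assert mask.all() and kept.n_trials == 3

    def test_all_rejected_raises(self):
        with pytest.raises(ValueError, match="all"):
            preprocess.reject_high_amplitude(self.make_epochs([500, 400]))

    def test_injected_artifact_fraction(self):
        """~10% injected >100 uV trials are rejected at ~10% rate."""
        cohort = synth.scaled_cohort(2, 20, seed=21, artifact_fraction=0.1,
                                     artifact_amplitude=200.0)
        prof = synth.sample_profile(cohort, 0)
        ep = synth.synthesize_epochs(prof, "stranger", 400)
        _, mask = preprocess.reject_high_amplitude(ep)
        assert 0.05 < np.mean(~mask) < 0.16


class TestBlankSubtract:
    def test_exact_blank_trial_zeroed(self, small_epochs):
        avg = preprocess.blank_average(small_epochs)
        data = np.concatenate([avg[None], small_epochs.data[:1]])
        ep = EpochSet(data, np.array(["self", "blank"], dtype=object),
                      small_epochs.times, small_epochs.fs)
        out = preprocess.blank_baseline_subtract(ep, avg)
        np.testing.assert_allclose(out.data[0], 0, atol=1e-12)

    def test_zero_average_identity(self, small_epochs):
        out = preprocess.blank_baseline_subtract(
            small_epochs, np.zeros(small_epochs.data.shape[1:]))
        names = small_epochs.select(small_epochs.labels != "blank")
        np.testing.assert_array_equal(out.data, names.data)
        assert "blank" not in out.labels

    def test_dc_blank_shifts_names(self, small_epochs):
        dc = np.full(small_epochs.data.shape[1:], 5.0)
        out = preprocess.blank_baseline_subtract(small_epochs, dc)
        names = small_epochs.select(small_epochs.labels != "blank")
        np.testing.assert_allclose(out.data, names.data - 5.0)

    def test_shape_mismatch(self, small_epochs):
        with pytest.raises(ValueError):
            preprocess.blank_baseline_subtract(small_epochs,
                                               np.zeros((16, 10)))


class TestOcularRemoval:
    def test_none_identity(self, small_epochs):
        assert preprocess.remove_ocular(small_epochs, "none") is small_epochs

    def test_ica_removes_injected_source(self, rng):
        """With a known frontal mixing vector, the cleaned data decorrelates
        from the injected artifact time course."""
        n_tr, n_s, fs = 30, 256, 256.0
        times = (np.arange(n_s) - 51) / fs * 1000
        base = rng.normal(size=(n_tr, 16, n_s))
        art = np.zeros((n_tr, n_s))
        for i in range(n_tr):
            c = rng.uniform(100, 600)
            art[i] = 40.0 * np.exp(-0.5 * ((times - c) / 60.0) ** 2)
        topo = np.array([synth._OCULAR_TOPO[c] for c in CHANNELS_16])
        mixed = base + topo[None, :, None] * art[:, None, :]
        ep = EpochSet(mixed, np.array(["self"] * n_tr, dtype=object),
                      times, fs)
        cleaned = preprocess.remove_ocular(ep, "ica",
                                           eog_proxy=art.ravel())
        art_flat = art.ravel()
        for ch in range(16):
            r = np.corrcoef(cleaned.data[:, ch, :].ravel(), art_flat)[0, 1]
            assert abs(r) < 0.2

    def test_idempotent_on_clean_data(self, rng):
        n_tr, n_s = 24, 256
        times = (np.arange(n_s) - 51) / 256 * 1000
        ep = EpochSet(rng.normal(size=(n_tr, 16, n_s)),
                      np.array(["self"] * n_tr, dtype=object), times, 256.0)
        once = preprocess.remove_ocular(ep, "ica", corr_threshold=0.95)
        twice = preprocess.remove_ocular(once, "ica", corr_threshold=0.95)
        rms = np.sqrt(np.mean(once.data ** 2))
        assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 0.05 * rms


class TestPipeline:
    def test_order_recorded(self, profile):
        raw = synth.synthesize_continuous(
            profile, {"self": 6, "familiar": 3, "stranger": 3, "blank": 4})
        epochs, record = preprocess.run_pipeline(raw)
        assert record["order"] == [
            "bandpass_and_resample", "rereference", "epoch_and_baseline",
            "remove_ocular", "reject_high_amplitude",
            "blank_baseline_subtract"]
        assert epochs.n_channels == 16
        assert set(epochs.labels) <= {"self", "familiar", "stranger"}

    def test_channel_order_preserved(self, profile):
        raw = synth.synthesize_continuous(
            profile, {"self": 4, "familiar": 2, "stranger": 2, "blank": 2})
        epochs, _ = preprocess.run_pipeline(raw)
        assert epochs.channels == raw.channels
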
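"""Filtering, resampling, referencing, epoching and artifact rejection."""

import numpy as np
import pytest

from resteeg.exceptions import ConfigError, DataError, SubjectExclusionError
from resteeg.preprocess import (
    PreprocessConfig,
    bandpass_filter,
    epoch_segments,
    reject_epochs,
    rereference_average,
    resample,
    run_preprocess,
    select_middle_epochs,
)

from .conftest import make_recording


def sine_recording(freq_hz, fs=1000.0, duration_s=20.0, amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return make_recording(
        np.tile(amplitude * np.sin(2 * np.pi * freq_hz * t), (8, 1)), fs=fs
    )


class TestBandpass:
    def test_attenuation_exceeds_20db_one_octave_out(self):
        rec = sine_recording(90.0)  # one octave above the 45 Hz edge
        out = bandpass_filter(rec, 0.1, 45.0)
        mid = slice(2000, -2000)  # skip filter edges
        assert np.sqrt(np.mean(out.data[0, mid] ** 2)) < 0.10 * np.sqrt(0.5)

    def test_50hz_tone_attenuated(self):
        # order-4 zero-phase response at 50 Hz with a 45 Hz edge is ~0.30
        rec = sine_recording(50.0)
        out = bandpass_filter(rec, 0.1, 45.0)
        mid = slice(2000, -2000)
        assert np.sqrt(np.mean(out.data[0, mid] ** 2)) < 0.40 * np.sqrt(0.5)

    def test_in_band_tone_preserved_with_zero_phase(self):
        rec = sine_recording(10.0)
        out = bandpass_filter(rec, 0.1, 45.0)
        mid = slice(2000, -2000)
        rms_in = np.sqrt(np.mean(rec.data[0, mid] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, mid] ** 2))
        assert abs(rms_out - rms_in) < 0.05 * rms_in
        # zero phase: cross-correlation of in/out peaks at lag 0
        a, b = rec.data[0, mid], out.data[0, mid]
        lags = range(-20, 21)
        cc = [np.dot(a, np.roll(b, lag)) for lag in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_zero_in_zero_out(self):
        # constant input fails validation, so spike one sample then zero it
        rec = make_recording(np.zeros((8, 1000)) + 1e-15, fs=250.0)
        out = bandpass_filter(rec, 0.1, 45.0)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_edge_above_nyquist_rejected(self):
        rec = sine_recording(10.0, fs=100.0)
        with pytest.raises(ConfigError):
            bandpass_filter(rec, 0.1, 60.0)


class TestResample:
    def test_length_arithmetic(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((8, 300_000)), fs=1000.0)
        out = resample(rec, 250.0)
        assert out.fs == 250.0
        assert out.n_samples == 75_000

    def test_sinusoid_amplitude_preserved(self):
        rec = sine_recording(10.0, fs=1000.0, duration_s=10.0, amplitude=2.0)
        out = resample(rec, 250.0)
        t = np.arange(out.n_samples) / out.fs
        # least-squares fit of a 10 Hz sinusoid recovers the amplitude
        design = np.column_stack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
        mid = slice(250, -250)
        coef, *_ = np.linalg.lstsq(design[mid], out.data[0, mid], rcond=None)
        assert abs(np.hypot(*coef) - 2.0) < 0.02 * 2.0

    def test_identity_when_rate_matches(self):
        rec = sine_recording(10.0, fs=250.0, duration_s=4.0)
        out = resample(rec, 250.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_upsampling_rejected(self):
        rec = sine_recording(10.0, fs=250.0, duration_s=4.0)
        with pytest.raises(ConfigError):
            resample(rec, 500.0)


class TestAverageReference:
    def test_already_zero_mean_unchanged(self):
        data = np.zeros((8, 100))
        data[0], data[1] = 1.0, -1.0
        rec = make_recording(data, fs=250.0)
        np.testing.assert_allclose(rereference_average(rec).data, data)

    def test_constant_offset_removed(self):
        data = np.zeros((8, 50))
        data[0] = 2.0
        out = rereference_average(make_recording(data, fs=250.0))
        np.testing.assert_allclose(out.data[0], 1.75)  # 2 - 2/8
        np.testing.assert_allclose(out.data[1], -0.25)

    def test_column_means_vanish(self):
        rng = np.random.default_rng(3)
        out = rereference_average(make_recording(rng.standard_normal((8, 1000)), fs=250.0))
        assert np.max(np.abs(out.data.mean(axis=0))) <= 1e-12


class TestEpoching:
    def test_300s_at_250hz_gives_75_epochs(self):
        rec = make_recording(
            np.random.default_rng(1).standard_normal((8, 75_000)), fs=250.0
        )
        ep = epoch_segments(rec, 4.0)
        assert ep.n_epochs == 75
        assert ep.epochs.shape == (75, 8, 1000)

    def test_trailing_remainder_dropped(self):
        rec = make_recording(
            np.random.default_rng(1).standard_normal((8, int(301.5 * 250))), fs=250.0
        )
        assert epoch_segments(rec, 4.0).n_epochs == 75

    def test_too_short_recording_rejected(self):
        rec = make_recording(np.random.default_rng(1).standard_normal((8, 750)), fs=250.0)
        with pytest.raises(DataError):
            epoch_segments(rec, 4.0)


class TestRejection:
    def _epoched(self, n_epochs=75):
        rng = np.random.default_rng(5)
        rec = make_recording(rng.standard_normal((8, n_epochs * 1000)) * 10, fs=250.0)
        return epoch_segments(rec, 4.0)

    def test_spike_epoch_dropped(self):
        ep = self._epoched()
        ep.epochs[10, 3, 500] = 500.0
        out = reject_epochs(ep, PreprocessConfig())
        assert out.n_epochs == 74
        assert 10 not in out.source_indices

    def test_flat_channel_epoch_dropped(self):
        ep = self._epoched()
        ep.epochs[5, 2, :] = 0.0
        out = reject_epochs(ep, PreprocessConfig())
        assert 5 not in out.source_indices

    def test_clean_epochs_untouched_and_idempotent(self):
        ep = self._epoched()
        once = reject_epochs(ep, PreprocessConfig())
        assert once.n_epochs == ep.n_epochs
        twice = reject_epochs(once, PreprocessConfig())
        np.testing.assert_array_equal(once.epochs, twice.epochs)

    def test_all_rejected_raises(self):
        ep = self._epoched(n_epochs=3)
        ep.epochs[:] = 1e4
        with pytest.raises(DataError, match="rejected"):
            reject_epochs(ep, PreprocessConfig())


class TestMiddleSelection:
    def test_75_survivors_keep_indices_22_to_51(self):
        ep = TestRejection()._epoched()
        out = select_middle_epochs(ep, 30)
        np.testing.assert_array_equal(out.source_indices, np.arange(22, 52))

    def test_exact_count_is_identity(self):
        ep = TestRejection()._epoched(n_epochs=30)
        out = select_middle_epochs(ep, 30)
        np.testing.assert_array_equal(out.epochs, ep.epochs)

    def test_too_few_survivors_excludes_subject(self):
        ep = TestRejection()._epoched(n_epochs=29)
        with pytest.raises(SubjectExclusionError):
            select_middle_epochs(ep, 30)


class TestFullChain:
    def test_clean_300s_1khz_recording_yields_30x8x1000(self):
        rng = np.random.default_rng(11)
        rec = make_recording(rng.standard_normal((8, 300_000)) * 10, fs=1000.0)
        ep = run_preprocess(rec, PreprocessConfig())
        assert ep.epochs.shape == (30, 8, 1000)
        assert ep.fs == 250.0

    def test_heavily_spiked_recording_excluded(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((8, 75_000)) * 10
        rec = make_recording(data, fs=250.0)
        ep = epoch_segments(rec, 4.0)
        ep.epochs[: 50, 0, 10] = 1e4  # 50 of 75 epochs spiked
        cleaned = reject_epochs(ep, PreprocessConfig())
        with pytest.raises(SubjectExclusionError):
            select_middle_epochs(cleaned, 30)

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        data = rng.standard_normal((8, 200_000)) * 10
        a = run_preprocess(make_recording(data, fs=500.0))
        b = run_preprocess(make_recording(data, fs=500.0))
        np.testing.assert_array_equal(a.epochs, b.epochs)

    def test_reference_and_epoching_commute(self):
        rng = np.random.default_rng(14)
        rec = make_recording(rng.standard_normal((8, 10_000)), fs=250.0)
        a = epoch_segments(rereference_average(rec), 4.0)
        b = epoch_segments(rec, 4.0)
        b_ref = b.epochs - b.epochs.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(a.epochs, b_ref, atol=1e-12)
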
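"""Phase extraction, PLV and wPLI estimators."""

import numpy as np
import pytest
from scipy.signal import butter, hilbert, sosfiltfilt

from resteeg.connectivity import (
    CrossSpectrum,
    instantaneous_phase,
    plv_matrix,
    plv_pair,
    windowed_cross_spectra,
    wpli_matrix,
    wpli_pair,
)
from resteeg.exceptions import ConfigError, DataError
from resteeg.io import BandDefinition, get_band
from resteeg.simulate import phase_diffusing_oscillator, pink_noise

from .conftest import epoched_from_channels

FS = 250.0
THETA = get_band("theta")


class TestInstantaneousPhase:
    def test_tone_phase_advances_at_carrier_frequency(self):
        t = np.arange(1000) / FS
        ph = instantaneous_phase(np.cos(2 * np.pi * 6.0 * t), FS, THETA)
        slope = np.polyfit(t[100:-100], np.unwrap(ph.phase)[100:-100], 1)[0]
        assert slope / (2 * np.pi) == pytest.approx(6.0, rel=0.01)

    def test_quadrature_pair_differs_by_half_pi(self):
        t = np.arange(1000) / FS
        a = instantaneous_phase(np.cos(2 * np.pi * 6.0 * t), FS, THETA)
        b = instantaneous_phase(np.sin(2 * np.pi * 6.0 * t), FS, THETA)
        diff = np.angle(np.exp(1j * (a.phase - b.phase)))[250:-250]
        # mirror padding leaves ~1% phase ripple even in the interior
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.03)

    def test_constant_epoch_has_undefined_phase(self):
        with pytest.raises(DataError):
            instantaneous_phase(np.zeros(1000), FS, THETA)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            instantaneous_phase(np.random.default_rng(0).standard_normal(1000), FS,
                                BandDefinition("hf", 100.0, 130.0))


class TestPlv:
    def test_identical_signals_lock_perfectly(self):
        x = pink_noise(int(120 * FS), FS, 1.0, 1)
        ep = epoched_from_channels([x, x.copy()])
        assert plv_pair(ep, "A", "B", THETA) == pytest.approx(1.0, abs=1e-9)

    def test_constant_phase_offset_still_locks(self):
        t = np.arange(int(120 * FS)) / FS
        tone = epoched_from_channels(
            [np.cos(2 * np.pi * 6.0 * t), np.cos(2 * np.pi * 6.0 * t - np.pi / 3)]
        )
        assert plv_pair(tone, "A", "B", THETA) == pytest.approx(1.0, abs=0.01)
        # a diffusing-phase pair with a constant offset locks almost as tightly
        _, phi = phase_diffusing_oscillator(t.size, FS, 6.0, 1.0, 1.0, 2)
        ep = epoched_from_channels([np.cos(phi), np.cos(phi - np.pi / 3)])
        assert plv_pair(ep, "A", "B", THETA) == pytest.approx(1.0, abs=0.02)

    def test_independent_oscillators_stay_near_null(self):
        # 4-s epochs hold ~16 decorrelated phase samples, so the null
        # sits near 0.27, far below any injected coupling
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(120 * FS)
            a, _ = phase_diffusing_oscillator(n, FS, 6.0, 1.5, 1.0, rng)
            b, _ = phase_diffusing_oscillator(n, FS, 6.0, 1.5, 1.0, rng)
            vals.append(plv_pair(epoched_from_channels([a, b]), "A", "B", THETA))
        assert np.mean(vals) < 0.35

    def test_matches_loop_based_oracle(self):
        rng = np.random.default_rng(5)
        n = 3 * 1000
        chans = [rng.standard_normal(n) for _ in range(2)]
        ep = epoched_from_channels(chans, epoch_length_s=4.0)

        # independent oracle: filter, mirror-pad, hilbert, then an explicit
        # per-sample loop over the phase differences
        sos = butter(4, [THETA.f_lo, THETA.f_hi], btype="bandpass", fs=FS, output="sos")
        per_epoch = []
        for e in range(ep.n_epochs):
            phs = []
            for c in range(2):
                y = sosfiltfilt(sos, ep.epochs[e, c])
                m = y.size
                padded = np.concatenate([y[::-1], y, y[::-1]])
                phs.append(np.angle(hilbert(padded)[m : 2 * m]))
            acc = 0j
            for tt in range(m):
                acc += np.exp(1j * (phs[0][tt] - phs[1][tt]))
            per_epoch.append(abs(acc / m))
        oracle = float(np.mean(per_epoch))
        assert plv_pair(ep, "A", "B", THETA) == pytest.approx(oracle, abs=1e-10)

    def test_matrix_of_copies_is_all_ones(self):
        x = pink_noise(int(20 * FS), FS, 1.0, 7)
        ep = epoched_from_channels([x.copy() for _ in range(8)])
        np.testing.assert_allclose(plv_matrix(ep, THETA).values.to_numpy(), 1.0, atol=1e-9)

    def test_matrix_invariants_and_pair_consistency(self):
        rng = np.random.default_rng(8)
        ep = epoched_from_channels([rng.standard_normal(int(20 * FS)) for _ in range(8)])
        mat = plv_matrix(ep, THETA)
        v = mat.values.to_numpy()
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert np.all((v >= 0) & (v <= 1))
        assert mat.pair_value("F3", "O1") == pytest.approx(
            plv_pair(ep, "F3", "O1", THETA), abs=1e-12
        )

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal((2, int(20 * FS)))
        p1 = plv_pair(epoched_from_channels([a, b]), "A", "B", THETA)
        p2 = plv_pair(epoched_from_channels([5 * a, 0.1 * b]), "A", "B", THETA)
        assert p1 == pytest.approx(p2, abs=1e-9)


class TestCrossSpectra:
    def test_120s_gives_23_windows_at_0p1hz_spacing(self):
        x, y = np.random.default_rng(0).standard_normal((2, int(120 * FS)))
        cs = windowed_cross_spectra(x, y, FS)
        assert cs.n_windows == 23
        assert np.diff(cs.freqs)[0] == pytest.approx(0.1, abs=1e-12)

    def test_autospectrum_is_real(self):
        x = np.random.default_rng(1).standard_normal(int(30 * FS))
        cs = windowed_cross_spectra(x, x, FS)
        assert np.max(np.abs(cs.s_xy.imag)) <= 1e-10 * np.max(np.abs(cs.s_xy.real))

    def test_short_signal_rejected(self):
        x = np.random.default_rng(2).standard_normal(int(5 * FS))
        with pytest.raises(DataError):
            windowed_cross_spectra(x, x, FS)


class TestWpli:
    def test_pure_delay_gives_unity_at_carrier(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 6.0 * t)
        y = np.sin(2 * np.pi * 6.0 * t - np.pi / 4)
        cs = windowed_cross_spectra(x, y, FS)
        carrier = BandDefinition("carrier", 5.95, 6.05)  # the 6.0 Hz bin alone
        assert wpli_pair(cs, carrier) == pytest.approx(1.0, abs=1e-9)

    def test_sign_balanced_windows_cancel_exactly(self):
        s_xy = np.zeros((10, 5), complex)
        s_xy[:5] += 1j * 2.0
        s_xy[5:] -= 1j * 2.0
        cs = CrossSpectrum(pair=("x", "y"), freqs=np.arange(5) * 0.1 + 4.0, s_xy=s_xy)
        assert wpli_pair(cs, BandDefinition("b", 4.0, 4.5)) == 0.0

    def test_zero_lag_mixture_invisible_but_plv_locks(self):
        # volume-conduction surrogate: common source plus independent
        # sensor noise reaches both channels with zero lag
        rng = np.random.default_rng(3)
        n = int(600 * FS)
        src, _ = phase_diffusing_oscillator(n, FS, 6.0, 1.5, 1.0, rng)
        x = src + 0.3 * rng.standard_normal(n)
        y = src + 0.3 * rng.standard_normal(n)
        assert plv_pair(epoched_from_channels([x, y]), "A", "B", THETA) > 0.5
        assert wpli_pair(windowed_cross_spectra(x, y, FS), THETA) < 0.2

    def test_empty_band_rejected(self):
        x, y = np.random.default_rng(4).standard_normal((2, int(20 * FS)))
        cs = windowed_cross_spectra(x, y, FS)
        with pytest.raises(ConfigError):
            wpli_pair(cs, BandDefinition("empty", 4.01, 4.09))

    def test_swap_symmetry(self):
        x, y = np.random.default_rng(5).standard_normal((2, int(60 * FS)))
        a = wpli_pair(windowed_cross_spectra(x, y, FS), THETA)
        b = wpli_pair(windowed_cross_spectra(y, x, FS), THETA)
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounds_hold_on_random_cross_spectra(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            nw = int(rng.integers(2, 12))
            s_xy = rng.standard_normal((nw, 8)) + 1j * rng.standard_normal((nw, 8))
            cs = CrossSpectrum(("x", "y"), np.arange(8) * 0.1 + 4.0, s_xy)
            v = wpli_pair(cs, BandDefinition("b", 4.0, 4.8))
            assert 0.0 <= v <= 1.0


class TestWpliMatrix:
    def test_delayed_common_source_couples_everything(self):
        rng = np.random.default_rng(7)
        n = int(120 * FS)
        base = sosfiltfilt(
            butter(4, [4, 8], btype="bandpass", fs=FS, output="sos"),
            rng.standard_normal(n + 400),
        )
        delays = [0, 5, 11, 17, 23, 29, 35, 41]
        chans = [base[400 - d : 400 - d + n] for d in delays]
        mat = wpli_matrix(epoched_from_channels(chans, names=None), THETA)
        off = mat.values.to_numpy()[np.triu_indices(8, 1)]
        assert np.all(off > 0.9)

    def test_independent_channels_stay_near_null(self):
        n = int(600 * FS)
        for seed in range(2):
            rng = np.random.default_rng(20 + seed)
            ep = epoched_from_channels([rng.standard_normal(n) for _ in range(8)])
            off = wpli_matrix(ep, THETA).values.to_numpy()[np.triu_indices(8, 1)]
            assert np.all(off < 0.2)

    def test_symmetry_range_and_zero_diagonal(self):
        rng = np.random.default_rng(9)
        ep = epoched_from_channels([rng.standard_normal(int(40 * FS)) for _ in range(8)])
        mat = wpli_matrix(ep, THETA)
        v = mat.values.to_numpy()
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert np.all((v >= 0) & (v <= 1))
        np.testing.assert_allclose(np.diag(v), 0.0)
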
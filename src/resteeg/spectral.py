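"""Power spectrum and band-power features.

The PSD estimator is a Welch scheme tailored to 30 x 4-s epoch blocks at
250 Hz: the epochs are concatenated, the block is mirror-padded with a
reflected copy of its first and last epoch to tame window edge effects,
and a 250-sample (1 s) Hamming window slides in 100-sample (0.4 s) steps
with a 1024-point FFT per window. Only windows whose centers fall inside
the unpadded span enter the average, so the padding shapes the taper at
the edges without biasing the estimate. Density normalization follows
the usual window-power (sum of squared taper) correction, so a
unit-amplitude sinusoid integrates to ~0.5 uV^2.

Band powers integrate the PSD over half-open intervals [f_lo, f_hi) --
the canonical bands share endpoints at 4, 8 and 13 Hz -- and relative
power divides by the integral over 1-45 Hz (so the four canonical
relative powers need not sum exactly to 1; delta starts at 0.1 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal import get_window

from .exceptions import ConfigError, DegenerateSpectrumError
from .io import CANONICAL_BANDS, BandDefinition, EpochedRecording


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, 0..Nyquist
    psd: np.ndarray  # channels x freqs, uV^2/Hz
    channel_names: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.psd < -1e-30):
            raise ValueError("PSD must be non-negative")
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequency grid must be strictly increasing")

    def mean_over_channels(self) -> np.ndarray:
        return self.psd.mean(axis=0)


@dataclass
class BandPowerTable:
    absolute: pd.DataFrame  # channels x bands, uV^2
    relative: pd.DataFrame  # channels x bands, dimensionless
    total_1_45: pd.Series  # per channel, uV^2


@dataclass
class AlphaPeak:
    frequency_hz: float
    has_peak: bool  # False when the 8-13 Hz range shows no credible peak


def psd_welch_mirrored(
    ep: EpochedRecording,
    window_samples: int = 250,
    step_samples: int = 100,
    nfft: int = 1024,
) -> PowerSpectrum:
    """Welch PSD of the concatenated epochs with mirror padding.

    Raises ConfigError if an epoch is shorter than the analysis window.
    """
    n_per = ep.epochs.shape[2]
    if n_per < window_samples:
        raise ConfigError(
            f"epoch of {n_per} samples shorter than the {window_samples}-sample window"
        )
    if nfft < window_samples:
        raise ConfigError("nfft must be >= window length")
    x = ep.concatenate()  # channels x L
    n_ch, L = x.shape
    pad = n_per  # one epoch of reflection on each side
    padded = np.concatenate([x[:, :pad][:, ::-1], x, x[:, -pad:][:, ::-1]], axis=1)

    starts = np.arange(0, padded.shape[1] - window_samples + 1, step_samples)
    centers = starts + window_samples / 2
    starts = starts[(centers >= pad) & (centers < pad + L)]
    if starts.size == 0:
        raise ConfigError("no analysis window falls inside the recording span")

    win = get_window("hamming", window_samples, fftbins=True)
    # gather windows: channels x n_win x window_samples
    idx = starts[:, None] + np.arange(window_samples)[None, :]
    segs = padded[:, idx] * win[None, None, :]
    spec = rfft(segs, n=nfft, axis=-1)
    p = (np.abs(spec) ** 2) / (ep.fs * np.sum(win**2))
    # one-sided density: double everything except DC (and Nyquist when nfft even)
    p[..., 1:] *= 2.0
    if nfft % 2 == 0:
        p[..., -1] /= 2.0
    psd = p.mean(axis=1)
    freqs = rfftfreq(nfft, d=1.0 / ep.fs)
    return PowerSpectrum(freqs=freqs, psd=psd, channel_names=ep.layout.names, fs=ep.fs)


def _band_mask(freqs: np.ndarray, band: BandDefinition, nyquist: float) -> np.ndarray:
    if band.f_hi > nyquist + 1e-9:
        raise ConfigError(f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) exceeds Nyquist")
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if mask.sum() < 2:
        raise ConfigError(f"band {band.name} covers fewer than 2 frequency bins")
    return mask


def band_powers(
    ps: PowerSpectrum, bands: Sequence[BandDefinition] = CANONICAL_BANDS
) -> BandPowerTable:
    """Absolute (trapezoidal) and relative band power per channel."""
    nyq = ps.fs / 2
    total_mask = (ps.freqs >= 1.0) & (ps.freqs < 45.0)
    total = np.trapezoid(ps.psd[:, total_mask], ps.freqs[total_mask], axis=1)
    if np.any(total <= 0):
        raise DegenerateSpectrumError("zero total power in 1-45 Hz on at least one channel")
    absolute = {}
    for band in bands:
        mask = _band_mask(ps.freqs, band, nyq)
        absolute[band.name] = np.trapezoid(ps.psd[:, mask], ps.freqs[mask], axis=1)
    abs_df = pd.DataFrame(absolute, index=list(ps.channel_names))
    rel_df = abs_df.div(pd.Series(total, index=abs_df.index), axis=0)
    return BandPowerTable(
        absolute=abs_df,
        relative=rel_df,
        total_1_45=pd.Series(total, index=abs_df.index, name="total_1_45"),
    )


def alpha_peak_frequency(
    ps: PowerSpectrum, f_lo: float = 8.0, f_hi: float = 13.0
) -> AlphaPeak:
    """Alpha peak of the all-channel mean spectrum, refined parabolically.

    The maximum bin in [f_lo, f_hi] is refined by 3-point parabolic
    interpolation. ``has_peak`` is False when the maximum sits on the
    range boundary or lacks prominence (max < 1.10 x the range median),
    i.e. when the spectrum shows no credible alpha peak.
    """
    mask = (ps.freqs >= f_lo) & (ps.freqs <= f_hi)
    if mask.sum() < 3:
        raise ConfigError("peak search range covers fewer than 3 bins")
    f = ps.freqs[mask]
    y = ps.mean_over_channels()[mask]
    i = int(np.argmax(y))
    interior = 0 < i < len(y) - 1
    prominent = y[i] >= 1.10 * np.median(y)
    freq = f[i]
    if interior:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom < 0:  # genuine local max; refine within +-half a bin
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            freq = f[i] + np.clip(delta, -0.5, 0.5) * (f[1] - f[0])
    return AlphaPeak(frequency_hz=float(freq), has_peak=bool(interior and prominent))


def theta_beta_ratio(bp: BandPowerTable) -> pd.Series:
    """Per-channel theta/beta relative-power ratio (power-to-power coupling).

    Values above 1 indicate energy concentrated in theta relative to beta,
    the shift associated with slowed cortical rhythms.
    """
    for need in ("theta", "beta"):
        if need not in bp.relative.columns:
            raise ConfigError(f"band '{need}' missing from band-power table")
    beta = bp.relative["beta"]
    if np.any(beta <= 0):
        raise DegenerateSpectrumError("zero beta power; theta/beta ratio undefined")
    ratio = bp.relative["theta"] / beta
    ratio.name = "theta_beta_ratio"
    return ratio
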
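"""Phase-synchrony estimation: PLV and wPLI.

PLV (phase locking value): each epoch is band-pass filtered, its
instantaneous phase extracted with the Hilbert transform (on a
mirror-padded copy to suppress transform edge effects), and the
magnitude of the time-averaged unit phasor of the phase difference
computed per epoch,

    PLV = | (1/T) sum_t exp(j (phi_x(t) - phi_y(t))) |,

then averaged over the retained epochs. PLV is blind to amplitude and,
importantly, to any *constant* phase offset -- including a zero one --
which makes it vulnerable to volume conduction.

wPLI (weighted phase lag index): the retained epochs are concatenated
and cut into 10-s Hamming windows with 50% overlap; each window's finite
Fourier transform at its natural 0.1 Hz bin spacing yields cross-spectra
S_xy = conj(X) * Y, and per frequency bin

    wPLI = | mean_t Im S_xy(t) | / mean_t |Im S_xy(t)|,

averaged over the bins of the band of interest. Because only the
imaginary cross-spectrum enters, zero-lag (volume-conducted) coupling
contributes nothing, and observations are weighted by the magnitude of
their imaginary part, damping near-zero-lag noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal import butter, get_window, hilbert, sosfiltfilt

from .exceptions import ConfigError, DataError
from .io import BandDefinition, ChannelLayout, EpochedRecording


@dataclass
class PhaseSeries:
    channel: str
    band: BandDefinition
    phase: np.ndarray  # radians per sample, (-pi, pi]
    amplitude: np.ndarray  # analytic amplitude per sample


@dataclass
class CrossSpectrum:
    """Per-window cross-spectra of one channel pair.

    ``s_xy`` is windows x freqs, S_xy(omega, t) = conj(X_t) * Y_t; the
    constant normalization of the spectral density cancels in wPLI.
    """

    pair: tuple[str, str]
    freqs: np.ndarray  # Hz, spacing 1/window_s
    s_xy: np.ndarray  # complex, n_windows x n_freqs

    @property
    def n_windows(self) -> int:
        return self.s_xy.shape[0]


@dataclass
class ConnectivityMatrix:
    method: str  # "plv" | "wpli"
    band: BandDefinition
    values: pd.DataFrame  # channels x channels, symmetric, in [0, 1]

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("connectivity values must lie in [0, 1]")

    def pair_value(self, ch_x: str, ch_y: str) -> float:
        return float(self.values.loc[ch_x, ch_y])

    def to_long(self) -> pd.DataFrame:
        rows = []
        names = list(self.values.index)
        for a, b in combinations(names, 2):
            rows.append(
                {
                    "method": self.method,
                    "band": self.band.name,
                    "ch1": a,
                    "ch2": b,
                    "value": float(self.values.loc[a, b]),
                }
            )
        return pd.DataFrame(rows)


def all_pairs(layout: ChannelLayout) -> list[tuple[str, str]]:
    """The unordered channel pairs of a layout (28 for 8 channels)."""
    return list(combinations(layout.names, 2))


def _band_sos(band: BandDefinition, fs: float, order: int = 4):
    if band.f_hi >= fs / 2:
        raise ConfigError(f"band {band.name} upper edge {band.f_hi} >= Nyquist {fs / 2}")
    if band.f_lo <= 0:
        return butter(order, band.f_hi, btype="lowpass", fs=fs, output="sos")
    return butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")


def instantaneous_phase(
    x: np.ndarray, fs: float, band: BandDefinition, channel: str = ""
) -> PhaseSeries:
    """Band-limited instantaneous phase of one epoch via the Hilbert transform.

    The epoch is zero-phase band-pass filtered, then mirror-padded by a
    full epoch length on both sides before the Hilbert transform; the
    padding is discarded so the returned series matches the epoch span.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel epoch")
    if np.ptp(x) == 0:
        raise DataError(f"phase undefined for a constant epoch on {channel or 'channel'}")
    y = sosfiltfilt(_band_sos(band, fs), x)
    n = y.size
    padded = np.concatenate([y[::-1], y, y[::-1]])
    analytic = hilbert(padded)[n : 2 * n]
    return PhaseSeries(
        channel=channel,
        band=band,
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
    )


def _epoch_phasors(ep: EpochedRecording, band: BandDefinition) -> np.ndarray:
    """Unit phasors exp(j phi) for all epochs/channels: (n_ep, n_ch, n_s)."""
    sos = _band_sos(band, ep.fs)
    if np.ptp(ep.epochs, axis=2).min() == 0:
        raise DataError("phase undefined: a channel epoch is constant")
    y = sosfiltfilt(sos, ep.epochs, axis=2)
    n = y.shape[2]
    padded = np.concatenate([y[..., ::-1], y, y[..., ::-1]], axis=2)
    analytic = hilbert(padded, axis=2)[..., n : 2 * n]
    return analytic / np.abs(analytic)


def plv_pair(ep: EpochedRecording, ch_x: str, ch_y: str, band: BandDefinition) -> float:
    """Epoch-averaged PLV between two channels in one band."""
    ix, iy = ep.layout.index(ch_x), ep.layout.index(ch_y)
    sub = EpochedRecording(
        subject_id=ep.subject_id,
        condition=ep.condition,
        fs=ep.fs,
        epochs=ep.epochs[:, [ix, iy], :],
        epoch_length_s=ep.epoch_length_s,
        layout=ChannelLayout((ep.layout.names[ix], ep.layout.names[iy])),
        source_indices=ep.source_indices,
    )
    u = _epoch_phasors(sub, band)
    per_epoch = np.abs((u[:, 0, :] * np.conj(u[:, 1, :])).mean(axis=1))
    return float(per_epoch.mean())


def plv_matrix(ep: EpochedRecording, band: BandDefinition) -> ConnectivityMatrix:
    """PLV over all unordered channel pairs; diagonal 1."""
    u = _epoch_phasors(ep, band)  # (n_ep, n_ch, n_s)
    n_s = u.shape[2]
    # per epoch the Gram matrix of phasors gives all pairwise mean exp(j dphi)
    gram = np.einsum("eit,ejt->eij", u, np.conj(u)) / n_s
    values = np.abs(gram).mean(axis=0)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    df = pd.DataFrame(values, index=list(ep.layout.names), columns=list(ep.layout.names))
    return ConnectivityMatrix(method="plv", band=band, values=df.clip(0.0, 1.0))


def windowed_cross_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    overlap: float = 0.5,
    pair: tuple[str, str] = ("x", "y"),
) -> CrossSpectrum:
    """Cross-spectra of overlapping Hamming windows of a continuous pair.

    With 10-s windows the FFT bin spacing is exactly 0.1 Hz.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    n_win = int(round(window_s * fs))
    if x.size < n_win:
        raise DataError(f"signal of {x.size} samples shorter than one {window_s}-s window")
    hop = int(round(n_win * (1 - overlap)))
    starts = np.arange(0, x.size - n_win + 1, hop)
    win = get_window("hamming", n_win, fftbins=True)
    idx = starts[:, None] + np.arange(n_win)[None, :]
    fx = rfft(x[idx] * win, axis=1)
    fy = rfft(y[idx] * win, axis=1)
    return CrossSpectrum(
        pair=pair, freqs=rfftfreq(n_win, 1.0 / fs), s_xy=np.conj(fx) * fy
    )


def wpli_pair(cs: CrossSpectrum, band: BandDefinition) -> float:
    """Band-mean wPLI from per-window cross-spectra.

    Per bin: |mean_t Im S| / mean_t |Im S|; a bin with zero denominator
    contributes 0 (no evidence of lagged synchrony).
    """
    if cs.n_windows < 2:
        raise DataError("wPLI needs at least 2 windows")
    mask = (cs.freqs >= band.f_lo) & (cs.freqs < band.f_hi)
    if not mask.any():
        raise ConfigError(f"band {band.name} contains no frequency bins")
    im = np.imag(cs.s_xy[:, mask])
    num = np.abs(im.mean(axis=0))
    den = np.abs(im).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(per_bin.mean())


def wpli_matrix(
    ep: EpochedRecording,
    band: BandDefinition,
    window_s: float = 10.0,
    overlap: float = 0.5,
) -> ConnectivityMatrix:
    """wPLI over all unordered pairs of the concatenated epochs; diagonal 0."""
    x = ep.concatenate()
    n_win = int(round(window_s * ep.fs))
    if x.shape[1] < n_win:
        raise DataError("concatenated recording shorter than one wPLI window")
    hop = int(round(n_win * (1 - overlap)))
    starts = np.arange(0, x.shape[1] - n_win + 1, hop)
    win = get_window("hamming", n_win, fftbins=True)
    idx = starts[:, None] + np.arange(n_win)[None, :]
    freqs = rfftfreq(n_win, 1.0 / ep.fs)
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if not mask.any():
        raise ConfigError(f"band {band.name} contains no frequency bins")
    spec = rfft(x[:, idx] * win, axis=2)[:, :, mask]  # n_ch x n_windows x n_bins

    names = list(ep.layout.names)
    values = np.zeros((len(names), len(names)))
    for i, j in combinations(range(len(names)), 2):
        im = np.imag(np.conj(spec[i]) * spec[j])
        num = np.abs(im.mean(axis=0))
        den = np.abs(im).mean(axis=0)
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        values[i, j] = values[j, i] = per_bin.mean()
    df = pd.DataFrame(values, index=names, columns=names)
    return ConnectivityMatrix(method="wpli", band=band, values=df.clip(0.0, 1.0))
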
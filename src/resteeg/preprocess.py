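"""Raw recording -> 30 clean 4-s epochs.

Stage order: zero-phase band-pass (0.1-45 Hz), downsample to 250 Hz,
average reference, cut into consecutive non-overlapping 4-s epochs,
amplitude/flatness artifact rejection, then retention of the middle 30
surviving epochs (2 min) so every subject-condition contributes the same
amount of data. A subject-condition with fewer than 30 clean epochs is
excluded, mirroring common practice for resting-state cohorts.

Artifact rejection here is a deliberately simple amplitude + flatness
rule (wavelet-ICA style pipelines are out of scope); thresholds are
configurable and the defaults are conventional for scalp EEG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError, DataError, SubjectExclusionError
from .io import EpochedRecording, Recording

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    bp_lo: float = 0.1  # Hz
    bp_hi: float = 45.0  # Hz
    target_fs: float = 250.0  # Hz
    epoch_length_s: float = 4.0
    n_keep: int = 30
    reject_abs_uv: float = 100.0  # |amplitude| threshold per channel
    flat_std_uv: float = 0.01  # within-epoch std below this = flat channel

    def __post_init__(self) -> None:
        if not (0 <= self.bp_lo < self.bp_hi < self.target_fs / 2):
            raise ConfigError(
                f"need 0 <= bp_lo < bp_hi < target_fs/2, got "
                f"({self.bp_lo}, {self.bp_hi}, {self.target_fs})"
            )
        if self.n_keep < 1:
            raise ConfigError("n_keep must be >= 1")


def bandpass_filter(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay).

    Implemented as separate low-pass and high-pass stages; the high-pass
    (whose impulse response spans ~1/lo seconds) gets edge padding
    proportional to its time constant to keep filtfilt transients out of
    the retained signal.
    """
    nyq = rec.fs / 2
    if not (0 <= lo < hi):
        raise ConfigError(f"need 0 <= lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ConfigError(f"upper edge {hi} Hz >= Nyquist {nyq} Hz")
    sos_lp = sps.butter(order, hi, btype="lowpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos_lp, rec.data, axis=1)
    if lo > 0:
        sos_hp = sps.butter(order, lo, btype="highpass", fs=rec.fs, output="sos")
        padlen = int(min(rec.n_samples - 1, np.ceil(2 * rec.fs / lo)))
        data = sps.sosfiltfilt(sos_hp, data, axis=1, padlen=padlen)
    return rec.copy_with(data=data)


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase downsampling; upsampling is out of scope."""
    if target_fs > rec.fs:
        raise ConfigError(f"upsampling {rec.fs} -> {target_fs} Hz not supported")
    if target_fs == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=data, fs=target_fs)


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def epoch_segments(rec: Recording, epoch_length_s: float) -> EpochedRecording:
    """Cut into consecutive non-overlapping epochs; trailing remainder dropped."""
    n_per = int(round(epoch_length_s * rec.fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise DataError(
            f"recording of {rec.duration_s:.1f} s shorter than one "
            f"{epoch_length_s}-s epoch"
        )
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2).copy()
    return EpochedRecording(
        subject_id=rec.subject_id,
        condition=rec.condition,
        fs=rec.fs,
        epochs=epochs,
        epoch_length_s=epoch_length_s,
        layout=rec.layout,
    )


def reject_epochs(ep: EpochedRecording, config: PreprocessConfig) -> EpochedRecording:
    """Drop epochs with an amplitude excursion or a flat channel.

    An epoch is rejected when any channel exceeds +-``reject_abs_uv`` or any
    channel's within-epoch standard deviation falls below ``flat_std_uv``.
    Surviving epochs keep their original order and source indices.
    """
    amp_bad = np.abs(ep.epochs).max(axis=2).max(axis=1) > config.reject_abs_uv
    flat_bad = ep.epochs.std(axis=2).min(axis=1) < config.flat_std_uv
    keep = ~(amp_bad | flat_bad)
    if not keep.any():
        raise DataError(
            f"all {ep.n_epochs} epochs rejected "
            f"(amplitude: {int(amp_bad.sum())}, flat: {int(flat_bad.sum())})"
        )
    return EpochedRecording(
        subject_id=ep.subject_id,
        condition=ep.condition,
        fs=ep.fs,
        epochs=ep.epochs[keep],
        epoch_length_s=ep.epoch_length_s,
        layout=ep.layout,
        source_indices=ep.source_indices[keep],
    )


def select_middle_epochs(ep: EpochedRecording, n_keep: int) -> EpochedRecording:
    """Keep the middle ``n_keep`` of the surviving epochs.

    With M survivors the retained slice is [floor((M-n)/2), floor((M-n)/2)+n).
    Fewer than ``n_keep`` survivors excludes the subject-condition.
    """
    m = ep.n_epochs
    if m < n_keep:
        raise SubjectExclusionError(
            f"{ep.subject_id}/{ep.condition}: only {m} clean epochs, need {n_keep}"
        )
    start = (m - n_keep) // 2
    sl = slice(start, start + n_keep)
    return EpochedRecording(
        subject_id=ep.subject_id,
        condition=ep.condition,
        fs=ep.fs,
        epochs=ep.epochs[sl],
        epoch_length_s=ep.epoch_length_s,
        layout=ep.layout,
        source_indices=ep.source_indices[sl],
    )


def run_preprocess(rec: Recording, config: PreprocessConfig | None = None) -> EpochedRecording:
    """Full chain: filter -> resample -> average reference -> epoch -> reject -> middle."""
    config = config or PreprocessConfig()
    rec = bandpass_filter(rec, config.bp_lo, config.bp_hi)
    logger.info("stage=bandpass kept=%d dropped=0", rec.n_samples)
    rec = resample(rec, config.target_fs)
    logger.info("stage=resample kept=%d dropped=0", rec.n_samples)
    rec = rereference_average(rec)
    ep = epoch_segments(rec, config.epoch_length_s)
    logger.info("stage=epoch kept=%d dropped=0", ep.n_epochs)
    n_before = ep.n_epochs
    ep = reject_epochs(ep, config)
    logger.info("stage=reject kept=%d dropped=%d", ep.n_epochs, n_before - ep.n_epochs)
    n_before = ep.n_epochs
    ep = select_middle_epochs(ep, config.n_keep)
    logger.info("stage=middle kept=%d dropped=%d", ep.n_epochs, n_before - ep.n_epochs)
    return ep
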
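"""Seeded synthetic resting-state EEG cohorts.

Each channel is a sum of 1/f ("pink") background noise and band-limited
oscillators (theta, alpha, beta) whose instantaneous phase performs a
random walk around a carrier frequency, giving Lorentzian spectral peaks
of configurable width. Group structure mirrors the classic AD-vs-control
resting-state picture, injected in the eyes-closed condition only:

* alpha power reduced and the alpha peak slowed in the AD group;
* elevated theta-band phase coupling at designated channel pairs in AD,
  injected through a shared phase-diffusing theta source mixed with each
  channel's independent theta component (mixing weight calibrated
  numerically against the package's own PLV estimator); pairs meant to
  carry *lagged* coupling receive the shared source with a nonzero phase
  offset so the coupling is visible to wPLI, while zero-offset pairs are
  visible to PLV only;
* an elevated theta/beta ratio at designated channels in AD;
* eyes-open recordings attenuate alpha in everyone (alpha reactivity)
  and, by default, carry no group effects at all.

Demographics are sampled to match the target study population in
distribution (ages ~ Normal(69.35, 10.08) for AD and Normal(64.17,
10.64) for controls, floored at 50; sex and 5-level education drawn at
the reported group proportions). Everything is reproducible bit-for-bit
from the cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal import butter, sosfiltfilt

from .exceptions import ConfigError, ValidationError
from .io import ChannelLayout, Recording, SubjectMeta

# Target-population demographics (group, mean/sd age, M/F counts,
# education counts P/J/S/A/U).
AD_AGE = (69.35, 10.08)
HC_AGE = (64.17, 10.64)
AGE_FLOOR = 50.0
AD_SEX_MF = (11, 15)
HC_SEX_MF = (12, 17)
AD_EDUCATION = (4, 2, 13, 2, 5)
HC_EDUCATION = (5, 2, 15, 3, 4)


def _as_rng(seed) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


def pink_noise(
    n_samples: int, fs: float, exponent: float, seed, amplitude: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Spectrally shaped white noise (DC removed), scaled to the requested
    RMS amplitude. exponent=0 gives white noise, exponent=1 classic pink.
    """
    if n_samples <= 0:
        raise ConfigError("n_samples must be positive")
    if not 0 <= exponent <= 2:
        raise ConfigError(f"exponent must lie in [0, 2], got {exponent}")
    rng = _as_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = rfft(white)
    f = rfftfreq(n_samples, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = irfft(spec * scale, n=n_samples)
    sd = x.std()
    if sd > 0:
        x *= amplitude / sd
    return x


def phase_diffusing_oscillator(
    n_samples: int,
    fs: float,
    f0: float,
    bandwidth: float,
    amplitude: float,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Oscillator cos(phi) whose phase diffuses around a linear trend.

    ``bandwidth`` is the Lorentzian full width at half maximum (Hz) of
    the resulting spectral peak; 0 gives a pure sinusoid with a random
    starting phase. Returns (signal, generative phase series).
    """
    if not 0 < f0 < fs / 2:
        raise ConfigError(f"f0 must lie in (0, Nyquist), got {f0}")
    if bandwidth < 0:
        raise ConfigError("bandwidth must be non-negative")
    rng = _as_rng(seed)
    phase0 = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_samples) / fs
    # Var[phi(t) - phi(0)] = D t with D = 2*pi*bandwidth -> FWHM = bandwidth Hz
    d = 2 * np.pi * bandwidth
    walk = np.cumsum(rng.standard_normal(n_samples)) * math.sqrt(d / fs) if bandwidth > 0 else 0.0
    phase = phase0 + 2 * np.pi * f0 * t + walk
    return amplitude * np.cos(phase), phase


#: canonical spectral confinement of each rendered oscillator component.
#: The random-walk phase model has heavy Lorentzian tails; real rhythm
#: peaks do not, so each component is band-limited to its nominal band
#: (zero-phase, applied identically to all channels, hence preserving
#: cross-channel phase relations).
_OSC_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


def _confine(x: np.ndarray, fs: float, which: str) -> np.ndarray:
    lo, hi = _OSC_BANDS[which]
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


Pair = tuple[str, str]


@dataclass(frozen=True)
class EffectSpec:
    """Group effects injected into AD subjects (eyes-closed by default)."""

    alpha_power_ratio_ad: float = 0.7  # multiplicative on alpha amplitude, < 1
    alpha_peak_shift_ad_hz: float = -0.33  # Hz, negative = slowing
    #: pairs carrying zero-lag shared theta: (pair, target PLV)
    theta_plv_pairs: tuple[tuple[Pair, float], ...] = (
        (("F3", "O1"), 0.5),
        (("C3", "O1"), 0.5),
    )
    #: pairs carrying lagged shared theta: (pair, target strength, lag radians)
    theta_wpli_pairs: tuple[tuple[Pair, float, float], ...] = (
        (("F3", "F4"), 0.5, math.pi / 4),
        (("F3", "T4"), 0.5, math.pi / 4),
        (("F4", "O1"), 0.5, math.pi / 4),
    )
    #: channels whose theta amplitude is boosted in AD: channel -> factor
    tbr_channels: Mapping[str, float] = field(
        default_factory=lambda: {"F3": 1.6, "F4": 1.6, "C4": 1.6}
    )
    eo_alpha_attenuation: float = 0.5  # applied to alpha in EO for everyone
    eo_effects_null: bool = True  # no group effects in EO

    def __post_init__(self) -> None:
        if not 0 < self.alpha_power_ratio_ad:
            raise ValidationError("alpha_power_ratio_ad must be > 0")
        if not 0 < self.eo_alpha_attenuation:
            raise ValidationError("eo_alpha_attenuation must be > 0")
        for pair, s in self.theta_plv_pairs:
            if not 0 <= s <= 1:
                raise ValidationError(f"PLV target for {pair} must lie in [0, 1]")
        for pair, s, lag in self.theta_wpli_pairs:
            if not 0 <= s <= 1:
                raise ValidationError(f"coupling target for {pair} must lie in [0, 1]")
            if not 0 < lag < math.pi:
                raise ValidationError(f"lag for {pair} must lie in (0, pi)")
        for ch, f in self.tbr_channels.items():
            if not f > 0:
                raise ValidationError(f"theta boost for {ch} must be > 0")

    @staticmethod
    def null() -> "EffectSpec":
        """No group effects anywhere (for null calibration)."""
        return EffectSpec(
            alpha_power_ratio_ad=1.0,
            alpha_peak_shift_ad_hz=0.0,
            theta_plv_pairs=(),
            theta_wpli_pairs=(),
            tbr_channels={},
        )

    def plv_items(self) -> list[Pair]:
        return [pair for pair, _ in self.theta_plv_pairs]

    def wpli_items(self) -> list[Pair]:
        return [pair for pair, _, _ in self.theta_wpli_pairs]

    def tbr_items(self) -> list[str]:
        return list(self.tbr_channels)

    def channels_used(self) -> set[str]:
        used: set[str] = set(self.tbr_channels)
        for pair, _ in self.theta_plv_pairs:
            used.update(pair)
        for pair, _, _ in self.theta_wpli_pairs:
            used.update(pair)
        return used


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort reproducibly."""

    n_ad: int = 26
    n_hc: int = 29
    duration_s: float = 300.0  # >= 300 so 75 four-second epochs exist
    fs: float = 250.0
    seed: int = 0
    effects: EffectSpec = field(default_factory=EffectSpec)
    noise_exponent: float = 1.0  # 1/f slope of the background
    noise_amplitude_uv: float = 5.0  # broadband RMS of the background
    osc_bandwidth_hz: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 1.5, "alpha": 1.0, "beta": 4.0}
    )
    alpha_amp_uv: float = 10.0
    theta_amp_uv: float = 3.0
    beta_amp_uv: float = 2.0
    theta_f0_hz: float = 6.0
    beta_f0_hz: float = 20.0
    alpha_peak_mean_hz: float = 10.09  # control-group mean alpha peak
    alpha_peak_sd_hz: float = 0.4
    amp_jitter_sd: float = 0.1  # per-subject lognormal amplitude jitter
    layout: ChannelLayout = field(default_factory=ChannelLayout)

    def __post_init__(self) -> None:
        if self.n_ad < 2 or self.n_hc < 2:
            raise ValidationError("need at least 2 subjects per group")
        if self.duration_s < 300:
            raise ValidationError("duration_s must be >= 300 (75 four-second epochs)")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        eff = self.effects
        return {
            "n_ad": self.n_ad,
            "n_hc": self.n_hc,
            "duration_s": self.duration_s,
            "fs": self.fs,
            "seed": self.seed,
            "noise_exponent": self.noise_exponent,
            "noise_amplitude_uv": self.noise_amplitude_uv,
            "osc_bandwidth_hz": dict(self.osc_bandwidth_hz),
            "alpha_amp_uv": self.alpha_amp_uv,
            "theta_amp_uv": self.theta_amp_uv,
            "beta_amp_uv": self.beta_amp_uv,
            "theta_f0_hz": self.theta_f0_hz,
            "beta_f0_hz": self.beta_f0_hz,
            "alpha_peak_mean_hz": self.alpha_peak_mean_hz,
            "alpha_peak_sd_hz": self.alpha_peak_sd_hz,
            "amp_jitter_sd": self.amp_jitter_sd,
            "channels": list(self.layout.names),
            "effects": {
                "alpha_power_ratio_ad": eff.alpha_power_ratio_ad,
                "alpha_peak_shift_ad_hz": eff.alpha_peak_shift_ad_hz,
                "theta_plv_pairs": [[list(p), s] for p, s in eff.theta_plv_pairs],
                "theta_wpli_pairs": [[list(p), s, lag] for p, s, lag in eff.theta_wpli_pairs],
                "tbr_channels": dict(eff.tbr_channels),
                "eo_alpha_attenuation": eff.eo_alpha_attenuation,
                "eo_effects_null": eff.eo_effects_null,
            },
        }

    @staticmethod
    def from_dict(d: Mapping) -> "CohortSpec":
        d = dict(d)
        eff_d = dict(d.pop("effects", {}))
        channels = d.pop("channels", None)
        effects = EffectSpec(
            alpha_power_ratio_ad=eff_d.get("alpha_power_ratio_ad", 0.7),
            alpha_peak_shift_ad_hz=eff_d.get("alpha_peak_shift_ad_hz", -0.33),
            theta_plv_pairs=tuple(
                (tuple(p), float(s)) for p, s in eff_d.get(
                    "theta_plv_pairs", [[["F3", "O1"], 0.5], [["C3", "O1"], 0.5]]
                )
            ),
            theta_wpli_pairs=tuple(
                (tuple(p), float(s), float(lag))
                for p, s, lag in eff_d.get(
                    "theta_wpli_pairs",
                    [
                        [["F3", "F4"], 0.5, math.pi / 4],
                        [["F3", "T4"], 0.5, math.pi / 4],
                        [["F4", "O1"], 0.5, math.pi / 4],
                    ],
                )
            ),
            tbr_channels=dict(eff_d.get("tbr_channels", {"F3": 1.6, "F4": 1.6, "C4": 1.6})),
            eo_alpha_attenuation=eff_d.get("eo_alpha_attenuation", 0.5),
            eo_effects_null=eff_d.get("eo_effects_null", True),
        )
        kwargs = dict(d)
        if channels is not None:
            kwargs["layout"] = ChannelLayout(tuple(channels))
        return CohortSpec(effects=effects, **kwargs)


# ---------------------------------------------------------------------------
# coupling-weight calibration
# ---------------------------------------------------------------------------

_WEIGHT_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
_CALIBRATION_SEED = 745_991  # internal, fixed: lookup must not vary run to run


def _calibration_key(spec: CohortSpec) -> tuple:
    return (
        round(spec.fs, 3),
        round(spec.noise_exponent, 3),
        round(spec.noise_amplitude_uv, 3),
        round(spec.theta_amp_uv, 3),
        round(spec.theta_f0_hz, 3),
        round(spec.osc_bandwidth_hz.get("theta", 1.5), 3),
        round(spec.alpha_amp_uv, 3),
        round(spec.beta_amp_uv, 3),
    )


def _measure_plv_for_weight(w: float, spec: CohortSpec, rng: Generator) -> float:
    """Theta PLV between two synthetic channels sharing a weighted source."""
    from .connectivity import plv_pair
    from .io import EpochedRecording, get_band

    fs = spec.fs
    n = int(round(120.0 * fs))
    bw = spec.osc_bandwidth_hz.get("theta", 1.5)
    _, phi_c = phase_diffusing_oscillator(n, fs, spec.theta_f0_hz, bw, 1.0, rng)
    chans = []
    for _ in range(2):
        noise = pink_noise(n, fs, spec.noise_exponent, rng, spec.noise_amplitude_uv)
        alpha, _ = phase_diffusing_oscillator(
            n, fs, spec.alpha_peak_mean_hz, spec.osc_bandwidth_hz.get("alpha", 1.0),
            spec.alpha_amp_uv, rng,
        )
        beta, _ = phase_diffusing_oscillator(
            n, fs, spec.beta_f0_hz, spec.osc_bandwidth_hz.get("beta", 4.0),
            spec.beta_amp_uv, rng,
        )
        _, phi_i = phase_diffusing_oscillator(n, fs, spec.theta_f0_hz, bw, 1.0, rng)
        theta = spec.theta_amp_uv * (
            w * np.cos(phi_c) + math.sqrt(max(0.0, 1 - w * w)) * np.cos(phi_i)
        )
        chans.append(
            noise
            + _confine(alpha, fs, "alpha")
            + _confine(beta, fs, "beta")
            + _confine(theta, fs, "theta")
        )
    n_per = int(round(4.0 * fs))
    n_ep = n // n_per
    epochs = np.stack(
        [np.stack([c[i * n_per : (i + 1) * n_per] for c in chans]) for i in range(n_ep)]
    )
    ep = EpochedRecording(
        subject_id="cal", condition="EC", fs=fs, epochs=epochs,
        epoch_length_s=4.0, layout=ChannelLayout(("A", "B")),
    )
    return plv_pair(ep, "A", "B", get_band("theta"))


def _weight_lookup(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Monotone (measured PLV -> mixing weight) table, cached per spec family."""
    key = _calibration_key(spec)
    if key not in _WEIGHT_CACHE:
        rng = default_rng(_CALIBRATION_SEED)
        weights = np.linspace(0.0, 1.0, 11)
        plvs = np.array(
            [
                np.mean([_measure_plv_for_weight(w, spec, rng) for _ in range(2)])
                for w in weights
            ]
        )
        plvs = np.maximum.accumulate(plvs)  # enforce monotonicity for inversion
        _WEIGHT_CACHE[key] = (plvs, weights)
    return _WEIGHT_CACHE[key]


def coupling_weight_for_target(target_plv: float, spec: CohortSpec) -> float:
    """Mixing weight whose measured theta PLV approximates ``target_plv``.

    Targets above the attainable ceiling saturate at weight 1.
    """
    plvs, weights = _weight_lookup(spec)
    return float(np.interp(target_plv, plvs, weights))


# ---------------------------------------------------------------------------
# subject/cohort synthesis
# ---------------------------------------------------------------------------

def _channel_coupling(
    spec: CohortSpec,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-channel (mixing weight, phase offset) implied by the effect pairs."""
    eff = spec.effects
    weights: dict[str, float] = {}
    offsets: dict[str, float] = {}
    edges: list[tuple[Pair, float, float]] = [
        (pair, s, 0.0) for pair, s in eff.theta_plv_pairs
    ] + [(pair, s, lag) for pair, s, lag in eff.theta_wpli_pairs]
    for (a, b), s, _ in edges:
        w = coupling_weight_for_target(s, spec)
        weights[a] = max(weights.get(a, 0.0), w)
        weights[b] = max(weights.get(b, 0.0), w)
    for (a, b), _, lag in edges:
        if a not in offsets and b not in offsets:
            offsets[a] = 0.0
            offsets[b] = lag
        elif a in offsets and b not in offsets:
            offsets[b] = offsets[a] + lag
        elif b in offsets and a not in offsets:
            offsets[a] = offsets[b] - lag
        # both assigned already: keep existing offsets (cycle in the pair graph)
    for ch in weights:
        offsets.setdefault(ch, 0.0)
    # Average referencing subtracts the across-channel mean, which would
    # strip a shared source carried near-in-phase by several channels.
    # Adding pi to a channel's offset is invisible to PLV (constant shift)
    # and to wPLI (sign flips cancel in the absolute values), so flip
    # offsets greedily to minimize the common mode of the shared source.
    phasor = {ch: weights[ch] * np.exp(1j * offsets[ch]) for ch in weights}
    changed = True
    while changed:
        changed = False
        for ch in sorted(phasor):
            total = sum(phasor.values())
            if abs(total - 2 * phasor[ch]) < abs(total) - 1e-12:
                phasor[ch] = -phasor[ch]
                offsets[ch] += math.pi
                changed = True
    return weights, offsets


def _validate_effect_channels(spec: CohortSpec) -> None:
    known = {n.upper() for n in spec.layout.names}
    unknown = {c for c in spec.effects.channels_used() if c.upper() not in known}
    if unknown:
        raise ConfigError(f"effect channels {sorted(unknown)} not in layout {spec.layout.names}")


def simulate_subject_condition(
    meta: SubjectMeta, condition: str, spec: CohortSpec, seed: int
) -> Recording:
    """Render one subject-condition recording.

    Subject traits (alpha peak, amplitude jitters) derive from the seed
    independently of the condition, so the same seed passed for EC and
    EO yields the same underlying subject with condition-specific noise.
    """
    if condition not in ("EC", "EO"):
        raise ValidationError(f"condition must be EC or EO, got {condition!r}")
    _validate_effect_channels(spec)
    eff = spec.effects
    trait_rng = default_rng(SeedSequence(entropy=int(seed), spawn_key=(0,)))
    cond_rng = default_rng(
        SeedSequence(entropy=int(seed), spawn_key=(1 if condition == "EC" else 2,))
    )

    # subject traits (drawn in fixed order)
    peak_base = trait_rng.normal(spec.alpha_peak_mean_hz, spec.alpha_peak_sd_hz)
    jit_alpha = math.exp(trait_rng.normal(0.0, spec.amp_jitter_sd))
    jit_theta = math.exp(trait_rng.normal(0.0, spec.amp_jitter_sd))
    jit_beta = math.exp(trait_rng.normal(0.0, spec.amp_jitter_sd))

    is_ad = meta.group == "AD"
    apply_group = is_ad and (condition == "EC" or not eff.eo_effects_null)

    alpha_f0 = peak_base + (eff.alpha_peak_shift_ad_hz if apply_group else 0.0)
    alpha_amp = spec.alpha_amp_uv * jit_alpha
    if apply_group:
        alpha_amp *= eff.alpha_power_ratio_ad
    if condition == "EO":
        alpha_amp *= eff.eo_alpha_attenuation

    weights, offsets = _channel_coupling(spec) if apply_group else ({}, {})

    n = spec.n_samples
    n_ch = len(spec.layout)
    bw = spec.osc_bandwidth_hz
    # common theta source: drawn unconditionally so the stream of random
    # draws (hence the background) is identical with and without effects
    _, phi_common = phase_diffusing_oscillator(
        n, spec.fs, spec.theta_f0_hz, bw.get("theta", 1.5), 1.0, cond_rng
    )

    noise = _pink_noise_multi(
        n_ch, n, spec.fs, spec.noise_exponent, spec.noise_amplitude_uv, cond_rng
    )
    alpha = alpha_amp * np.cos(
        _diffusing_phases_multi(n_ch, n, spec.fs, alpha_f0, bw.get("alpha", 1.0), cond_rng)
    )
    phi_ind = _diffusing_phases_multi(
        n_ch, n, spec.fs, spec.theta_f0_hz, bw.get("theta", 1.5), cond_rng
    )
    beta = spec.beta_amp_uv * jit_beta * np.cos(
        _diffusing_phases_multi(n_ch, n, spec.fs, spec.beta_f0_hz, bw.get("beta", 4.0), cond_rng)
    )

    theta_amp = np.full(n_ch, spec.theta_amp_uv * jit_theta)
    w = np.zeros(n_ch)
    off = np.zeros(n_ch)
    for k, ch in enumerate(spec.layout.names):
        if apply_group and ch in eff.tbr_channels:
            theta_amp[k] *= eff.tbr_channels[ch]
        w[k] = weights.get(ch, 0.0)
        off[k] = offsets.get(ch, 0.0)
    theta = theta_amp[:, None] * (
        w[:, None] * np.cos(phi_common[None, :] + off[:, None])
        + np.sqrt(1 - w**2)[:, None] * np.cos(phi_ind)
    )

    data = (
        noise
        + _confine(alpha, spec.fs, "alpha")
        + _confine(theta, spec.fs, "theta")
        + _confine(beta, spec.fs, "beta")
    )
    return Recording(
        subject_id=meta.subject_id,
        condition=condition,
        fs=spec.fs,
        data=data,
        layout=spec.layout,
    )


def _pink_noise_multi(
    n_ch: int, n: int, fs: float, exponent: float, amplitude: float, rng: Generator
) -> np.ndarray:
    """Batched pink noise, one row per channel (same model as pink_noise)."""
    white = rng.standard_normal((n_ch, n))
    spec = rfft(white, axis=1)
    f = rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = irfft(spec * scale, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return amplitude * x / np.where(sd > 0, sd, 1.0)


def _diffusing_phases_multi(
    n_ch: int, n: int, fs: float, f0: float, bandwidth: float, rng: Generator
) -> np.ndarray:
    """Batched random-walk phases, one row per channel."""
    phase0 = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
    trend = 2 * np.pi * f0 * np.arange(n) / fs
    if bandwidth > 0:
        d = 2 * np.pi * bandwidth
        walk = np.cumsum(rng.standard_normal((n_ch, n)), axis=1) * math.sqrt(d / fs)
    else:
        walk = 0.0
    return phase0 + trend[None, :] + walk


def _draw_meta(group: str, index: int, rng: Generator) -> SubjectMeta:
    mean, sd = AD_AGE if group == "AD" else HC_AGE
    m, f = AD_SEX_MF if group == "AD" else HC_SEX_MF
    edu_counts = AD_EDUCATION if group == "AD" else HC_EDUCATION
    age = max(AGE_FLOOR, rng.normal(mean, sd))
    sex = rng.choice(["M", "F"], p=[m / (m + f), f / (m + f)])
    edu = int(rng.choice(np.arange(1, 6), p=np.array(edu_counts) / sum(edu_counts)))
    return SubjectMeta(
        subject_id=f"{group}{index + 1:02d}",
        group=group,
        age=float(age),
        sex=str(sex),
        education=edu,
        handedness="R",
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[Recording], list[SubjectMeta]]:
    """Generate the full cohort: both conditions for every subject.

    Returns (recordings, metas); recordings are ordered subject-major,
    EC before EO.
    """
    _validate_effect_channels(spec)
    root = default_rng(spec.seed)
    metas = [_draw_meta("AD", i, root) for i in range(spec.n_ad)]
    metas += [_draw_meta("HC", i, root) for i in range(spec.n_hc)]
    subject_seeds = root.integers(0, 2**31 - 1, size=len(metas))
    recordings: list[Recording] = []
    for meta, sseed in zip(metas, subject_seeds):
        for condition in ("EC", "EO"):
            recordings.append(
                simulate_subject_condition(meta, condition, spec, int(sseed))
            )
    return recordings, metas
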
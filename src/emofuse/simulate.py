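"""Synthetic multimodal trial generator.

Emulates the statistical structure the perception method assumes:

* EEG trials are sums of band-limited oscillations (filtered white noise,
  amplitude-modulated so the band components are super-Gaussian, as real
  rhythm bursts are). Overall oscillation amplitude scales with the arousal
  level; a left-minus-right amplitude offset on the symmetric electrode
  pairs scales with the valence level. White sensor noise is added.
* Eye records contain a chronologically ordered, non-overlapping stream of
  fixation/saccade/blink events whose rates and durations depend on the
  levels, plus a pupil-diameter series made of slow oscillatory components,
  an illumination-correlated confound, and noise.
* Stimulus rating tables carry per-clip rating samples on both dimensions
  with exactly-controlled normalized scores, so anchor-based selection is
  exercised across the full score range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import EEGTrial, EyeRecord, ValidationError
from .eeg_features import BANDS, _band_sos
from .eye_features import PUPIL_BANDS
from .montage import DEFAULT_MONTAGE, SYMMETRIC_PAIRS
from .stimuli import StimulusRatingTable

#: Baseline per-band RMS amplitudes (arbitrary microvolt-scale units).
BAND_AMPLITUDES = {
    "delta": 8.0,
    "theta": 6.0,
    "slow_alpha": 3.0,
    "alpha": 10.0,
    "beta": 4.0,
    "gamma": 2.0,
}

#: Depth and rate range (Hz) of the slow amplitude modulation of each band
#: component; the modulation makes band noise super-Gaussian (bursty).
ENVELOPE_DEPTH = 0.8
ENVELOPE_RATE_HZ = (0.1, 0.5)

#: White sensor-noise SD added to every channel.
SENSOR_NOISE_SD = 2.0

#: Trial-to-trial variability: the level-conditioned parameters are means of
#: per-trial draws (log-normal for positive quantities, Gaussian offsets for
#: the asymmetry), reflecting the large inter-trial variability of real
#: affective recordings.
GAIN_JITTER_SIGMA = 0.2
ASYM_JITTER_SD = 0.1
EYE_RATE_JITTER_SIGMA = 0.15
EYE_ROT_JITTER_SD = 1.5


@dataclass(frozen=True)
class EyeEventParams:
    """Level-dependent eye-event parameters (index 0 = level 1).

    Rates are events per second; durations are log-normal with the given
    mean (seconds) and a fixed log-space sigma. Blink and saccade rates and
    saccade durations rise with arousal while fixations shorten; saccade and
    fixation rotation angles (degrees) are keyed to the valence level.
    """

    blink_rate: tuple[float, ...] = (0.2, 0.25, 0.3, 0.35, 0.4)
    saccade_rate: tuple[float, ...] = (1.0, 1.15, 1.3, 1.45, 1.6)
    blink_dur_mean: tuple[float, ...] = (0.25,) * 5
    saccade_dur_mean: tuple[float, ...] = (0.040, 0.043, 0.046, 0.049, 0.052)
    fixation_dur_mean: tuple[float, ...] = (0.40, 0.36, 0.32, 0.28, 0.25)
    saccade_rot_mean: tuple[float, ...] = (8.0, 10.0, 12.0, 14.0, 16.0)
    fixation_rot_mean: tuple[float, ...] = (1.2, 1.4, 1.6, 1.8, 2.0)
    duration_sigma: float = 0.3


#: RMS amplitudes of the pupil's slow oscillatory components, one per band in
#: :data:`emofuse.eye_features.PUPIL_BANDS` order (highest band first); the
#: amplitudes scale mildly with the arousal level.
PUPIL_BAND_AMPLITUDES = (0.10, 0.15, 0.20, 0.40)
PUPIL_RATE_HZ = 60.0
PUPIL_BASELINE_MM = 4.0
PUPIL_NOISE_SD = 0.05


@dataclass
class SimConfig:
    """Study conditions for the synthetic recordings."""

    n_trials_per_level: int = 40
    sampling_rate_hz: float = 250.0
    n_channels: int = 30
    trial_duration_s: float = 55.0
    seed: int = 0
    arousal_gain_per_level: tuple[float, ...] = (0.6, 0.85, 1.1, 1.4, 1.8)
    valence_asymmetry_per_level: tuple[float, ...] = (-0.4, -0.2, 0.0, 0.2, 0.4)
    eye_rate_params: EyeEventParams = field(default_factory=EyeEventParams)
    illum_coupling: float = 0.8

    def __post_init__(self) -> None:
        if self.n_trials_per_level <= 0:
            raise ValidationError("n_trials_per_level must be positive")
        if self.sampling_rate_hz <= 0 or self.trial_duration_s <= 0:
            raise ValidationError("sampling rate and duration must be positive")
        if self.n_channels != len(DEFAULT_MONTAGE):
            raise ValidationError("the montage is fixed at 30 named channels")
        for name in ("arousal_gain_per_level", "valence_asymmetry_per_level"):
            if len(getattr(self, name)) != 5:
                raise ValidationError(f"{name} must have length 5")
        if any(g <= 0 for g in self.arousal_gain_per_level):
            raise ValidationError("arousal gains must be positive")
        n = self.sampling_rate_hz * self.trial_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("sampling_rate_hz * trial_duration_s must be integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.trial_duration_s))


def _check_level(level: int, what: str) -> int:
    if not (isinstance(level, (int, np.integer)) and 1 <= level <= 5):
        raise ValidationError(f"{what} level must be an integer in 1..5, got {level!r}")
    return int(level)


def _pair_side_factors(asym: float) -> np.ndarray:
    """Per-channel amplitude factor implementing the left-minus-right offset."""
    factors = np.ones(len(DEFAULT_MONTAGE))
    for left, right in SYMMETRIC_PAIRS:
        factors[DEFAULT_MONTAGE.index(left)] = 1.0 + 0.5 * asym
        factors[DEFAULT_MONTAGE.index(right)] = 1.0 - 0.5 * asym
    return factors


def simulate_eeg_trial(
    cfg: SimConfig,
    arousal_level: int,
    valence_level: int,
    rng: np.random.Generator,
    trial_id: str = "",
    noise_sd: float = SENSOR_NOISE_SD,
) -> EEGTrial:
    """One synthetic EEG trial (channels x samples)."""
    a = _check_level(arousal_level, "arousal")
    v = _check_level(valence_level, "valence")
    fs = cfg.sampling_rate_hz
    n = cfg.n_samples
    t = np.arange(n) / fs
    gain = cfg.arousal_gain_per_level[a - 1] * float(
        np.exp(GAIN_JITTER_SIGMA * rng.standard_normal())
    )
    asym = cfg.valence_asymmetry_per_level[v - 1] + ASYM_JITTER_SD * float(
        rng.standard_normal()
    )
    side = _pair_side_factors(asym)

    # Each channel is one coherent cortical generator: a single broadband
    # noise process shaped into the six rhythm bands (the band oscillations
    # of a channel are phase-consistent), amplitude-modulated by a slow burst
    # envelope shared across bands. The modulation makes the source
    # super-Gaussian; the single-generator structure gives every channel one
    # dominant independent component.
    f_m = rng.uniform(*ENVELOPE_RATE_HZ, size=(cfg.n_channels, 1))
    phase = rng.uniform(0, 2 * np.pi, size=(cfg.n_channels, 1))
    env = 1.0 + ENVELOPE_DEPTH * np.sin(2 * np.pi * f_m * t[None, :] + phase)

    from scipy.signal import sosfiltfilt

    white = rng.standard_normal((cfg.n_channels, n))
    data = np.zeros((cfg.n_channels, n))
    for band in BANDS:
        sos = _band_sos(band, fs)
        osc = sosfiltfilt(sos, white, axis=-1)
        rms = np.sqrt(np.mean(osc**2, axis=-1, keepdims=True))
        rms[rms == 0] = 1.0
        osc /= rms
        amp = BAND_AMPLITUDES[band.name] * gain * side
        data += amp[:, None] * env * osc
    data += noise_sd * rng.standard_normal(data.shape)
    return EEGTrial(
        data=data,
        sampling_rate_hz=fs,
        channel_names=DEFAULT_MONTAGE,
        trial_id=trial_id,
        arousal_level=a,
        valence_level=v,
    )


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    # parameterized so the *linear-space* mean equals `mean`
    mu = np.log(mean) - 0.5 * sigma**2
    return float(rng.lognormal(mu, sigma))


def simulate_eye_record(
    cfg: SimConfig,
    arousal_level: int,
    valence_level: int,
    rng: np.random.Generator,
    trial_id: str = "",
) -> EyeRecord:
    """One synthetic eye record: ordered non-overlapping events + pupil series."""
    a = _check_level(arousal_level, "arousal")
    v = _check_level(valence_level, "valence")
    p = cfg.eye_rate_params
    T = cfg.trial_duration_s
    sig = p.duration_sigma

    # per-trial parameter draws around the level-conditioned means
    jit = lambda: float(np.exp(EYE_RATE_JITTER_SIGMA * rng.standard_normal()))
    blink_rate = p.blink_rate[a - 1] * jit()
    fix_dur = p.fixation_dur_mean[a - 1] * jit()
    sac_dur = p.saccade_dur_mean[a - 1] * jit()
    sac_rot = p.saccade_rot_mean[v - 1] + EYE_ROT_JITTER_SD * rng.standard_normal()
    fix_rot = max(
        0.2, p.fixation_rot_mean[v - 1] + 0.15 * EYE_ROT_JITTER_SD * rng.standard_normal()
    )

    # blinks: Poisson process with level-keyed rate
    blinks: list[tuple[float, float]] = []
    t = rng.exponential(1.0 / blink_rate)
    while True:
        dur = _lognormal(rng, p.blink_dur_mean[a - 1], sig)
        if t + dur >= T:
            break
        blinks.append((t, dur))
        t += dur + rng.exponential(1.0 / blink_rate)

    # alternating fixation/saccade chain filling the non-blink time
    rows: list[tuple[str, float, float, float]] = []
    for onset, dur in blinks:
        rows.append(("blink", onset, dur, np.nan))
    t = 0.0
    bi = 0
    is_fixation = True
    while t < T:
        if bi < len(blinks) and t >= blinks[bi][0]:
            t = blinks[bi][0] + blinks[bi][1] + 1e-4
            bi += 1
            continue
        if is_fixation:
            dur = _lognormal(rng, fix_dur, sig)
            rot = max(0.05, rng.normal(fix_rot, 0.4))
        else:
            dur = _lognormal(rng, sac_dur, sig)
            rot = max(0.5, rng.normal(sac_rot, 4.0))
        if bi < len(blinks) and t + dur > blinks[bi][0]:
            dur = blinks[bi][0] - t - 1e-4
        if t + dur >= T:
            dur = T - t - 1e-4
        if dur > 5e-3:
            rows.append(("fixation" if is_fixation else "saccade", t, dur, rot))
            is_fixation = not is_fixation
        t += max(dur, 1e-4) + 1e-4

    events = pd.DataFrame(
        rows, columns=["event_type", "onset_s", "duration_s", "rotation_deg"]
    ).sort_values("onset_s", kind="stable").reset_index(drop=True)

    # pupil series: slow oscillatory bands + illumination confound + noise
    from scipy.signal import butter, sosfiltfilt

    n = int(round(T * PUPIL_RATE_HZ))
    pupil = np.full(n, PUPIL_BASELINE_MM)
    scale = 1.0 + 0.1 * (a - 3)
    for (low, high), amp in zip(PUPIL_BANDS, PUPIL_BAND_AMPLITUDES):
        sos = butter(2, [low, high], btype="bandpass", fs=PUPIL_RATE_HZ, output="sos")
        comp = sosfiltfilt(sos, rng.standard_normal(n))
        rms = np.sqrt(np.mean(comp**2))
        if rms > 0:
            comp *= amp * scale / rms
        pupil += comp
    lp = butter(2, 0.1, btype="lowpass", fs=PUPIL_RATE_HZ, output="sos")
    lum = sosfiltfilt(lp, rng.standard_normal(n))
    lum = (lum - lum.mean()) / (lum.std() if lum.std() > 0 else 1.0)
    pupil += cfg.illum_coupling * lum
    pupil += PUPIL_NOISE_SD * rng.standard_normal(n)

    return EyeRecord(
        events=events,
        pupil=pupil,
        pupil_rate_hz=PUPIL_RATE_HZ,
        luminance=lum,
        trial_id=trial_id,
        arousal_level=a,
        valence_level=v,
    )


def simulate_rating_table(
    n_clips: int, rng: np.random.Generator, n_raters: int = 15
) -> StimulusRatingTable:
    """Per-clip rating samples on both dimensions with exactly-controlled
    normalized scores spanning the anchor ranges."""
    if n_clips < 40:
        raise ValidationError("need at least 40 clips")
    # target scores: a deterministic spread covering the anchor ranges, the
    # remainder random; score = mean / population SD is met exactly by
    # standardizing the rating noise before scaling.
    n_fixed = 12
    targets_a = np.concatenate(
        [np.linspace(-3.0, 3.0, n_fixed), rng.uniform(-3.0, 3.0, n_clips - n_fixed)]
    )
    targets_v = np.concatenate(
        [np.linspace(-2.0, 3.5, n_fixed), rng.uniform(-2.0, 3.5, n_clips - n_fixed)]
    )
    rows = []
    for i in range(n_clips):
        clip = f"clip_{i:03d}"
        for dim, target in (("arousal", targets_a[i]), ("valence", targets_v[i])):
            sd = rng.uniform(0.6, 1.4)
            z = rng.standard_normal(n_raters)
            z = (z - z.mean()) / z.std()
            ratings = sd * (target + z)
            for r in ratings:
                rows.append((clip, dim, float(r)))
    table = pd.DataFrame(rows, columns=["clip_id", "dimension", "rating"])
    return StimulusRatingTable(table)


@dataclass
class EmotionDataset:
    """A simulated multimodal recording session."""

    eeg_trials: list[EEGTrial]
    eye_records: list[EyeRecord]
    labels: pd.DataFrame  # trial_id, participant_id, arousal_level, valence_level
    config: SimConfig


def simulate_dataset(
    cfg: SimConfig,
    participant_id: str = "p01",
    eeg: bool = True,
    eye: bool = True,
) -> EmotionDataset:
    """Simulate a full balanced session: 5 levels on both dimensions,
    cfg.n_trials_per_level trials per level on each dimension."""
    n_total = cfg.n_trials_per_level * 5
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_total)
    eeg_trials: list[EEGTrial] = []
    eye_records: list[EyeRecord] = []
    rows = []
    for i in range(n_total):
        # Latin-square pairing keeps both dimensions balanced for any
        # multiple-of-5 trial count while spreading the joint combinations.
        arousal = i % 5 + 1
        valence = (i % 5 + i // 5) % 5 + 1
        rng = np.random.default_rng(children[i])
        tid = f"{participant_id}_t{i:04d}"
        if eeg:
            eeg_trials.append(
                simulate_eeg_trial(cfg, arousal, valence, rng, trial_id=tid)
            )
        if eye:
            eye_records.append(
                simulate_eye_record(cfg, arousal, valence, rng, trial_id=tid)
            )
        rows.append((tid, participant_id, arousal, valence))
    labels = pd.DataFrame(
        rows, columns=["trial_id", "participant_id", "arousal_level", "valence_level"]
    )
    return EmotionDataset(eeg_trials, eye_records, labels, cfg)
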
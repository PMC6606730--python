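"""Eye-movement features: per-event-class duration/rotation statistics and
event-rate statistics (20 dimensions per trial), plus optional pupil
spectral features (band PSD mean and differential entropy)."""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .containers import EyeRecord, FeatureVector, ValidationError

logger = logging.getLogger(__name__)

#: Pupil-diameter frequency bands (Hz), highest first.
PUPIL_BANDS: tuple[tuple[float, float], ...] = (
    (0.6, 1.0),
    (0.4, 0.6),
    (0.2, 0.4),
    (0.01, 0.2),
)

#: Floor for the differential entropy of a (near-)constant series.
DE_FLOOR = -20.0

EVENT_CLASS_NAMES = (
    "blink_dur_mean",
    "blink_dur_sd",
    "saccade_dur_mean",
    "saccade_dur_sd",
    "saccade_rot_mean",
    "fixation_dur_mean",
    "fixation_dur_sd",
)

EVENT_STAT_NAMES = (
    "saccade_freq",
    "blink_freq",
    "fixation_freq",
    "fixation_dur_max",
    "fixation_dur_avg",
    "fixation_dur_min",
    "fixation_rot_max",
    "fixation_rot_avg",
    "saccade_dur_max",
    "saccade_dur_avg",
    "saccade_dur_min",
    "saccade_rot_max",
    "saccade_rot_avg",
)


def _dur_stats(durations: np.ndarray, what: str) -> tuple[float, float]:
    """Mean and population SD; (0, 0) with a warning when no events."""
    if len(durations) == 0:
        logger.warning("no %s events; statistics set to 0", what)
        return 0.0, 0.0
    return float(np.mean(durations)), float(np.std(durations))


def event_class_stats(record: EyeRecord) -> FeatureVector:
    """7 values: blink duration mean/SD, saccade duration mean/SD and mean
    rotation angle, fixation duration mean/SD."""
    values = []
    blink = record.events_of("blink")["duration_s"].to_numpy()
    values.extend(_dur_stats(blink, "blink"))
    sacc = record.events_of("saccade")
    sd_mean, sd_sd = _dur_stats(sacc["duration_s"].to_numpy(), "saccade")
    rot = sacc["rotation_deg"].to_numpy()
    rot_mean = float(np.mean(rot)) if len(rot) else 0.0
    values.extend([sd_mean, sd_sd, rot_mean])
    fix = record.events_of("fixation")["duration_s"].to_numpy()
    values.extend(_dur_stats(fix, "fixation"))
    return FeatureVector(
        values=np.array(values),
        names=EVENT_CLASS_NAMES,
        modality="eye",
        trial_id=record.trial_id,
    )


def event_statistical_features(
    record: EyeRecord, trial_duration_s: float
) -> FeatureVector:
    """13 values: saccade/blink/fixation frequency (events per second), then
    duration max/avg/min and rotation-angle max/avg for fixations and for
    saccades."""
    if trial_duration_s <= 0:
        raise ValidationError("trial duration must be positive")
    values = []
    for etype in ("saccade", "blink", "fixation"):
        values.append(len(record.events_of(etype)) / trial_duration_s)
    for etype in ("fixation", "saccade"):
        ev = record.events_of(etype)
        dur = ev["duration_s"].to_numpy()
        rot = ev["rotation_deg"].to_numpy()
        if len(dur):
            values.extend([float(dur.max()), float(dur.mean()), float(dur.min())])
        else:
            values.extend([0.0, 0.0, 0.0])
        if len(rot) and np.any(np.isfinite(rot)):
            finite = rot[np.isfinite(rot)]
            values.extend([float(finite.max()), float(finite.mean())])
        else:
            values.extend([0.0, 0.0])
    return FeatureVector(
        values=np.array(values),
        names=EVENT_STAT_NAMES,
        modality="eye",
        trial_id=record.trial_id,
    )


def assemble_eye_vector(
    record: EyeRecord,
    trial_duration_s: float | None = None,
    include_pupil_spectral: bool = False,
) -> FeatureVector:
    """Per-trial eye vector: event-class stats (7) + event statistics (13)
    = 20 dimensions; pupil spectral features (8 more) are opt-in."""
    if trial_duration_s is None:
        trial_duration_s = len(record.pupil) / record.pupil_rate_hz
    a = event_class_stats(record)
    b = event_statistical_features(record, trial_duration_s)
    values = np.concatenate([a.values, b.values])
    names = a.names + b.names
    if include_pupil_spectral:
        c = pupil_spectral_features(record)
        values = np.concatenate([values, c.values])
        names = names + c.names
    return FeatureVector(
        values=values, names=names, modality="eye", trial_id=record.trial_id
    )


def pupil_spectral_features(record: EyeRecord) -> FeatureVector:
    """8 values: mean PSD and differential entropy of the pupil series in the
    four slow bands (0.6-1.0, 0.4-0.6, 0.2-0.4, 0.01-0.2 Hz).

    DE uses the Gaussian closed form 0.5*ln(2*pi*e*sigma^2) with the band
    variance estimated by integrating the periodogram over the band.
    """
    x = np.asarray(record.pupil, dtype=float)
    fs = record.pupil_rate_hz
    freqs, psd = signal.periodogram(x - x.mean(), fs=fs)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 0.0
    values, names = [], []
    for low, high in PUPIL_BANDS:
        mask = (freqs >= low) & (freqs <= high)
        if not np.any(mask):
            raise ValidationError(
                f"pupil series too short to resolve the {low}-{high} Hz band"
            )
        band_psd = psd[mask]
        var = float(band_psd.sum() * df)
        if var <= 0:
            logger.warning("zero band variance; differential entropy floored")
            de = DE_FLOOR
        else:
            de = 0.5 * np.log(2 * np.pi * np.e * var)
        tag = f"{low}-{high}Hz"
        values.extend([float(band_psd.mean()), de])
        names.extend([f"pupil_psd_{tag}", f"pupil_de_{tag}"])
    return FeatureVector(
        values=np.array(values),
        names=tuple(names),
        modality="eye",
        trial_id=record.trial_id,
    )
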
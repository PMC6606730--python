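"""In-memory containers for trials, frames, eye records and feature vectors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class EEGTrial:
    """One multichannel EEG trial.

    data is channels x samples in microvolt-scale arbitrary units;
    channel_names is the ordered 10-20 montage labelling the rows.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    trial_id: str = ""
    arousal_level: Optional[int] = None
    valence_level: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValidationError("EEG trial data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"channel count {self.data.shape[0]} != "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"trial {self.trial_id!r} contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, data: np.ndarray) -> "EEGTrial":
        return EEGTrial(
            data=data,
            sampling_rate_hz=self.sampling_rate_hz,
            channel_names=self.channel_names,
            trial_id=self.trial_id,
            arousal_level=self.arousal_level,
            valence_level=self.valence_level,
        )


@dataclass
class FrameSet:
    """Short-time frames cut from one trial.

    Consecutive frame start offsets differ by ``frame_length_N - overlap_M``.
    """

    frames: list[np.ndarray]
    frame_length_N: int
    overlap_M: int
    source_trial_id: str = ""
    sampling_rate_hz: float = 0.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for f in self.frames:
            if f.shape[-1] != self.frame_length_N:
                raise ValidationError("every frame must have exactly N columns")

    def __len__(self) -> int:
        return len(self.frames)

    def stacked(self) -> np.ndarray:
        """All frames as one (n_frames, channels, N) array."""
        return np.stack(self.frames, axis=0)


#: Eye-movement event types understood by the feature extractors.
EVENT_TYPES = ("fixation", "saccade", "blink")


@dataclass
class EyeRecord:
    """Eye-movement event stream plus pupil-diameter series for one trial.

    events: DataFrame with columns event_type, onset_s, duration_s, rotation_deg
    (rotation_deg is NaN for blinks). pupil/luminance are aligned series sampled
    at pupil_rate_hz; luminance may be absent.
    """

    events: pd.DataFrame
    pupil: np.ndarray
    pupil_rate_hz: float
    luminance: Optional[np.ndarray] = None
    trial_id: str = ""
    arousal_level: Optional[int] = None
    valence_level: Optional[int] = None

    def __post_init__(self) -> None:
        required = {"event_type", "onset_s", "duration_s", "rotation_deg"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValidationError(f"eye events missing columns: {sorted(missing)}")
        onsets = self.events["onset_s"].to_numpy()
        if len(onsets) and np.any(np.diff(onsets) < 0):
            raise ValidationError("event onsets must be nondecreasing")
        if len(self.events) and np.any(self.events["duration_s"].to_numpy() <= 0):
            raise ValidationError("event durations must be positive")
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.luminance is not None:
            self.luminance = np.asarray(self.luminance, dtype=float)
            if self.luminance.shape != self.pupil.shape:
                raise ValidationError("pupil and luminance series must be aligned")

    def events_of(self, event_type: str) -> pd.DataFrame:
        return self.events[self.events["event_type"] == event_type]


@dataclass
class FeatureVector:
    """Named, ordered per-trial (or per-frame) feature values."""

    values: np.ndarray
    names: tuple[str, ...]
    modality: str  # "eeg" | "eye" | "spatial"
    trial_id: str = ""
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.names = tuple(self.names)
        if self.values.shape != (len(self.names),):
            raise ValidationError("values and names must have equal length")
        if self.modality not in ("eeg", "eye", "spatial"):
            raise ValidationError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.trial_id)


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors (same names, same modality) into a trial x feature table."""
    if not vectors:
        raise ValidationError("empty feature list")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise ValidationError("feature vectors have inconsistent names")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        columns=list(names),
        index=[v.trial_id for v in vectors],
    )
    df.index.name = "trial_id"
    return df
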
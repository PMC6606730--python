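"""Time-frequency EEG features: band average power spectral density (APS),
band average energy (AE), and differential APS (DAPS) over symmetric
electrode pairs; plus the [0,1] absolute-min-max feature normalization.

With the 30-channel montage the per-frame feature vector is
30*6 (APS) + 30*6 (AE) + 12*5 (DAPS) = 420 dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EEGTrial, FeatureVector, FrameSet, ValidationError
from .montage import SYMMETRIC_PAIRS, channel_index

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValidationError(f"band {self.name}: require low < high")


#: Canonical EEG rhythm bands. Slow alpha is a sub-band of alpha used for
#: APS/AE but excluded from the hemispheric-difference features.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("slow_alpha", 8.0, 10.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)

#: The 5 bands entering DAPS (all except slow alpha).
DAPS_BANDS: tuple[BandDefinition, ...] = tuple(
    b for b in BANDS if b.name != "slow_alpha"
)

BAND_BY_NAME = {b.name: b for b in BANDS}


def _band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not np.any(mask):
        raise ValidationError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) contains no "
            f"frequency bin at this resolution"
        )
    return mask


def band_power_spectrum(
    frame_channel: np.ndarray, sampling_rate: float, band: BandDefinition
) -> float:
    """APS: mean periodogram PSD over the frequency bins inside the band.

    The frame is assumed already tapered (the framing stage applies the
    Hamming window), so the periodogram here uses a boxcar window.
    """
    x = np.asarray(frame_channel, dtype=float)
    if band.high_hz > sampling_rate / 2:
        raise ValidationError(f"band {band.name} exceeds Nyquist")
    freqs, psd = signal.periodogram(x, fs=sampling_rate, window="boxcar")
    return float(psd[_band_bins(freqs, band)].mean())


def _band_sos(band: BandDefinition, sampling_rate: float) -> np.ndarray:
    nyq = sampling_rate / 2
    low = max(band.low_hz, 1e-3)
    high = min(band.high_hz, nyq * 0.999)
    return signal.butter(4, [low, high], btype="bandpass", fs=sampling_rate, output="sos")


def band_average_energy(
    frame_channel: np.ndarray, sampling_rate: float, band: BandDefinition
) -> float:
    """AE: mean squared sample of the band-filtered frame (zero-phase IIR)."""
    x = np.asarray(frame_channel, dtype=float)
    if band.high_hz > sampling_rate / 2:
        raise ValidationError(f"band {band.name} exceeds Nyquist")
    sos = _band_sos(band, sampling_rate)
    y = signal.sosfiltfilt(sos, x)
    return float(np.mean(y**2))


def daps(
    frame: np.ndarray,
    channel_names: Sequence[str],
    pairs: Sequence[tuple[str, str]] = SYMMETRIC_PAIRS,
    bands: Sequence[BandDefinition] = DAPS_BANDS,
    sampling_rate: float = 250.0,
) -> np.ndarray:
    """Differential APS: left-minus-right APS per symmetric pair and band.

    Signed (not absolute): the direction of the hemispheric asymmetry is the
    valence-informative part. Output is pair-major then band (12 x 5 = 60).
    """
    idx = channel_index(list(channel_names))
    out = np.empty(len(pairs) * len(bands))
    k = 0
    for left, right in pairs:
        for ch in (left, right):
            if ch.upper() not in idx:
                raise ValidationError(f"channel {ch} missing from montage")
        li, ri = idx[left.upper()], idx[right.upper()]
        for band in bands:
            out[k] = band_power_spectrum(frame[li], sampling_rate, band) - \
                band_power_spectrum(frame[ri], sampling_rate, band)
            k += 1
    return out


def eeg_feature_names(channel_names: Sequence[str]) -> tuple[str, ...]:
    names: list[str] = []
    for ch in channel_names:
        for band in BANDS:
            names.append(f"APS_{ch}_{band.name}")
    for ch in channel_names:
        for band in BANDS:
            names.append(f"AE_{ch}_{band.name}")
    for left, right in SYMMETRIC_PAIRS:
        for band in DAPS_BANDS:
            names.append(f"DAPS_{left}-{right}_{band.name}")
    return tuple(names)


def _frame_aps_matrix(
    frames: np.ndarray, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram PSD for every (frame, channel): returns (freqs, psd array
    of shape (n_frames, n_channels, n_bins))."""
    freqs, psd = signal.periodogram(frames, fs=sampling_rate, window="boxcar", axis=-1)
    return freqs, psd


def assemble_eeg_vector(
    frame: np.ndarray,
    channel_names: Sequence[str],
    sampling_rate: float,
) -> FeatureVector:
    """Per-frame 420-dimensional EEG vector: [APS 30x6 | AE 30x6 | DAPS 12x5]."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape[0] != 30 or len(channel_names) != 30:
        raise ValidationError("EEG feature assembly expects the 30-channel montage")
    values = _assemble_from_frames(frame[None, :, :], channel_names, sampling_rate)[0]
    return FeatureVector(values=values, names=eeg_feature_names(channel_names), modality="eeg")


def _assemble_from_frames(
    frames: np.ndarray, channel_names: Sequence[str], sampling_rate: float
) -> np.ndarray:
    """Vectorized per-frame feature assembly: frames (n_frames, 30, N) ->
    (n_frames, 420). Identical to the scalar operators applied per entry."""
    n_frames, n_ch, N = frames.shape
    freqs, psd = _frame_aps_matrix(frames, sampling_rate)
    band_masks = [_band_bins(freqs, b) for b in BANDS]
    aps = np.stack(
        [psd[:, :, m].mean(axis=-1) for m in band_masks], axis=-1
    )  # (n_frames, n_ch, 6)

    flat = frames.reshape(n_frames * n_ch, N)
    ae_list = []
    for band in BANDS:
        sos = _band_sos(band, sampling_rate)
        y = signal.sosfiltfilt(sos, flat, axis=-1)
        ae_list.append(np.mean(y**2, axis=-1).reshape(n_frames, n_ch))
    ae = np.stack(ae_list, axis=-1)  # (n_frames, n_ch, 6)

    idx = channel_index(list(channel_names))
    daps_band_pos = [i for i, b in enumerate(BANDS) if b.name != "slow_alpha"]
    daps_cols = []
    for left, right in SYMMETRIC_PAIRS:
        li, ri = idx[left.upper()], idx[right.upper()]
        daps_cols.append(aps[:, li, daps_band_pos] - aps[:, ri, daps_band_pos])
    dp = np.concatenate(daps_cols, axis=-1)  # (n_frames, 60)

    return np.concatenate(
        [aps.reshape(n_frames, -1), ae.reshape(n_frames, -1), dp], axis=-1
    )


def trial_eeg_features(
    frameset: FrameSet,
) -> FeatureVector:
    """Per-trial EEG vector: mean of the per-frame 420-d vectors."""
    frames = frameset.stacked()
    per_frame = _assemble_from_frames(
        frames, frameset.channel_names, frameset.sampling_rate_hz
    )
    return FeatureVector(
        values=per_frame.mean(axis=0),
        names=eeg_feature_names(frameset.channel_names),
        modality="eeg",
        trial_id=frameset.source_trial_id,
    )


def normalize_features(
    table: pd.DataFrame, participant_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Scale every feature into [0,1] by absolute-value min-max:
    y = (|x| - min|x|) / (max|x| - min|x|), per participant group when ids
    are given. Constant columns map to 0 (logged)."""
    if table.empty:
        raise ValidationError("empty feature table")
    if participant_ids is None:
        return _normalize_group(table)
    parts = pd.Series(list(participant_ids), index=table.index)
    out = table.copy()
    for _, idx in parts.groupby(parts).groups.items():
        out.loc[idx] = _normalize_group(table.loc[idx])
    return out


def _normalize_group(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) < 2:
        raise ValidationError("need >= 2 vectors per group to normalize")
    a = table.abs()
    lo, hi = a.min(axis=0), a.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning(
            "%d constant feature column(s) normalized to 0", int(constant.sum())
        )
    span = span.replace(0, 1.0)
    out = (a - lo) / span
    out.loc[:, constant[constant].index] = 0.0
    return out


class AbsMinMaxScaler:
    """Fit/transform form of :func:`normalize_features` for use inside
    cross-validation (train-fold statistics, clipped transform)."""

    def __init__(self) -> None:
        self.lo_: np.ndarray | None = None
        self.hi_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "AbsMinMaxScaler":
        a = np.abs(np.asarray(X, dtype=float))
        self.lo_ = a.min(axis=0)
        self.hi_ = a.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo_ is None or self.hi_ is None:
            raise ValidationError("scaler not fitted")
        a = np.abs(np.asarray(X, dtype=float))
        span = self.hi_ - self.lo_
        span = np.where(span == 0, 1.0, span)
        out = (a - self.lo_) / span
        out[:, self.hi_ == self.lo_] = 0.0
        return np.clip(out, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
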
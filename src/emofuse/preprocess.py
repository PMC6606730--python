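"""Preprocessing: frame blocking/windowing, FIR band-pass filtering,
artifact-trial rejection and pupil illumination removal."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import EEGTrial, EyeRecord, FrameSet, ValidationError

logger = logging.getLogger(__name__)

#: Frame length / overlap in samples (2 s / 1 s at 250 Hz).
DEFAULT_FRAME_N = 500
DEFAULT_FRAME_M = 250


def hamming_window(N: int) -> np.ndarray:
    """Hamming taper w(n) = 0.54 - 0.46 cos(2 pi n / (N-1)), n = 0..N-1."""
    if N < 2:
        raise ValidationError("window length must be >= 2")
    n = np.arange(N)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (N - 1))


def frame_count(samples: int, N: int, M: int) -> int:
    """Number of complete frames of length N with overlap M; trailing samples
    that do not fill a frame are dropped."""
    if not 0 <= M < N:
        raise ValidationError("require 0 <= M < N")
    if N > samples:
        raise ValidationError(f"frame length {N} exceeds trial length {samples}")
    return (samples - N) // (N - M) + 1


def frame_block(
    trial: EEGTrial,
    N: int = DEFAULT_FRAME_N,
    M: int = DEFAULT_FRAME_M,
    apply_window: bool = True,
) -> FrameSet:
    """Cut a trial into overlapping frames of N samples (hop N - M).

    With apply_window each channel of each frame is tapered by the Hamming
    window, the standard short-time treatment that limits discontinuities at
    frame edges.
    """
    n = frame_count(trial.n_samples, N, M)
    hop = N - M
    w = hamming_window(N) if apply_window else None
    frames = []
    for k in range(n):
        frame = trial.data[:, k * hop : k * hop + N].copy()
        if w is not None:
            frame *= w
        frames.append(frame)
    return FrameSet(
        frames=frames,
        frame_length_N=N,
        overlap_M=M,
        source_trial_id=trial.trial_id,
        sampling_rate_hz=trial.sampling_rate_hz,
        channel_names=trial.channel_names,
    )


def fir_bandpass_taps(
    order: int, low_hz: float, high_hz: float, sampling_rate_hz: float
) -> np.ndarray:
    """Design linear-phase FIR band-pass taps (order + 1 Hamming-windowed taps)."""
    nyq = sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValidationError(
            f"invalid band edges ({low_hz}, {high_hz}) for fs={sampling_rate_hz}"
        )
    # order interpreted as filter order -> order+1 taps; odd tap count keeps a
    # type-I linear-phase response, valid for band-pass.
    numtaps = order + 1 if (order + 1) % 2 == 1 else order + 2
    return signal.firwin(
        numtaps, [low_hz, high_hz], pass_zero=False, window="hamming", fs=sampling_rate_hz
    )


def fir_bandpass(
    trial: EEGTrial,
    order: int = 32,
    low_hz: float = 0.5,
    high_hz: float = 60.0,
) -> EEGTrial:
    """Band-pass each channel with a linear-phase FIR filter (default
    32-order, 0.5-60 Hz), removing drift and high-frequency noise."""
    taps = fir_bandpass_taps(order, low_hz, high_hz, trial.sampling_rate_hz)
    filtered = signal.lfilter(taps, [1.0], trial.data, axis=-1)
    return trial.copy_with(filtered)


def reject_artifact_trials(
    trials: Sequence[EEGTrial], amplitude_threshold: float = 100.0
) -> tuple[list[EEGTrial], list[str]]:
    """Split trials into kept / rejected by a peak-amplitude criterion.

    A trial is rejected iff any sample's absolute value exceeds the threshold;
    this automates the usual manual screening of artifact-contaminated trials.
    """
    if amplitude_threshold <= 0:
        raise ValidationError("amplitude threshold must be positive")
    kept: list[EEGTrial] = []
    rejected_ids: list[str] = []
    for t in trials:
        if np.max(np.abs(t.data)) > amplitude_threshold:
            rejected_ids.append(t.trial_id)
        else:
            kept.append(t)
    return kept, rejected_ids


def remove_pupil_illumination(
    record: EyeRecord, corr_floor: float = 0.1
) -> EyeRecord:
    """Remove the illumination-reflection component from the pupil series.

    The illumination-driven component is the luminance-aligned direction of
    the standardized pupil/luminance covariance; its contribution is
    regressed out of the pupil, shrunk by corr_floor so that incidental
    sample correlation between independent slow series is not removed. The
    cleaned pupil is no more correlated with luminance than the input.
    """
    if record.luminance is None:
        logger.warning(
            "trial %s: no luminance regressor; illumination removal skipped",
            record.trial_id,
        )
        return record
    pupil = record.pupil
    lum = record.luminance
    p_mu, p_sd = pupil.mean(), pupil.std()
    l_sd = lum.std()
    if p_sd == 0 or l_sd == 0:
        # constant pupil or luminance: nothing to estimate
        return record
    zp = (pupil - p_mu) / p_sd
    zl = (lum - lum.mean()) / l_sd
    r = float(np.mean(zp * zl))
    shrunk = np.sign(r) * max(abs(r) - corr_floor, 0.0)
    if shrunk == 0.0:
        return record
    cleaned = (zp - shrunk * zl) * p_sd + p_mu
    return EyeRecord(
        events=record.events,
        pupil=cleaned,
        pupil_rate_hz=record.pupil_rate_hz,
        luminance=record.luminance,
        trial_id=record.trial_id,
        arousal_level=record.arousal_level,
        valence_level=record.valence_level,
    )
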
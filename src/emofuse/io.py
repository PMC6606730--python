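"""Plain-text dataset I/O.

Conventions: EEG trials as one CSV matrix per trial (header row = channel
names, one row per sample); eye events, pupil series, labels and feature
tables as flat CSVs. EDF reading is supported when mne is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import EEGTrial, EyeRecord, ValidationError
from .simulate import EmotionDataset


def write_eeg_trial(trial: EEGTrial, path: str | Path, fmt: str = "%.5g") -> None:
    df = pd.DataFrame(trial.data.T, columns=list(trial.channel_names))
    df.to_csv(path, index=False, float_format=fmt)


def read_eeg_trial(
    path: str | Path,
    sampling_rate_hz: float,
    trial_id: str = "",
    arousal_level: int | None = None,
    valence_level: int | None = None,
) -> EEGTrial:
    df = pd.read_csv(path)
    return EEGTrial(
        data=df.to_numpy(dtype=float).T,
        sampling_rate_hz=sampling_rate_hz,
        channel_names=tuple(df.columns),
        trial_id=trial_id or Path(path).stem,
        arousal_level=arousal_level,
        valence_level=valence_level,
    )


def read_edf_trial(path: str | Path, trial_id: str = "") -> EEGTrial:
    """Read a single-trial EDF recording (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne (pip install emofuse[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGTrial(
        data=raw.get_data(),
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        trial_id=trial_id or Path(path).stem,
    )


def write_dataset(dataset: EmotionDataset, outdir: str | Path) -> None:
    """Write a simulated session under outdir: labels.csv, eeg/<trial>.csv,
    eye_events.csv, pupil.csv, meta.json."""
    out = Path(outdir)
    (out / "eeg").mkdir(parents=True, exist_ok=True)
    dataset.labels.to_csv(out / "labels.csv", index=False)
    for trial in dataset.eeg_trials:
        write_eeg_trial(trial, out / "eeg" / f"{trial.trial_id}.csv")
    ev_rows = []
    pupil_rows = []
    for rec in dataset.eye_records:
        ev = rec.events.copy()
        ev.insert(0, "trial_id", rec.trial_id)
        ev_rows.append(ev)
        t = np.arange(len(rec.pupil)) / rec.pupil_rate_hz
        pupil_rows.append(
            pd.DataFrame(
                {
                    "trial_id": rec.trial_id,
                    "time_s": t,
                    "diameter": rec.pupil,
                    "luminance": rec.luminance
                    if rec.luminance is not None
                    else np.nan,
                }
            )
        )
    if ev_rows:
        pd.concat(ev_rows).to_csv(out / "eye_events.csv", index=False)
        pd.concat(pupil_rows).to_csv(
            out / "pupil.csv", index=False, float_format="%.5g"
        )
    meta = {
        "sampling_rate_hz": dataset.config.sampling_rate_hz,
        "pupil_rate_hz": dataset.eye_records[0].pupil_rate_hz
        if dataset.eye_records
        else None,
        "trial_duration_s": dataset.config.trial_duration_s,
        "seed": dataset.config.seed,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def read_eye_records(datadir: str | Path) -> list[EyeRecord]:
    d = Path(datadir)
    labels = pd.read_csv(d / "labels.csv").set_index("trial_id")
    events = pd.read_csv(d / "eye_events.csv")
    pupil = pd.read_csv(d / "pupil.csv")
    meta = json.loads((d / "meta.json").read_text())
    records = []
    for tid, ev in events.groupby("trial_id", sort=False):
        pu = pupil[pupil["trial_id"] == tid]
        lum = pu["luminance"].to_numpy()
        row = labels.loc[tid]
        records.append(
            EyeRecord(
                events=ev.drop(columns="trial_id").reset_index(drop=True),
                pupil=pu["diameter"].to_numpy(),
                pupil_rate_hz=float(meta["pupil_rate_hz"]),
                luminance=None if np.all(np.isnan(lum)) else lum,
                trial_id=str(tid),
                arousal_level=int(row["arousal_level"]),
                valence_level=int(row["valence_level"]),
            )
        )
    return records


def read_eeg_trials(datadir: str | Path) -> list[EEGTrial]:
    d = Path(datadir)
    labels = pd.read_csv(d / "labels.csv")
    meta = json.loads((d / "meta.json").read_text())
    trials = []
    for _, row in labels.iterrows():
        path = d / "eeg" / f"{row['trial_id']}.csv"
        if not path.exists():
            raise ValidationError(f"missing EEG trial file {path}")
        trials.append(
            read_eeg_trial(
                path,
                sampling_rate_hz=float(meta["sampling_rate_hz"]),
                trial_id=str(row["trial_id"]),
                arousal_level=int(row["arousal_level"]),
                valence_level=int(row["valence_level"]),
            )
        )
    return trials


def write_feature_table(
    df: pd.DataFrame, labels: pd.DataFrame, path: str | Path
) -> None:
    merged = labels.set_index("trial_id").join(df, how="inner").reset_index()
    merged.to_csv(path, index=False, float_format="%.6g")


def read_feature_table(path: str | Path, sep: str = "__") -> tuple[dict, pd.DataFrame]:
    """Load a feature CSV into (features-by-modality, labels) using the
    modality prefix convention (eeg__*, eye__*, spatial__*)."""
    df = pd.read_csv(path)
    label_cols = [
        c for c in ("trial_id", "participant_id", "arousal_level", "valence_level")
        if c in df.columns
    ]
    feats: dict[str, list[str]] = {}
    for col in df.columns:
        if sep in col:
            feats.setdefault(col.split(sep, 1)[0], []).append(col)
    if not feats:
        raise ValidationError("no modality-prefixed feature columns found")
    return (
        {m: df[cols].to_numpy(dtype=float) for m, cols in feats.items()},
        df[label_cols],
    )
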
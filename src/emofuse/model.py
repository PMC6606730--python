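"""Model/Results objects for dual emotion-intensity perception.

`EmotionFusionModel` holds per-modality feature matrices and the intensity
labels of one dimension (arousal or valence); `fit()` trains one SVM per
modality, learns the per-class fuzzy measures from the training confidence
profiles, and returns an `EmotionFusionResults` carrying classifiers,
measures and training diagnostics. `DualEmotionModel` pairs an arousal and a
valence model so both dimensions are perceived synchronously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ValidationError
from .eeg_features import AbsMinMaxScaler
from .fusion import (
    FuzzyMeasure,
    ModalityClassifier,
    classify_fused,
    learn_fuzzy_measures,
    profiles_from_confidences,
    train_modality_classifier,
)

CLASS_IDS = (1, 2, 3, 4, 5)


class EmotionFusionModel:
    """Choquet-fusion classifier over one emotion dimension.

    Parameters
    ----------
    features : mapping of modality name -> (n_trials, n_features) array or
        DataFrame; trials must align across modalities.
    labels : intensity levels (1..5), one per trial.
    dimension : "arousal" or "valence" (informational).
    svm_params : per-modality SVM keyword overrides, e.g. {"C": 1.0}.
    normalize : apply the absolute min-max [0,1] scaling per modality.
    """

    def __init__(
        self,
        features: Mapping[str, np.ndarray | pd.DataFrame],
        labels: Sequence[int],
        dimension: str = "arousal",
        svm_params: Mapping | None = None,
        normalize: bool = True,
        class_ids: Sequence[int] = CLASS_IDS,
    ):
        if not features:
            raise ValidationError("need at least one modality")
        self.modalities = tuple(features)
        self.features = {
            k: np.asarray(v, dtype=float) for k, v in features.items()
        }
        self.labels = np.asarray(labels, dtype=int)
        n = len(self.labels)
        for k, X in self.features.items():
            if X.shape[0] != n:
                raise ValidationError(f"modality {k}: {X.shape[0]} rows != {n} labels")
        self.dimension = dimension
        self.svm_params = dict(svm_params) if svm_params else {}
        self.normalize = normalize
        self.class_ids = tuple(int(c) for c in class_ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str,
        dimension: str | None = None,
        sep: str = "__",
        **kwargs,
    ) -> "EmotionFusionModel":
        """Build from a wide table whose feature columns are prefixed with
        their modality, e.g. ``eeg__APS_F3_alpha``, ``eye__blink_freq``."""
        feats: dict[str, list[str]] = {}
        for col in df.columns:
            if col == label_col or sep not in col:
                continue
            modality = col.split(sep, 1)[0]
            feats.setdefault(modality, []).append(col)
        if not feats:
            raise ValidationError(f"no feature columns with modality prefix '{sep}'")
        features = {m: df[cols].to_numpy(dtype=float) for m, cols in feats.items()}
        return cls(
            features,
            df[label_col].to_numpy(dtype=int),
            dimension=dimension or label_col.replace("_level", ""),
            **kwargs,
        )

    def fit(self, seed: int = 0) -> "EmotionFusionResults":
        scalers: dict[str, AbsMinMaxScaler] = {}
        classifiers: dict[str, ModalityClassifier] = {}
        confidences: dict[str, np.ndarray] = {}
        for k in self.modalities:
            X = self.features[k]
            if self.normalize:
                scaler = AbsMinMaxScaler().fit(X)
                scalers[k] = scaler
                X = scaler.transform(X)
            clf = train_modality_classifier(
                X,
                self.labels,
                modality=k,
                svm_params={**self.svm_params, "random_state": seed},
                class_ids=self.class_ids,
            )
            classifiers[k] = clf
            confidences[k] = clf.confidences(X)
        profiles = profiles_from_confidences(confidences, self.class_ids)
        measures = learn_fuzzy_measures(profiles, list(self.labels))
        return EmotionFusionResults(
            model=self,
            classifiers=classifiers,
            measures=measures,
            scalers=scalers,
            seed=seed,
        )


@dataclass
class EmotionFusionResults:
    """Fitted classifiers, learned fuzzy measures and diagnostics."""

    model: EmotionFusionModel
    classifiers: dict[str, ModalityClassifier]
    measures: dict[int, FuzzyMeasure]
    scalers: dict[str, AbsMinMaxScaler]
    seed: int
    _train_acc: dict[str, float] = field(default_factory=dict)

    def _transform(self, features: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for k in self.model.modalities:
            X = np.asarray(features[k], dtype=float)
            if k in self.scalers:
                X = self.scalers[k].transform(X)
            out[k] = X
        return out

    def predict_confidences(
        self, features: Mapping[str, np.ndarray]
    ) -> dict[str, np.ndarray]:
        Xs = self._transform(features)
        return {k: self.classifiers[k].confidences(Xs[k]) for k in self.model.modalities}

    def predict(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        """Fused level predictions for new trials."""
        conf = self.predict_confidences(features)
        profiles = profiles_from_confidences(conf, self.model.class_ids)
        return np.array([classify_fused(p, self.measures) for p in profiles])

    def predict_modality(
        self, modality: str, features: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        Xs = self._transform(features)
        return self.classifiers[modality].predict(Xs[modality])

    def training_accuracy(self) -> dict[str, float]:
        if not self._train_acc:
            y = self.model.labels
            for k in self.model.modalities:
                pred = self.predict_modality(k, self.model.features)
                self._train_acc[k] = float(np.mean(pred == y))
            self._train_acc["fused"] = float(
                np.mean(self.predict(self.model.features) == y)
            )
        return dict(self._train_acc)

    def summary(self) -> str:
        acc = self.training_accuracy()
        lines = [
            f"Emotion fusion model ({self.model.dimension} dimension)",
            "=" * 52,
            f"trials: {len(self.model.labels)}   classes: {sorted(set(self.model.labels))}",
            f"modalities: {', '.join(self.model.modalities)}   seed: {self.seed}",
            "",
            "training accuracy",
            "-" * 30,
        ]
        for k, v in acc.items():
            lines.append(f"  {k:<10s} {v:6.3f}")
        lines += ["", "learned singleton measure coefficients (per class)", "-" * 50]
        header = "  class  " + "  ".join(f"{m:>10s}" for m in self.model.modalities)
        lines.append(header)
        for cid in self.model.class_ids:
            mu = self.measures[cid]
            vals = "  ".join(
                f"{mu.mu({i}):10.3f}" for i in range(len(self.model.modalities))
            )
            lines.append(f"  {cid:>5d}  {vals}")
        return "\n".join(lines)


class DualEmotionModel:
    """Arousal and valence perception as two independent fusion sub-models
    trained on the same trials."""

    def __init__(
        self,
        features: Mapping[str, np.ndarray | pd.DataFrame],
        labels: pd.DataFrame,
        svm_params: Mapping | None = None,
        normalize: bool = True,
    ):
        for col in ("arousal_level", "valence_level"):
            if col not in labels.columns:
                raise ValidationError(f"labels need column {col}")
        self.arousal = EmotionFusionModel(
            features, labels["arousal_level"], dimension="arousal",
            svm_params=svm_params, normalize=normalize,
        )
        self.valence = EmotionFusionModel(
            features, labels["valence_level"], dimension="valence",
            svm_params=svm_params, normalize=normalize,
        )

    def fit(self, seed: int = 0) -> "DualEmotionResults":
        return DualEmotionResults(
            arousal=self.arousal.fit(seed=seed),
            valence=self.valence.fit(seed=seed + 1),
        )


@dataclass
class DualEmotionResults:
    arousal: EmotionFusionResults
    valence: EmotionFusionResults

    def predict(self, features: Mapping[str, np.ndarray]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arousal_level": self.arousal.predict(features),
                "valence_level": self.valence.predict(features),
            }
        )

    def summary(self) -> str:
        return self.arousal.summary() + "\n\n" + self.valence.summary()
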
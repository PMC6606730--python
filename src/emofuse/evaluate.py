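"""Repeated stratified cross-validation of the fusion pipeline and
prediction scoring (accuracy + row-normalized confusion matrices)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import ValidationError
from .eeg_features import AbsMinMaxScaler
from .fusion import classify_fused, learn_fuzzy_measures, profiles_from_confidences, \
    train_modality_classifier

logger = logging.getLogger(__name__)

CLASS_IDS = (1, 2, 3, 4, 5)


def evaluate_predictions(
    predicted: Sequence[int],
    truth: Sequence[int],
    class_ids: Sequence[int] = CLASS_IDS,
) -> tuple[float, np.ndarray]:
    """Exact-match accuracy and the row-normalized confusion matrix
    confusion[i][j] = P(predicted class j | true class i)."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValidationError("predicted and truth lengths differ")
    if predicted.size == 0:
        raise ValidationError("empty prediction list")
    m = len(class_ids)
    idx = {c: i for i, c in enumerate(class_ids)}
    counts = np.zeros((m, m))
    for p, t in zip(predicted, truth):
        counts[idx[int(t)], idx[int(p)]] += 1
    accuracy = float(np.mean(predicted == truth))
    row_sums = counts.sum(axis=1, keepdims=True)
    confusion = np.divide(counts, row_sums, out=np.zeros_like(counts),
                          where=row_sums > 0)
    return accuracy, confusion


@dataclass
class EvaluationReport:
    """Cross-validated accuracies and confusion matrices.

    accuracies[dimension][modality] is the mean over all repeats x folds
    ("fused" is the Choquet-fusion result); confusion[dimension] is the
    fused 5x5 row-normalized matrix averaged over splits.
    """

    accuracies: dict[str, dict[str, float]]
    accuracy_sd: dict[str, dict[str, float]]
    confusion: dict[str, np.ndarray]
    repeats: int
    folds: int
    n_trials: int
    seed: int
    class_ids: tuple[int, ...] = CLASS_IDS
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Cross-validation report ({self.repeats} x {self.folds}, "
            f"{self.n_trials} trials, seed {self.seed})",
            "=" * 60,
        ]
        for dim, accs in self.accuracies.items():
            lines.append(f"\n{dim} dimension")
            lines.append("-" * 30)
            for mod, a in accs.items():
                sd = self.accuracy_sd[dim][mod]
                lines.append(f"  {mod:<10s} {100 * a:5.1f}%  (sd {100 * sd:4.1f})")
            cm = self.confusion[dim]
            lines.append("  fused confusion (rows = truth):")
            for i, cid in enumerate(self.class_ids):
                lines.append(
                    f"    L{cid}  " + " ".join(f"{v:5.3f}" for v in cm[i])
                )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "accuracies": self.accuracies,
            "accuracy_sd": self.accuracy_sd,
            "confusion": {k: v.tolist() for k, v in self.confusion.items()},
            "repeats": self.repeats,
            "folds": self.folds,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "class_ids": list(self.class_ids),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _split_indices(
    y: np.ndarray, folds: int, rng_seed: int, max_retries: int = 5
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold partition; resplit with a shifted seed if a class is
    ever absent from a training part (degenerate tiny datasets)."""
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=rng_seed + attempt)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(set(np.unique(y[tr])) == set(np.unique(y)) for tr, _ in splits):
            if attempt:
                logger.info("resplit after %d attempt(s)", attempt)
            return splits
    raise ValidationError("could not build folds with every class in training")


def cross_validate(
    features: Mapping[str, np.ndarray | pd.DataFrame],
    labels: pd.DataFrame,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    dimensions: Sequence[str] = ("arousal", "valence"),
    normalization: str = "fold",
    svm_params: Mapping | None = None,
    class_ids: Sequence[int] = CLASS_IDS,
) -> EvaluationReport:
    """Repeated stratified k-fold evaluation of the fusion pipeline.

    For every split, feature scaling, the per-modality SVMs and the fuzzy
    measures are fitted on the training folds only (normalization="fold";
    "global" instead scales once on all trials, the per-participant variant)
    and the held-out fold is scored per modality and fused.
    """
    if normalization not in ("fold", "global"):
        raise ValidationError("normalization must be 'fold' or 'global'")
    feats = {k: np.asarray(v, dtype=float) for k, v in features.items()}
    modalities = tuple(feats)
    n = len(labels)
    for k, X in feats.items():
        if X.shape[0] != n:
            raise ValidationError(f"modality {k}: rows != labels")
    class_ids = tuple(int(c) for c in class_ids)

    global_scaled = None
    if normalization == "global":
        global_scaled = {k: AbsMinMaxScaler().fit_transform(X) for k, X in feats.items()}

    acc: dict[str, dict[str, list[float]]] = {
        d: {m: [] for m in modalities + ("fused",)} for d in dimensions
    }
    conf_sum = {d: np.zeros((len(class_ids), len(class_ids))) for d in dimensions}
    conf_n = {d: 0 for d in dimensions}
    norm_ranges: list[dict] = []

    for dim in dimensions:
        y = labels[f"{dim}_level"].to_numpy(dtype=int)
        dim_off = sum(ord(c) for c in dim) % 97
        for rep in range(repeats):
            split_seed = (seed * 1000 + rep * 17 + dim_off) % (2**31 - 1)
            splits = _split_indices(y, folds, split_seed)
            for train_idx, test_idx in splits:
                conf_train: dict[str, np.ndarray] = {}
                conf_test: dict[str, np.ndarray] = {}
                for k in modalities:
                    if normalization == "fold":
                        scaler = AbsMinMaxScaler().fit(feats[k][train_idx])
                        Xtr = scaler.transform(feats[k][train_idx])
                        Xte = scaler.transform(feats[k][test_idx])
                        norm_ranges.append(
                            {"dimension": dim, "modality": k,
                             "test_idx": test_idx.tolist(),
                             "hi": scaler.hi_.tolist()}
                        )
                    else:
                        Xtr = global_scaled[k][train_idx]
                        Xte = global_scaled[k][test_idx]
                    clf = train_modality_classifier(
                        Xtr, y[train_idx], modality=k,
                        svm_params={**(dict(svm_params) if svm_params else {}),
                                    "random_state": (seed + rep) % (2**31 - 1)},
                        class_ids=class_ids,
                    )
                    acc[dim][k].append(
                        float(np.mean(clf.predict(Xte) == y[test_idx]))
                    )
                    conf_train[k] = clf.confidences(Xtr)
                    conf_test[k] = clf.confidences(Xte)
                train_profiles = profiles_from_confidences(conf_train, class_ids)
                measures = learn_fuzzy_measures(train_profiles, list(y[train_idx]))
                test_profiles = profiles_from_confidences(conf_test, class_ids)
                fused_pred = np.array(
                    [classify_fused(p, measures) for p in test_profiles]
                )
                a, cm = evaluate_predictions(fused_pred, y[test_idx], class_ids)
                acc[dim]["fused"].append(a)
                conf_sum[dim] += cm
                conf_n[dim] += 1

    return EvaluationReport(
        accuracies={d: {m: float(np.mean(v)) for m, v in accs.items()}
                    for d, accs in acc.items()},
        accuracy_sd={d: {m: float(np.std(v)) for m, v in accs.items()}
                     for d, accs in acc.items()},
        confusion={d: conf_sum[d] / max(conf_n[d], 1) for d in dimensions},
        repeats=repeats,
        folds=folds,
        n_trials=n,
        seed=seed,
        class_ids=class_ids,
        diagnostics={"normalization": normalization, "norm_ranges": norm_ranges},
    )


def cross_validate_per_participant(
    features: Mapping[str, np.ndarray | pd.DataFrame],
    labels: pd.DataFrame,
    **kwargs,
) -> dict[str, EvaluationReport]:
    """Run cross_validate separately for each participant_id and return the
    per-participant reports (the pooled variant is cross_validate itself)."""
    if "participant_id" not in labels.columns:
        raise ValidationError("labels need a participant_id column")
    out = {}
    for pid, grp in labels.groupby("participant_id"):
        idx = grp.index.to_numpy()
        sub_feats = {k: np.asarray(v)[idx] for k, v in features.items()}
        out[str(pid)] = cross_validate(sub_feats, grp.reset_index(drop=True), **kwargs)
    return out
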
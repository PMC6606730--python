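"""Stimulus-clip scoring and anchor-based training-set selection.

Each candidate clip carries subjective ratings on the arousal and valence
dimensions. The normalized score of a clip is mean/SD of its ratings; the
training set takes, for each of five anchor scores per dimension, the eight
clips nearest the anchor (without replacement), yielding 40 clips tagged
with intensity levels 1-5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError

logger = logging.getLogger(__name__)

#: Anchor scores per dimension, in level order 1..5. The valence anchors are
#: asymmetric because induced valence skews toward higher intensity.
ANCHORS = {
    "arousal": (-2.5, -0.7, 0.0, 0.7, 2.5),
    "valence": (-1.5, -0.4, 0.0, 1.0, 3.0),
}


def normalized_score(ratings, ddof: int = 0) -> float:
    """mean / SD of a clip's ratings (population SD by default)."""
    r = np.asarray(ratings, dtype=float)
    if r.size < 2:
        raise ValidationError("need at least 2 ratings")
    sd = r.std(ddof=ddof)
    if sd == 0:
        raise ValidationError("zero rating dispersion: score undefined")
    return float(r.mean() / sd)


@dataclass
class StimulusRatingTable:
    """Long-format rating table: columns clip_id, dimension, rating."""

    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"clip_id", "dimension", "rating"}
        if not required <= set(self.ratings.columns):
            raise ValidationError(f"rating table needs columns {sorted(required)}")

    @property
    def clip_ids(self) -> list[str]:
        return sorted(self.ratings["clip_id"].unique())

    def scores(self, ddof: int = 0) -> pd.DataFrame:
        """Per-clip normalized scores: columns clip_id, score_arousal, score_valence."""
        rows = []
        for clip, grp in self.ratings.groupby("clip_id"):
            row = {"clip_id": clip}
            for dim in ("arousal", "valence"):
                r = grp.loc[grp["dimension"] == dim, "rating"]
                try:
                    row[f"score_{dim}"] = normalized_score(r.to_numpy(), ddof=ddof)
                except ValidationError as exc:
                    raise ValidationError(f"clip {clip}, {dim}: {exc}") from exc
            rows.append(row)
        return pd.DataFrame(rows).sort_values("clip_id").reset_index(drop=True)


def select_training_stimuli(
    table: StimulusRatingTable,
    dimension: str,
    n_per_level: int = 8,
    ddof: int = 0,
) -> pd.DataFrame:
    """Anchor-nearest selection: for each of the five anchors of the chosen
    dimension (processed in level order 1 -> 5), pick the n_per_level clips
    with smallest |score - anchor|, without replacement.

    Returns a DataFrame (clip_id, dimension, level, score); 5 * n_per_level
    unique clips. Distance ties break to the lexicographically lower clip id.
    """
    if dimension not in ANCHORS:
        raise ValidationError(f"unknown dimension {dimension!r}")
    scores = table.scores(ddof=ddof)
    col = f"score_{dimension}"
    if len(scores) < 5 * n_per_level:
        raise ValidationError(
            f"need at least {5 * n_per_level} clips with defined scores, "
            f"got {len(scores)}"
        )
    available = scores[["clip_id", col]].copy()
    out = []
    for level, anchor in enumerate(ANCHORS[dimension], start=1):
        d = (available[col] - anchor).abs()
        picked = (
            available.assign(_d=d)
            .sort_values(["_d", "clip_id"], kind="stable")
            .head(n_per_level)
        )
        for _, row in picked.iterrows():
            out.append((row["clip_id"], dimension, level, row[col]))
        available = available[~available["clip_id"].isin(picked["clip_id"])]
    return pd.DataFrame(out, columns=["clip_id", "dimension", "level", "score"])
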
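"""Unknown-cell rejection from latent encodings.

A Local Outlier Factor (LOF) model is fitted in novelty mode on the
*learning* split's encodings, so scores for new points are always computed
against that reference and reference points never score themselves.  The
similarity score of a query is the negative LOF (higher = denser
neighborhood = more like the training distribution; a deep inlier sits near
-1).  The unassigned threshold is derived from the *validation* split:
per cell type, a Tukey lower fence

    w_c = q1 - 1.5 (q3 - q1)

of the type's validation similarity scores, then the threshold is the mean
of the per-type fences.  At prediction a cell with similarity strictly
below the threshold is labeled "unassigned"; a cell exactly at the fence is
kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor


@dataclass
class SimilarityScores:
    """Per-cell similarity scores with provenance tag (validation or query)."""

    cell_ids: list
    scores: np.ndarray = field(repr=False)
    split: str = "query"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.cell_ids),):
            raise ValueError("one score per cell id required")
        if not np.isfinite(self.scores).all():
            raise ValueError("similarity scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "similarity": self.scores, "split": self.split})


@dataclass
class NoveltyModel:
    """LOF reference set plus per-cell-type fences and the scalar threshold."""

    k: int
    reference: np.ndarray = field(repr=False)
    lof: LocalOutlierFactor = field(repr=False, default=None)
    fences: dict | None = None
    threshold: float | None = None

    @property
    def calibrated(self) -> bool:
        return self.threshold is not None


def fit_lof(reference, k: int = 20) -> NoveltyModel:
    """Fit LOF in novelty mode on reference encodings (one row per cell)."""
    reference = np.asarray(reference, dtype=np.float64)
    if reference.ndim != 2:
        raise ValueError("reference encodings must be 2-D (cells x dims)")
    n = reference.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the reference size n={n}")
    lof = LocalOutlierFactor(n_neighbors=k, novelty=True)
    lof.fit(reference)
    return NoveltyModel(k=k, reference=reference, lof=lof)


def score(model: NoveltyModel, queries) -> np.ndarray:
    """Similarity = -LOF of each query against the reference (higher = inlier)."""
    queries = np.asarray(queries, dtype=np.float64)
    if queries.ndim != 2 or queries.shape[1] != model.reference.shape[1]:
        raise ValueError(
            f"query dimension {queries.shape} does not match reference "
            f"dimension {model.reference.shape[1]}"
        )
    # sklearn's score_samples in novelty mode is already the negated LOF
    return model.lof.score_samples(queries)


def tukey_lower_fence(scores) -> float:
    """q1 - 1.5 IQR with linearly interpolated quartiles."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("cannot compute a fence from an empty score vector")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    q1, q3 = np.quantile(scores, [0.25, 0.75], method="linear")
    return float(q1 - 1.5 * (q3 - q1))


def calibrate_threshold(
    model: NoveltyModel, validation_scores, validation_labels, expected_labels=None
) -> NoveltyModel:
    """Set the unassigned threshold to the mean of per-type lower fences.

    Fences are computed per cell type on *validation* similarity scores only;
    every expected cell type must contribute at least one score.
    """
    scores = np.asarray(validation_scores, dtype=np.float64)
    labels = np.asarray(validation_labels)
    if scores.shape != labels.shape:
        raise ValueError("validation scores and labels must align")
    present = set(labels.tolist())
    expected = sorted(present) if expected_labels is None else list(expected_labels)
    missing = [c for c in expected if c not in present]
    if missing:
        raise ValueError(f"cell types absent from validation split: {missing}")
    model.fences = {c: tukey_lower_fence(scores[labels == c]) for c in expected}
    model.threshold = float(np.mean(list(model.fences.values())))
    return model


def is_unassigned(model: NoveltyModel, scores) -> np.ndarray:
    """True for cells whose similarity falls strictly below the threshold."""
    if not model.calibrated:
        raise ValueError("novelty model has no calibrated threshold")
    return np.asarray(scores, dtype=np.float64) < model.threshold
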
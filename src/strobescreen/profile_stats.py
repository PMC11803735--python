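"""Profile-level analyses of motion vectors.

A well's full-battery MI trace is its behavioral profile.  Two analyses ask
whether treatment classes are distinct and predictable: a multiclass
random-forest classifier evaluated by stratified cross-validation (confusion
matrix, per-class recall) and a 2-D t-SNE embedding of the motion vectors
for visual structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .motion_index import WellTrace


@dataclass
class ProfileMatrix:
    """Wells x MI-samples matrix with class labels."""

    values: np.ndarray
    labels: np.ndarray
    wells: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("profile matrix must be 2-D")
        if len(self.labels) != self.values.shape[0] or len(self.wells) != self.values.shape[0]:
            raise ValueError("labels/wells must match the number of rows")
        if np.isnan(self.values).any():
            raise ValueError("profile matrix contains missing values")

    @property
    def classes(self) -> list[str]:
        return sorted(set(map(str, self.labels)))


def build_profile_matrix(
    traces: Sequence[WellTrace],
    classes: Optional[Sequence[str]] = None,
    downsample_factor: int = 1,
) -> ProfileMatrix:
    """Stack MI traces into a wells x samples matrix.

    ``downsample_factor`` block-averages consecutive samples (factor 25 at
    25 fps gives per-second means); a trailing partial block is dropped.
    Class labels default to each trace's treatment id.
    """
    if not traces:
        raise ValueError("no traces supplied")
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    n = traces[0].mi.size
    if any(t.mi.size != n for t in traces):
        raise ValueError("all traces must have the same length")
    if classes is None:
        classes = [t.treatment for t in traces]
    if len(classes) != len(traces):
        raise ValueError("one class label per trace required")
    rows = []
    k = downsample_factor
    m = n // k
    for t in traces:
        v = t.mi[: m * k]
        rows.append(v.reshape(m, k).mean(axis=1) if k > 1 else v.copy())
    wells = [f"{t.plate}:{t.well}" if t.plate else t.well for t in traces]
    return ProfileMatrix(np.vstack(rows), np.asarray(classes), wells)


@dataclass
class ConfusionMatrix:
    """Out-of-sample confusion counts (rows = true class) with per-class recall."""

    counts: pd.DataFrame
    recall: pd.Series

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        return float(np.trace(self.counts.to_numpy()) / total)


def classify_profiles(
    matrix: ProfileMatrix,
    n_trees: int = 500,
    cv_folds: int = 5,
    seed: int = 0,
    n_jobs: int = 1,
) -> ConfusionMatrix:
    """Stratified cross-validated random-forest classification of profiles.

    Every prediction is out-of-sample (each well predicted by a forest that
    never saw it), so the confusion matrix measures whether the phenotype
    classes are predictable, not merely memorizable.  ``n_jobs`` is a
    performance hint only; results depend on the seed, never on worker count.
    """
    y = np.asarray([str(c) for c in matrix.labels])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < cv_folds:
        lacking = classes[counts < cv_folds]
        raise ValueError(
            f"classes {list(lacking)} have fewer wells than cv_folds={cv_folds}"
        )
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=n_jobs
    )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, matrix.values, y, cv=cv, n_jobs=1)
    cm = _sk_confusion(y, pred, labels=classes)
    counts_df = pd.DataFrame(cm, index=classes, columns=classes)
    recall = pd.Series(np.diag(cm) / cm.sum(axis=1), index=classes, name="recall")
    return ConfusionMatrix(counts_df, recall)


def embed_2d(
    matrix: ProfileMatrix,
    perplexity: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """t-SNE embedding of the motion vectors: one 2-D point per well.

    Deterministic under the seed; perplexity must be below the well count.
    Returns a DataFrame with well, label, x, y.
    """
    n = matrix.values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 wells to embed")
    if not perplexity < n:
        raise ValueError(f"perplexity {perplexity} must be below n wells ({n})")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    xy = tsne.fit_transform(matrix.values)
    return pd.DataFrame(
        {
            "well": matrix.wells,
            "label": [str(c) for c in matrix.labels],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
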
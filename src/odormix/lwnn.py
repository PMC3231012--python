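"""Locally weighted nearest-neighbor (LWNN) classification of odor mixtures.

Each predefined class (a component set such as "M" or "MEA") is summarized by
its centroid o and a per-feature weight vector w.  A query x is assigned to
the class whose centroid minimizes the weighted Euclidean distance

    d(x, o_i) = sqrt( sum_j w_ij (x_j - o_ij)^2 ).

The weights minimize the total squared weighted distance of the training
points to their own centroid subject to the unit-product constraint
prod_j w_ij = 1 (without a constraint the trivial minimum is w = 0).  By
Lagrange multipliers the solution is closed-form: with the per-feature
scatter S_ij = sum_{p in class i} (p_j - o_ij)^2,

    w_ij = lambda_i / S_ij,     lambda_i = (prod_j S_ij)^(1/m),

i.e. features on which a class is tightly concentrated get large weights.
This is a nearest-centroid rule (K = 1); no K search is needed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ComponentSet, ComponentUniverse, Dataset
from .preprocess import normalize_pattern

__all__ = [
    "ClassScatter",
    "LwnnClassModel",
    "LwnnModel",
    "compute_centroid",
    "compute_class_weights",
    "train_lwnn",
    "weighted_distance",
    "classify",
]

#: relative floor applied to per-feature scatter before inversion
DEFAULT_SCATTER_FLOOR = 1e-12


@dataclass
class ClassScatter:
    """Per-feature within-class scatter S and its geometric-mean normalizer."""

    per_feature_scatter: np.ndarray
    normalizer: float


@dataclass
class LwnnClassModel:
    label: ComponentSet
    centroid: np.ndarray
    weights: np.ndarray


@dataclass
class LwnnModel:
    classes: list[LwnnClassModel]
    normalization: str | None = "l2"

    @property
    def m(self) -> int:
        return self.classes[0].centroid.shape[0]

    def class_labels(self) -> list[str]:
        return [c.label.label for c in self.classes]

    def to_table(self) -> pd.DataFrame:
        """Plain-text serialization: one row per class, centroid then weights."""
        m = self.m
        rows = []
        for c in self.classes:
            row = {"label": c.label.label}
            row.update({f"o_{j+1}": c.centroid[j] for j in range(m)})
            row.update({f"w_{j+1}": c.weights[j] for j in range(m)})
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        df = self.to_table()
        header = f"# normalization: {self.normalization or 'none'}\n"
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.17g")
        Path(path).write_text(header + buf.getvalue())

    @classmethod
    def load(cls, path: str | Path, universe: ComponentUniverse) -> "LwnnModel":
        text = Path(path).read_text().splitlines()
        norm = text[0].split(":", 1)[1].strip()
        df = pd.read_csv(io.StringIO("\n".join(text[1:])))
        m = sum(c.startswith("o_") for c in df.columns)
        classes = []
        for _, row in df.iterrows():
            classes.append(
                LwnnClassModel(
                    label=universe.set_from_label(str(row["label"])),
                    centroid=row[[f"o_{j+1}" for j in range(m)]].to_numpy(float),
                    weights=row[[f"w_{j+1}" for j in range(m)]].to_numpy(float),
                )
            )
        return cls(classes, normalization=None if norm == "none" else norm)


def compute_centroid(points: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Mean point of a class."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need a non-empty 2-d array of points")
    return pts.mean(axis=0)


def compute_class_weights(
    points: Sequence[np.ndarray] | np.ndarray,
    centroid: np.ndarray,
    floor: float = DEFAULT_SCATTER_FLOOR,
) -> tuple[np.ndarray, ClassScatter]:
    """Closed-form unit-product feature weights for one class.

    The per-feature scatter is clamped below at ``floor * mean(S)`` so a
    feature that happens to be constant within a class cannot receive an
    infinite weight.  A class whose scatter is zero in every feature (e.g. a
    singleton class) carries no anisotropy information and gets unit weights.
    """
    pts = np.asarray(points, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    m = centroid.shape[0]
    if m == 0:
        raise ValueError("zero-length feature vectors")
    S = ((pts - centroid) ** 2).sum(axis=0)
    mean_S = S.mean()
    if mean_S == 0.0:
        w = np.ones(m)
        return w, ClassScatter(S, 1.0)
    S_clamped = np.maximum(S, floor * mean_S)
    # geometric mean in log space for numerical range safety
    lam = float(np.exp(np.mean(np.log(S_clamped))))
    w = lam / S_clamped
    return w, ClassScatter(S_clamped, lam)


def train_lwnn(
    train: Dataset,
    normalization: str | None = "l2",
    floor: float = DEFAULT_SCATTER_FLOOR,
) -> LwnnModel:
    """Fit one centroid + weight vector per distinct component-set label."""
    if len(train) == 0:
        raise ValueError("empty training dataset")
    groups: dict[str, list[np.ndarray]] = {}
    labels: dict[str, ComponentSet] = {}
    for s in train:
        if s.label is None:
            raise ValueError(f"sample {s.sample_id!r} is unlabeled")
        x = s.features
        if normalization is not None:
            x = normalize_pattern(x, normalization)
        groups.setdefault(s.label.label, []).append(x)
        labels[s.label.label] = s.label
    classes = []
    for lab in sorted(groups):
        pts = np.asarray(groups[lab])
        o = compute_centroid(pts)
        w, _ = compute_class_weights(pts, o, floor=floor)
        classes.append(LwnnClassModel(labels[lab], o, w))
    return LwnnModel(classes, normalization=normalization)


def weighted_distance(x: np.ndarray, cls: LwnnClassModel) -> float:
    """Weighted Euclidean distance from x to a class centroid."""
    x = np.asarray(x, dtype=float)
    if x.shape != cls.centroid.shape:
        raise ValueError(
            f"feature length {x.shape} does not match centroid {cls.centroid.shape}"
        )
    d = x - cls.centroid
    return float(np.sqrt(np.sum(cls.weights * d * d)))


def classify(x: np.ndarray, model: LwnnModel) -> ComponentSet:
    """Assign x to the class of the nearest (weighted) centroid.

    Ties are broken toward the lexicographically smallest canonical label so
    classification is deterministic.
    """
    if not model.classes:
        raise ValueError("model has no classes")
    x = np.asarray(x, dtype=float)
    if model.normalization is not None:
        x = normalize_pattern(x, model.normalization)
    best: ComponentSet | None = None
    best_d = np.inf
    for cls in model.classes:
        d = weighted_distance(x, cls)
        if d < best_d or (d == best_d and best is not None and cls.label.label < best.label):
            best, best_d = cls.label, d
    assert best is not None
    return best
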
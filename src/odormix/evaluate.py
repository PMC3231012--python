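"""Metrics, baseline classifiers and experiment runners.

Provides the RMSE and accuracy metrics, the three KNN-style comparison
baselines (plain KNN, KNN after PCA, KNN after a regularized LDA
projection), a comparison runner that sweeps K for each baseline while LWNN
is evaluated once (its K is structurally 1), and a concentration-estimation
runner that applies CLS or WCLS per test sample and aggregates RMSE by
component set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.decomposition import PCA

from .data import ComponentSet, Dataset
from .lwnn import LwnnModel, classify, train_lwnn
from .preprocess import normalize_pattern
from .unmix import (
    EstimationResult,
    MixtureModel,
    SensorWeights,
    solve_cls,
    solve_wcls,
)

__all__ = [
    "rmse",
    "accuracy",
    "confusion_table",
    "AccuracyReport",
    "EstimationReport",
    "knn_classify",
    "Projection",
    "project_pca",
    "project_lda",
    "run_comparison",
    "estimate_dataset",
]


def rmse(c_est: np.ndarray, c_real: np.ndarray) -> float:
    """Root mean squared error over all n components (absent ones count at 0 ppm)."""
    c_est = np.asarray(c_est, dtype=float)
    c_real = np.asarray(c_real, dtype=float)
    if c_est.shape != c_real.shape or c_est.ndim != 1 or c_est.size == 0:
        raise ValueError("concentration vectors must be equal-length and non-empty")
    d = c_est - c_real
    return float(np.sqrt(np.mean(d * d)))


def accuracy(pred: list, truth: list) -> float:
    """Percentage of matching labels (component sets or their label strings)."""
    if len(pred) != len(truth) or not pred:
        raise ValueError("prediction and truth lists must be equal-length and non-empty")
    to_s = lambda x: x.label if isinstance(x, ComponentSet) else str(x)
    hits = sum(to_s(p) == to_s(t) for p, t in zip(pred, truth))
    return 100.0 * hits / len(pred)


def confusion_table(pred: list, truth: list) -> pd.DataFrame:
    """Rows = true component set, columns = predicted, values = counts."""
    to_s = lambda x: x.label if isinstance(x, ComponentSet) else str(x)
    t = [to_s(x) for x in truth]
    p = [to_s(x) for x in pred]
    labels = sorted(set(t) | set(p))
    table = pd.DataFrame(0, index=labels, columns=labels)
    for ti, pi in zip(t, p):
        table.loc[ti, pi] += 1
    return table


@dataclass
class AccuracyReport:
    method: str
    K: int | None
    accuracy: float  # percent, reported to 2 decimals
    confusion: pd.DataFrame
    best: bool = False


@dataclass
class EstimationReport:
    """Per-sample estimates plus RMSE aggregates by component set."""

    method: str
    results: pd.DataFrame  # sample_id, label, c_* estimates, objective, rmse
    per_set_mean_rmse: pd.Series
    max_rmse: float | None


# ---------------------------------------------------------------------------
# KNN baseline

def knn_classify(train: Dataset, x: np.ndarray, K: int) -> ComponentSet:
    """Majority vote among the K Euclidean-nearest training samples.

    Distance ties keep training-sample order (stable sort); vote ties fall
    back to the tied label whose nearest representative is closest, then to
    the lexicographically smallest label.
    """
    N = len(train)
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, {N}]")
    X = train.feature_matrix()
    d = np.linalg.norm(X - np.asarray(x, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")[:K]
    votes: dict[str, int] = {}
    nearest_rank: dict[str, int] = {}
    labels: dict[str, ComponentSet] = {}
    for rank, idx in enumerate(order):
        lab = train.samples[idx].label
        if lab is None:
            raise ValueError(f"training sample {train.samples[idx].sample_id!r} is unlabeled")
        votes[lab.label] = votes.get(lab.label, 0) + 1
        nearest_rank.setdefault(lab.label, rank)
        labels[lab.label] = lab
    best = min(votes, key=lambda lab: (-votes[lab], nearest_rank[lab], lab))
    return labels[best]


# ---------------------------------------------------------------------------
# dimensionality-reduction baselines

@dataclass
class Projection:
    """Linear map x -> (x - mean) @ components.T applied before KNN."""

    mean: np.ndarray
    components: np.ndarray  # (d, m)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.components.T

    def transform_dataset(self, ds: Dataset) -> Dataset:
        from .data import OdorSample

        return Dataset(
            ds.universe,
            [
                OdorSample(s.sample_id, self(s.features), label=s.label,
                           concentrations=s.concentrations)
                for s in ds
            ],
        )


def project_pca(features: np.ndarray, d: int | None = None,
                variance: float = 0.95) -> Projection:
    """PCA projection onto the top-d principal directions.

    With ``d=None`` the smallest dimension capturing ``variance`` of the
    training variance is used.
    """
    X = np.asarray(features, dtype=float)
    if d is not None and not 1 <= d <= X.shape[1]:
        raise ValueError(f"d must be in [1, {X.shape[1]}]")
    pca = PCA(n_components=d if d is not None else variance, svd_solver="full")
    pca.fit(X)
    return Projection(pca.mean_, pca.components_)


def project_lda(features: np.ndarray, labels: list, d: int | None = None,
                reg: float = 1e-8) -> Projection:
    """Fisher discriminant projection via the generalized eigenproblem.

    Solves S_b v = mu (S_w + eps I) v with eps = reg * trace(S_w)/m, keeping
    the top-d eigenvectors; default d = min(#classes - 1, m).  The small
    ridge keeps the within-class scatter invertible for singleton classes.
    """
    X = np.asarray(features, dtype=float)
    labs = [l.label if isinstance(l, ComponentSet) else str(l) for l in labels]
    classes = sorted(set(labs))
    N_cls, m = len(classes), X.shape[1]
    if N_cls < 2:
        raise ValueError("LDA needs at least two classes")
    if d is None:
        d = min(N_cls - 1, m)
    if not 1 <= d <= min(m, N_cls - 1):
        raise ValueError(f"d must be in [1, {min(m, N_cls - 1)}]")
    mean = X.mean(axis=0)
    Sw = np.zeros((m, m))
    Sb = np.zeros((m, m))
    for cls in classes:
        Xi = X[[l == cls for l in labs]]
        mu = Xi.mean(axis=0)
        D = Xi - mu
        Sw += D.T @ D
        dm = (mu - mean)[:, None]
        Sb += Xi.shape[0] * (dm @ dm.T)
    eps = reg * (np.trace(Sw) / m if np.trace(Sw) > 0 else 1.0)
    vals, vecs = eigh(Sb, Sw + eps * np.eye(m))
    order = np.argsort(vals)[::-1][:d]
    return Projection(mean, vecs[:, order].T)


# ---------------------------------------------------------------------------
# runners

def run_comparison(
    train: Dataset,
    test: Dataset,
    methods: tuple[str, ...] = ("knn", "pca+knn", "lda+knn", "lwnn"),
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5),
    normalization: str | None = "l2",
) -> list[AccuracyReport]:
    """Accuracy of each method on the test set, sweeping K for the baselines.

    LWNN has no K to sweep and is reported once.  ``normalization`` is the
    pattern normalization applied to features before every method (None for
    raw averaged responses); which mode was active is recorded implicitly by
    the caller's configuration.
    """

    def normalized(ds: Dataset) -> Dataset:
        if normalization is None:
            return ds
        from .data import OdorSample

        return Dataset(
            ds.universe,
            [
                OdorSample(s.sample_id, normalize_pattern(s.features, normalization),
                           label=s.label, concentrations=s.concentrations)
                for s in ds
            ],
        )

    tr, te = normalized(train), normalized(test)
    truth = [s.label for s in te]
    reports: list[AccuracyReport] = []

    def knn_reports(name: str, tr_m: Dataset, te_m: Dataset) -> list[AccuracyReport]:
        out = []
        for K in k_range:
            pred = [knn_classify(tr_m, s.features, K) for s in te_m]
            out.append(AccuracyReport(name, K, accuracy(pred, truth),
                                      confusion_table(pred, truth)))
        return out

    for method in methods:
        if method == "knn":
            reports += knn_reports("KNN", tr, te)
        elif method == "pca+knn":
            proj = project_pca(tr.feature_matrix())
            reports += knn_reports("PCA+KNN", proj.transform_dataset(tr),
                                   proj.transform_dataset(te))
        elif method == "lda+knn":
            proj = project_lda(tr.feature_matrix(), [s.label for s in tr])
            reports += knn_reports("LDA+KNN", proj.transform_dataset(tr),
                                   proj.transform_dataset(te))
        elif method == "lwnn":
            # features already normalized above; the model must not renormalize
            model = train_lwnn(tr, normalization=None)
            pred = [classify(s.features, model) for s in te]
            reports.append(AccuracyReport("LWNN", None, accuracy(pred, truth),
                                          confusion_table(pred, truth)))
        else:
            raise ValueError(f"unknown method {method!r}")

    for name in {r.method for r in reports}:
        group = [r for r in reports if r.method == name]
        best = max(group, key=lambda r: r.accuracy)
        best.best = True
    return reports


def estimate_dataset(
    model: MixtureModel,
    test: Dataset,
    weights: SensorWeights | None = None,
    method: str = "wcls",
) -> EstimationReport:
    """Estimate concentrations for every test sample and aggregate RMSE.

    ``method`` is "wcls" (requires weights) or "cls".  RMSE columns appear
    only when the test samples carry true concentrations.
    """
    if method not in ("cls", "wcls"):
        raise ValueError(f"unknown method {method!r}")
    if method == "wcls" and weights is None:
        raise ValueError("wcls requires sensor weights")
    universe = test.universe
    rows = []
    for s in test:
        res: EstimationResult = (
            solve_wcls(model, s.features, weights) if method == "wcls"
            else solve_cls(model, s.features)
        )
        row: dict = {"sample_id": s.sample_id,
                     "label": s.label.label if s.label else ""}
        for j, name in enumerate(universe.names):
            row[f"c_{name}"] = res.concentrations[j]
        row["objective"] = res.objective
        if s.concentrations is not None:
            res.rmse = rmse(res.concentrations, s.concentrations)
            row["rmse"] = res.rmse
        rows.append(row)
    df = pd.DataFrame(rows)
    if "rmse" in df.columns and df["rmse"].notna().all():
        per_set = df.groupby("label")["rmse"].mean()
        max_rmse = float(df["rmse"].max())
    else:
        per_set = pd.Series(dtype=float)
        max_rmse = None
    return EstimationReport(method.upper(), df, per_set, max_rmse)
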
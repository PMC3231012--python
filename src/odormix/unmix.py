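"""Concentration estimation by (weighted) constrained least squares.

The estimator rests on two assumptions about carbon-black composite sensors:

* homogeneity — a sensor's response to a pure compound is proportional to its
  concentration, r_i(c_j) = alpha_ij * c_j;
* linear additivity — a mixture's response is (approximately) the sum of the
  pure-component responses, refined by a per-sensor affine correction
  r_i(c) = beta_offset_i + sum_j beta_ij * alpha_ij * c_j.

Fitting proceeds in two stages: through-origin slopes alpha_ij from pure
samples, then per-sensor ordinary least squares for the beta coefficients on
the full training set.  Given an observed response vector t, concentrations
are recovered by non-negative least squares on the shifted system
G c ~ t - beta_offset with G_ij = beta_ij alpha_ij (CLS).  The weighted
variant (WCLS) multiplies each sensor's squared residual by a reliability
weight w_i derived from how well the mixture model predicts that sensor on
the training data, normalized so prod_i w_i = 1 — the same closed form as
the LWNN class weights, with training residual sums in place of scatters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data import Dataset

__all__ = [
    "PureOdorModel",
    "MixtureModel",
    "SensorWeights",
    "EstimationResult",
    "fit_pure_model",
    "fit_mixture_model",
    "predict_response",
    "compute_sensor_weights",
    "solve_cls",
    "solve_wcls",
]

DEFAULT_RESIDUAL_FLOOR = 1e-12


@dataclass
class PureOdorModel:
    """Through-origin slopes: alpha[i, j] = response of sensor i per ppm of component j."""

    alpha: np.ndarray  # (m, n)

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @property
    def n(self) -> int:
        return self.alpha.shape[1]


@dataclass
class MixtureModel:
    """Affine additive mixture response model per sensor."""

    beta_offset: np.ndarray  # (m,)
    beta: np.ndarray  # (m, n)
    alpha: np.ndarray  # (m, n) pure slopes the betas compose with
    effective_gain: np.ndarray  # (m, n), beta * alpha elementwise

    @property
    def m(self) -> int:
        return self.beta.shape[0]

    @property
    def n(self) -> int:
        return self.beta.shape[1]

    def to_table(self) -> pd.DataFrame:
        rows = []
        for i in range(self.m):
            row = {"sensor": i + 1, "beta_offset": self.beta_offset[i]}
            for j in range(self.n):
                row[f"alpha_{j+1}"] = self.alpha[i, j]
                row[f"beta_{j+1}"] = self.beta[i, j]
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        buf = io.StringIO()
        self.to_table().to_csv(buf, index=False, float_format="%.17g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "MixtureModel":
        df = pd.read_csv(path)
        n = sum(c.startswith("alpha_") for c in df.columns)
        alpha = df[[f"alpha_{j+1}" for j in range(n)]].to_numpy(float)
        beta = df[[f"beta_{j+1}" for j in range(n)]].to_numpy(float)
        offset = df["beta_offset"].to_numpy(float)
        return cls(offset, beta, alpha, beta * alpha)


@dataclass
class SensorWeights:
    """Unit-product reliability weights; small training residual => large weight."""

    omega: np.ndarray
    normalizer: float
    training_residual_sums: np.ndarray


@dataclass
class EstimationResult:
    """Non-negative concentration estimate with residual diagnostics."""

    concentrations: np.ndarray  # (n,), ppm
    objective: float  # achieved (1/2) sum_i w_i residual_i^2
    rmse: float | None = None  # vs known truth, set by the caller when available


def fit_pure_model(train: Dataset) -> PureOdorModel:
    """Per-sensor, per-component through-origin slopes from pure samples.

    For component j only samples whose single positive component is j enter
    the fit; the slope is the least-squares line through the origin,
    alpha = sum_k r_k c_k / sum_k c_k^2.
    """
    universe = train.universe
    m, n = train.m, universe.n
    alpha = np.zeros((m, n))
    for j, name in enumerate(universe.names):
        pure = [
            s
            for s in train
            if s.concentrations is not None
            and s.concentrations[j] > 0
            and np.count_nonzero(s.concentrations) == 1
        ]
        if not pure:
            raise ValueError(f"no pure training sample for component {name!r}")
        c = np.array([s.concentrations[j] for s in pure])
        R = np.array([s.features for s in pure])  # (k, m)
        alpha[:, j] = (R.T @ c) / (c @ c)
    return PureOdorModel(alpha)


def fit_mixture_model(
    train: Dataset, pure: PureOdorModel, include_pure: bool = True
) -> MixtureModel:
    """Per-sensor OLS of observed responses on the pure-model responses.

    Sensor i's regressors are {alpha_ij * c_j}_j plus an intercept.  By
    default all training samples (pure and mixed) enter the fit; with
    ``include_pure=False`` only samples containing >= 2 components do.
    """
    samples = [s for s in train if s.concentrations is not None]
    if not include_pure:
        samples = [s for s in samples if np.count_nonzero(s.concentrations) >= 2]
    m, n = pure.m, pure.n
    if len(samples) < n + 1:
        raise ValueError(
            f"need at least n+1={n+1} training samples with concentrations, got {len(samples)}"
        )
    C = np.array([s.concentrations for s in samples])  # (k, n)
    T = np.array([s.features for s in samples])  # (k, m)
    beta = np.zeros((m, n))
    offset = np.zeros(m)
    for i in range(m):
        X = np.column_stack([np.ones(len(samples)), C * pure.alpha[i]])  # (k, n+1)
        if np.linalg.matrix_rank(X) < n + 1:
            raise ValueError(f"rank-deficient design for sensor {i + 1}")
        coef, *_ = np.linalg.lstsq(X, T[:, i], rcond=None)
        offset[i] = coef[0]
        beta[i] = coef[1:]
    return MixtureModel(offset, beta, pure.alpha.copy(), beta * pure.alpha)


def predict_response(model: MixtureModel, c: np.ndarray) -> np.ndarray:
    """Predicted sensor responses for a concentration vector (ppm)."""
    c = np.asarray(c, dtype=float)
    if c.shape != (model.n,):
        raise ValueError(f"expected concentration vector of length {model.n}")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite concentration")
    return model.beta_offset + model.effective_gain @ c


def compute_sensor_weights(
    model: MixtureModel, train: Dataset, floor: float = DEFAULT_RESIDUAL_FLOOR
) -> SensorWeights:
    """Unit-product sensor reliability weights from training residuals.

    R_i = sum over training samples of the squared prediction error of sensor
    i, clamped below at floor * mean(R); then w_i = lambda / R_i with lambda
    the geometric mean of the R_i, which enforces prod_i w_i = 1.
    """
    samples = [s for s in train if s.concentrations is not None]
    if not samples:
        raise ValueError("no training samples with concentrations")
    R = np.zeros(model.m)
    for s in samples:
        resid = predict_response(model, s.concentrations) - s.features
        R += resid * resid
    mean_R = R.mean()
    if mean_R == 0.0:
        return SensorWeights(np.ones(model.m), 1.0, R)
    R_clamped = np.maximum(R, floor * mean_R)
    lam = float(np.exp(np.mean(np.log(R_clamped))))
    return SensorWeights(lam / R_clamped, lam, R_clamped)


def _nnls_result(G: np.ndarray, y: np.ndarray, omega: np.ndarray) -> EstimationResult:
    sw = np.sqrt(omega)
    c, _ = nnls(G * sw[:, None], y * sw)
    resid = G @ c - y
    objective = 0.5 * float(np.sum(omega * resid * resid))
    return EstimationResult(c, objective)


def solve_cls(model: MixtureModel, t: np.ndarray) -> EstimationResult:
    """Non-negative least-squares concentration estimate from responses t."""
    t = np.asarray(t, dtype=float)
    if t.shape != (model.m,):
        raise ValueError(f"expected response vector of length {model.m}")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite response")
    return _nnls_result(model.effective_gain, t - model.beta_offset, np.ones(model.m))


def solve_wcls(model: MixtureModel, t: np.ndarray, w: SensorWeights) -> EstimationResult:
    """Weighted variant: sensor i's squared residual is scaled by w.omega[i].

    Equivalent to CLS on the row-scaled system (rows multiplied by sqrt(w));
    with unit weights it reduces exactly to :func:`solve_cls`.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != (model.m,):
        raise ValueError(f"expected response vector of length {model.m}")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite response")
    omega = np.asarray(w.omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("sensor weights must be positive")
    return _nnls_result(model.effective_gain, t - model.beta_offset, omega)
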
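"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the weight oracle is
a generic numerical constrained minimizer, the non-negative least-squares
oracle enumerates every support set, and the KNN oracle is a literal
sort-and-vote.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def minimize_weight_objective(S: np.ndarray, n_starts: int = 4, seed: int = 0) -> np.ndarray:
    """Numerically minimize sum_j w_j S_j subject to prod_j w_j = 1, w > 0.

    Parametrized as w = exp(z) with sum(z) = 0, solved by SLSQP from several
    feasible starting points; returns the best w found.
    """
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    rng = np.random.default_rng(seed)
    best_w, best_obj = None, np.inf
    starts = [np.zeros(m)] + [rng.uniform(-1, 1, m) for _ in range(n_starts - 1)]
    for z0 in starts:
        z0 = z0 - z0.mean()
        res = minimize(
            lambda z: float(np.exp(np.clip(z, -700, 700)) @ S),
            z0,
            jac=lambda z: np.exp(np.clip(z, -700, 700)) * S,
            constraints=[{"type": "eq", "fun": lambda z: z.sum(),
                          "jac": lambda z: np.ones(m)}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        w = np.exp(res.x - res.x.mean())  # re-project onto the constraint
        obj = float(w @ S)
        if obj < best_obj:
            best_w, best_obj = w, obj
    return best_w


def nnls_by_enumeration(G: np.ndarray, y: np.ndarray,
                        omega: np.ndarray | None = None) -> np.ndarray:
    """Global solution of min ||sqrt(omega) (G c - y)||^2, c >= 0, by trying
    the unconstrained least-squares solution on every subset of columns and
    keeping the feasible one with the smallest objective."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = G.shape
    sw = np.ones(m) if omega is None else np.sqrt(np.asarray(omega, dtype=float))
    Gw, yw = G * sw[:, None], y * sw
    best_c, best_obj = np.zeros(n), float(yw @ yw)
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            sub = Gw[:, list(support)]
            coef, *_ = np.linalg.lstsq(sub, yw, rcond=None)
            if np.any(coef < -1e-10):
                continue
            c = np.zeros(n)
            c[list(support)] = np.clip(coef, 0.0, None)
            r = Gw @ c - yw
            obj = float(r @ r)
            if obj < best_obj - 1e-15:
                best_c, best_obj = c, obj
    return best_c


def knn_sort_and_vote(X: np.ndarray, labels: list[str], x: np.ndarray, K: int) -> str:
    """Literal K-nearest-neighbor vote with the package's tie conventions:
    distance ties keep sample order, vote ties prefer the label seen nearest,
    then the lexicographically smallest label."""
    d = [float(np.linalg.norm(row - x)) for row in X]
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:K]
    counts: dict[str, int] = {}
    first_rank: dict[str, int] = {}
    for rank, i in enumerate(order):
        counts[labels[i]] = counts.get(labels[i], 0) + 1
        first_rank.setdefault(labels[i], rank)
    return min(counts, key=lambda lab: (-counts[lab], first_rank[lab], lab))
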
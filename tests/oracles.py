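"""Independent oracles for the bridge solver, built on scipy.optimize.

These deliberately avoid the Sinkhorn code path: the k = 2 oracle reduces
the coupling to its single free parameter and minimizes by bounded scalar
search; the general-k oracle runs SLSQP on the full coupling with equality
constraints on both marginals.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, linear_sum_assignment, minimize, minimize_scalar
from scipy.special import rel_entr


def kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(rel_entr(p, q).sum())


def bruteforce_cost_k2(pi: np.ndarray, pi_target: np.ndarray, Q: np.ndarray) -> float:
    """Exhaustive 1-D minimization over the free entry P_00 of a 2x2 coupling."""
    a, b = pi[0], pi_target[0]
    lo = max(0.0, a + b - 1.0)
    hi = min(a, b)

    def objective(p00: float) -> float:
        P = np.array([[p00, a - p00], [b - p00, 1.0 - a - b + p00]])
        P = np.clip(P, 0.0, None)
        mask = P > 0
        if np.any(mask & (Q == 0)):
            return np.inf
        return kl(P, Q)

    if hi - lo < 1e-15:
        return objective(lo)
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-13})
    return min(res.fun, objective(lo), objective(hi))


def constrained_cost(pi: np.ndarray, pi_target: np.ndarray, Q: np.ndarray) -> float:
    """General-k oracle: trust-region convex solve over the full coupling.

    Equality constraints pin all k row marginals and the first k - 1 column
    marginals (the last is implied), keeping the constraint Jacobian full
    rank.
    """
    k = Q.shape[0]
    x0 = np.outer(pi, pi_target).ravel()
    A_row = np.kron(np.eye(k), np.ones(k))
    A_col = np.kron(np.ones(k), np.eye(k))[:-1]
    constraints = [
        LinearConstraint(A_row, pi, pi),
        LinearConstraint(A_col, pi_target[:-1], pi_target[:-1]),
    ]

    def objective(x):
        return kl(np.clip(x.reshape(k, k), 1e-300, None), Q)

    def jac(x):
        P = np.clip(x.reshape(k, k), 1e-300, None)
        return (np.log(P / Q) + 1.0).ravel()

    res = minimize(
        objective, x0, jac=jac, method="trust-constr",
        bounds=[(1e-14, 1.0)] * (k * k), constraints=constraints,
        options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
    )
    assert res.status in (1, 2), res.message
    return float(res.fun)


def path_kl_by_enumeration(p_path, q_path) -> float:
    """Full-path KL by exhaustive trajectory enumeration (exponential in T)."""
    total = 0.0
    q_probs = dict(q_path.enumerate_paths())
    for path, pp in p_path.enumerate_paths():
        if pp > 0:
            total += pp * np.log(pp / q_probs[path])
    return total


def align_accuracy(truth: np.ndarray, predicted: np.ndarray, k: int) -> float:
    """Assignment accuracy after optimal label matching (Hungarian)."""
    confusion = np.zeros((k, k))
    for t, p in zip(truth, predicted):
        confusion[t, p] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return float(confusion[rows, cols].sum() / truth.size)
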
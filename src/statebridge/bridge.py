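"""Discrete Schrödinger-Bridge endpoint problem and KL transition cost.

The baseline ("uncontrolled") dynamics is a first-order Markov chain with
row-stochastic kernel ``Q_{j|i}``. Moving the system from an initial state
distribution ``pi`` at t = 0 to a target distribution ``pi'`` at t = T
requires deviating from that baseline; the cost of a controlled path law p is
its KL divergence from the uncontrolled path law q. Because the path KL
decomposes into an endpoint term plus a conditional-bridge term that can be
driven to zero, the minimum over controlled paths equals

    C = min_P  D_KL(P || Q)   over couplings P with row marginal pi
                              and column marginal pi',

where ``Q_ij = pi_i * (kernel^T)_ij`` is the uncontrolled endpoint joint.
This is an entropy-regularized optimal-transport problem with cost matrix
``C_ij = -log Q_ij``; its unique minimizer has the Gibbs form
``P*_ij = exp(alpha_i + beta_j) Q_ij`` and is found by Sinkhorn iteration,
run here in the log domain for numerical stability. Costs are in nats.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, rel_entr, xlogy

from .errors import (
    ConvergenceError,
    DimensionError,
    InfeasibleMarginalError,
    SupportViolationError,
)
from .types import (
    BridgeSolution,
    JointEndpointDistribution,
    PathDistribution,
    ProbabilityVector,
    TransitionMatrix,
)

__all__ = [
    "uncontrolled_joint",
    "kl_divergence",
    "solve_bridge",
    "transition_cost",
    "reconstruct_full_path",
    "ot_identity_check",
]


def uncontrolled_joint(
    pi: ProbabilityVector, kernel: TransitionMatrix, T: int = 1
) -> JointEndpointDistribution:
    """Endpoint joint of the uncontrolled chain: Q_ij = pi_i * (kernel^T)_ij.

    ``kernel^T`` is the T-step kernel (T-fold matrix power), so for T > 1 the
    interior of the path is already marginalized out.
    """
    if pi.k != kernel.k:
        raise DimensionError(f"pi has k={pi.k} but kernel has k={kernel.k}")
    stepT = kernel.power(T)
    return JointEndpointDistribution(pi.probs[:, None] * stepT, horizon=T)


def _joint_arrays(P, Q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(P, dtype=float)
    q = np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise DimensionError(f"shape mismatch: {p.shape} vs {q.shape}")
    return p, q


def kl_divergence(P, Q) -> float:
    """D_KL(P || Q) = sum_ij P_ij log(P_ij / Q_ij), in nats.

    Convention 0 * log(0/q) = 0. Mass of P outside the support of Q raises
    :class:`SupportViolationError` rather than silently returning infinity.
    """
    p, q = _joint_arrays(P, Q)
    bad = (p > 0) & (q == 0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise SupportViolationError(
            f"P has mass {p[i, j]:.3g} at ({i}, {j}) where Q is zero; "
            "KL(P || Q) is infinite"
        )
    return float(rel_entr(p, q).sum())


def _check_feasible(pi: np.ndarray, pi_target: np.ndarray, q: np.ndarray) -> None:
    row_mass = q.sum(axis=1)
    col_mass = q.sum(axis=0)
    bad_rows = np.flatnonzero((pi > 0) & (row_mass == 0))
    if bad_rows.size:
        raise InfeasibleMarginalError(
            f"initial distribution has mass on state(s) {bad_rows.tolist()} "
            "(0-based) that are never a source under Q",
            states=bad_rows,
        )
    bad_cols = np.flatnonzero((pi_target > 0) & (col_mass == 0))
    if bad_cols.size:
        raise InfeasibleMarginalError(
            f"target distribution has mass on state(s) {bad_cols.tolist()} "
            "(0-based) that are unreachable under Q",
            states=bad_cols,
        )


def solve_bridge(
    pi: ProbabilityVector,
    pi_target: ProbabilityVector,
    Q: JointEndpointDistribution,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    smoothing: float = 0.0,
) -> BridgeSolution:
    """Find the minimum-KL coupling P* with marginals (pi, pi') relative to Q.

    Alternating log-domain Sinkhorn updates of the multipliers:

        alpha_i = log pi_i  - logsumexp_j(beta_j  + log Q_ij)
        beta_j  = log pi'_j - logsumexp_i(alpha_i + log Q_ij)

    The normalization constant is a gauge freedom once both constraints hold;
    it is folded into alpha so that P* = exp(alpha_i + beta_j) Q_ij exactly.
    Convergence is declared when the max absolute marginal residual of the
    candidate P falls below ``tol``. Deterministic: no randomness anywhere.

    Parameters
    ----------
    smoothing
        Optional lambda in [0, 1): replaces Q with (1-lambda) Q + lambda U,
        U the uniform joint, before solving. Off by default because it
        changes the reported cost; use only to regularize empirical zeros.
    """
    if not (pi.k == pi_target.k == Q.k):
        raise DimensionError(
            f"dimension mismatch: pi k={pi.k}, target k={pi_target.k}, Q k={Q.k}"
        )
    q = np.asarray(Q.joint, dtype=float)
    if smoothing:
        if not 0.0 <= smoothing < 1.0:
            raise ValueError("smoothing must be in [0, 1)")
        q = (1.0 - smoothing) * q + smoothing / q.size
        q = q / q.sum()
    a = pi.probs
    b = pi_target.probs
    _check_feasible(a, b, q)

    with np.errstate(divide="ignore"):
        log_q = np.log(q)
        log_a = np.log(a)
        log_b = np.log(b)

    beta = np.zeros(Q.k)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        alpha = log_a - logsumexp(log_q + beta[None, :], axis=1)
        # pi_i = 0 on a zero row of Q gives -inf - (-inf): that state carries
        # no mass either way, so pin its multiplier at -inf.
        alpha = np.where(np.isnan(alpha), -np.inf, alpha)
        beta = log_b - logsumexp(log_q + alpha[:, None], axis=0)
        beta = np.where(np.isnan(beta), -np.inf, beta)
        # alpha rows are exact after the beta update only up to the change in
        # beta, so the residual is measured on the actual candidate coupling.
        with np.errstate(invalid="ignore"):
            log_p = alpha[:, None] + beta[None, :] + log_q
        log_p = np.where(np.isneginf(log_q), -np.inf, log_p)
        p = np.exp(log_p)
        residual = max(
            float(np.max(np.abs(p.sum(axis=1) - a))),
            float(np.max(np.abs(p.sum(axis=0) - b))),
        )
        if residual <= tol:
            break
    else:
        raise ConvergenceError(
            f"Sinkhorn did not reach tol={tol:g} within {max_iter} iterations "
            f"(last residual {residual:.3g}); the marginals may be infeasible "
            "under the zero pattern of Q",
            residual=residual,
            iterations=max_iter,
        )

    p[q == 0] = 0.0
    p = p / p.sum()  # remove O(tol) normalization slack
    solution_joint = JointEndpointDistribution(p, horizon=Q.horizon)
    cost = kl_divergence(p, q)
    return BridgeSolution(
        optimal_joint=solution_joint,
        alpha=alpha,
        beta=beta,
        cost=cost,
        iterations=it,
        residual=residual,
        converged=True,
        tol=tol,
    )


def transition_cost(
    pi: ProbabilityVector,
    pi_target: ProbabilityVector,
    kernel: TransitionMatrix,
    T: int = 1,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    smoothing: float = 0.0,
) -> float:
    """Minimum KL control cost of steering pi to pi' in T steps, in nats.

    Composes :func:`uncontrolled_joint` and :func:`solve_bridge`; by the
    path-KL decomposition this endpoint minimum equals the full-path minimum.
    """
    Q = uncontrolled_joint(pi, kernel, T)
    return solve_bridge(pi, pi_target, Q, tol=tol, max_iter=max_iter, smoothing=smoothing).cost


def reconstruct_full_path(
    solution: BridgeSolution, kernel: TransitionMatrix, T: int | None = None
) -> PathDistribution:
    """Expand the optimal endpoint coupling into the full controlled path law.

    The optimal path keeps the baseline bridge in its interior:
    p*(x_0..x_T) = P*(x_0, x_T) q(x_1..x_{T-1} | x_0, x_T). Because P* has
    the Gibbs form exp(alpha + beta) Q, this path is a time-inhomogeneous
    Markov chain with step kernels

        K_t(s, s') = kernel(s, s') h_{t+1}(s') / h_t(s),
        h_t(s) = sum_j (kernel^(T-t))_{s,j} exp(beta_j),   h_T = exp(beta),

    obtained by backward recursion over q(X_T = j | X_t = s). States with
    h_t(s) = 0 have zero probability at time t under p*; their rows are left
    at the baseline kernel to keep every kernel row-stochastic.
    """
    if T is None:
        T = solution.optimal_joint.horizon
    if T < 1:
        raise ValueError(f"horizon T must be >= 1, got {T}")
    P = solution.optimal_joint.joint
    stepT = kernel.power(T)
    if np.any((P > 0) & (stepT == 0)):
        i, j = np.argwhere((P > 0) & (stepT == 0))[0]
        raise InfeasibleMarginalError(
            f"optimal coupling conditions on endpoint pair ({i}, {j}) that has "
            "zero probability under the supplied kernel; kernel and solution "
            "are inconsistent",
            states=(int(i), int(j)),
        )
    pi = solution.optimal_joint.row_marginal()

    # h_t for t = 0..T, by backward recursion; exp(beta) can underflow for
    # extreme multipliers, so recurse in the log domain.
    log_h: list[np.ndarray] = [np.empty(0)] * (T + 1)
    log_h[T] = np.asarray(solution.beta, dtype=float)
    with np.errstate(divide="ignore"):
        log_kernel = np.log(kernel.kernel)
    for t in range(T - 1, -1, -1):
        log_h[t] = logsumexp(log_kernel + log_h[t + 1][None, :], axis=1)

    kernels = []
    for t in range(T):
        with np.errstate(invalid="ignore", over="ignore"):
            log_K = log_kernel + log_h[t + 1][None, :] - log_h[t][:, None]
            K = np.where(np.isneginf(log_kernel), 0.0, np.exp(log_K))
        dead = np.isneginf(log_h[t])
        if np.any(dead):
            K[dead] = kernel.kernel[dead]
        K = K / K.sum(axis=1, keepdims=True)
        kernels.append(K)
    return PathDistribution(initial=pi, kernels=tuple(kernels))


def ot_identity_check(P, Q) -> tuple[float, float, float]:
    """Return (KL, transport term, entropy) of the optimal-transport form.

    With cost matrix C_ij = -log Q_ij the bridge objective splits as
    D_KL(P || Q) = <C, P> - H(P): the first element equals the second minus
    the third to machine precision, which ties the bridge problem to
    entropy-regularized optimal transport.
    """
    p, q = _joint_arrays(P, Q)
    kl = kl_divergence(p, q)
    transport = float(-xlogy(p, q).sum())
    entropy = float(-xlogy(p, p).sum())
    return kl, transport, entropy
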
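"""Validated containers for distributions, kernels and path laws.

The discrete state space is ``{0, .., k-1}`` internally; reports use 1-based
labels. All probability containers validate on construction:

* :class:`ProbabilityVector` — a distribution over the k states.
* :class:`TransitionMatrix` — a row-stochastic one-step kernel.
* :class:`JointEndpointDistribution` — a joint law over (X_0, X_T).
* :class:`PathDistribution` — a (possibly time-inhomogeneous) Markov chain law.
* :class:`BridgeSolution` — the optimally controlled endpoint coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import DimensionError

_ATOL = 1e-12


def _as_float_array(x, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise DimensionError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class ProbabilityVector:
    """A distribution over k >= 2 discrete states.

    Parameters
    ----------
    probs
        Length-k nonnegative vector summing to 1 (within 1e-12).
    labels
        Optional state names; defaults to 1-based numbers at report time.
    """

    probs: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        probs = _as_float_array(self.probs, 1, "probs")
        object.__setattr__(self, "probs", probs)
        if probs.size < 2:
            raise DimensionError(f"need k >= 2 states, got k={probs.size}")
        if np.any(probs < -_ATOL):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum():.12g}, not 1")
        if self.labels is not None and len(self.labels) != probs.size:
            raise DimensionError("labels length must match number of states")

    @property
    def k(self) -> int:
        return self.probs.size

    @classmethod
    def from_counts(cls, counts, labels=None) -> "ProbabilityVector":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize all-zero counts")
        return cls(counts / total, labels)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic k x k kernel: entry (i, j) = P(next = j | current = i)."""

    kernel: np.ndarray

    def __post_init__(self):
        kernel = _as_float_array(self.kernel, 2, "kernel")
        object.__setattr__(self, "kernel", kernel)
        k1, k2 = kernel.shape
        if k1 != k2 or k1 < 2:
            raise DimensionError(f"kernel must be square with k >= 2, got {kernel.shape}")
        if np.any(kernel < -_ATOL):
            raise ValueError("kernel entries must be nonnegative")
        rows = kernel.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(f"row {bad} sums to {rows[bad]:.12g}, not 1")

    @property
    def k(self) -> int:
        return self.kernel.shape[0]

    def power(self, T: int) -> np.ndarray:
        """T-step kernel (T-fold composition)."""
        if T < 1:
            raise ValueError(f"horizon T must be >= 1, got {T}")
        return np.linalg.matrix_power(self.kernel, T)

    def stationary(self) -> ProbabilityVector:
        """Stationary distribution via the leading left eigenvector.

        Raises
        ------
        NonErgodicKernelError
            If the unit eigenvalue is not simple (no unique stationary law).
        """
        from .errors import NonErgodicKernelError

        vals, vecs = np.linalg.eig(self.kernel.T)
        close = np.isclose(vals, 1.0, atol=1e-8)
        if close.sum() != 1:
            raise NonErgodicKernelError(
                f"kernel has {int(close.sum())} unit eigenvalues; stationary "
                "distribution is not unique (use a uniform start instead)"
            )
        v = np.real(vecs[:, int(np.argmax(close))])
        v = np.abs(v)
        return ProbabilityVector(v / v.sum())

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.kernel, dtype=dtype)


@dataclass(frozen=True)
class JointEndpointDistribution:
    """Joint law over the endpoints (X_0 = i, X_T = j) of a horizon-T path."""

    joint: np.ndarray
    horizon: int = 1

    def __post_init__(self):
        joint = _as_float_array(self.joint, 2, "joint")
        object.__setattr__(self, "joint", joint)
        k1, k2 = joint.shape
        if k1 != k2 or k1 < 2:
            raise DimensionError(f"joint must be square with k >= 2, got {joint.shape}")
        if np.any(joint < -_ATOL):
            raise ValueError("joint entries must be nonnegative")
        if abs(joint.sum() - 1.0) > 1e-9:
            raise ValueError(f"joint sums to {joint.sum():.12g}, not 1")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")

    @property
    def k(self) -> int:
        return self.joint.shape[0]

    def row_marginal(self) -> ProbabilityVector:
        """Marginal of X_0 (exact row sums)."""
        return ProbabilityVector(self.joint.sum(axis=1))

    def col_marginal(self) -> ProbabilityVector:
        """Marginal of X_T (exact column sums)."""
        return ProbabilityVector(self.joint.sum(axis=0))

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.joint, dtype=dtype)


@dataclass(frozen=True)
class BridgeSolution:
    """Optimal endpoint coupling P* with its multipliers and KL cost.

    ``P*_ij = exp(alpha_i + beta_j) * Q_ij`` wherever Q_ij > 0 (the
    normalization constant is folded into alpha, fixing the gauge).
    ``cost`` is D_KL(P* || Q) in nats.
    """

    optimal_joint: JointEndpointDistribution
    alpha: np.ndarray
    beta: np.ndarray
    cost: float
    iterations: int
    residual: float
    converged: bool
    tol: float

    def cost_bits(self) -> float:
        """The transition cost converted from nats to bits."""
        return self.cost / float(np.log(2.0))


@dataclass(frozen=True)
class PathDistribution:
    """Law of a (time-inhomogeneous) Markov chain (X_0, ..., X_T).

    ``kernels[t]`` moves the chain from time t to t+1; T = len(kernels).
    """

    initial: ProbabilityVector
    kernels: tuple[np.ndarray, ...]

    def __post_init__(self):
        kernels = tuple(_as_float_array(K, 2, "kernel") for K in self.kernels)
        object.__setattr__(self, "kernels", kernels)
        k = self.initial.k
        for t, K in enumerate(kernels):
            if K.shape != (k, k):
                raise DimensionError(f"kernel at step {t} has shape {K.shape}, expected {(k, k)}")
            rows = K.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > 1e-9) or np.any(K < -_ATOL):
                raise ValueError(f"kernel at step {t} is not row-stochastic")

    @property
    def horizon(self) -> int:
        return len(self.kernels)

    @property
    def k(self) -> int:
        return self.initial.k

    def marginal(self, t: int) -> ProbabilityVector:
        """Marginal law of X_t, by forward propagation."""
        if not 0 <= t <= self.horizon:
            raise ValueError(f"t must be in [0, {self.horizon}]")
        p = self.initial.probs.copy()
        for K in self.kernels[:t]:
            p = p @ K
        return ProbabilityVector(p)

    def path_probability(self, path: Sequence[int]) -> float:
        """Probability of one full trajectory (x_0, ..., x_T)."""
        if len(path) != self.horizon + 1:
            raise DimensionError(
                f"path length {len(path)} does not match horizon {self.horizon}"
            )
        p = self.initial.probs[path[0]]
        for t in range(self.horizon):
            p *= self.kernels[t][path[t], path[t + 1]]
        return float(p)

    def enumerate_paths(self) -> Iterator[tuple[tuple[int, ...], float]]:
        """Yield every trajectory with its probability (exponential in T)."""
        import itertools

        for path in itertools.product(range(self.k), repeat=self.horizon + 1):
            yield path, self.path_probability(path)


@dataclass(frozen=True)
class TransitionList:
    """Within-subject consecutive-frame transition pairs for one condition.

    ``subjects[m]`` is the subject contributing pair (``sources[m]`` ->
    ``targets[m]``); pairs never span a subject boundary.
    """

    subjects: np.ndarray
    sources: np.ndarray
    targets: np.ndarray
    k: int

    def __post_init__(self):
        subjects = np.asarray(self.subjects)
        sources = np.asarray(self.sources, dtype=np.int64)
        targets = np.asarray(self.targets, dtype=np.int64)
        if not (subjects.shape == sources.shape == targets.shape) or sources.ndim != 1:
            raise DimensionError("subjects/sources/targets must be equal-length 1-D arrays")
        for name, arr in (("sources", sources), ("targets", targets)):
            if arr.size and (arr.min() < 0 or arr.max() >= self.k):
                raise ValueError(f"{name} contain states outside [0, {self.k - 1}]")
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "sources", sources)
        object.__setattr__(self, "targets", targets)

    def __len__(self) -> int:
        return self.sources.size


@dataclass(frozen=True)
class StateSequenceRecord:
    subject: str
    condition: str
    states: np.ndarray

    def __post_init__(self):
        states = np.asarray(self.states, dtype=np.int64)
        if states.ndim != 1:
            raise DimensionError("state sequence must be 1-D")
        if not self.subject or not self.condition:
            raise ValueError("subject and condition labels must be nonempty")
        object.__setattr__(self, "states", states)


@dataclass(frozen=True)
class StateSequenceSet:
    """Coarse-grained state sequences for many subject x condition sessions."""

    sequences: tuple[StateSequenceRecord, ...]
    k: int
    frame_period: float | None = None

    def __post_init__(self):
        seqs = tuple(self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if self.k < 2:
            raise DimensionError(f"need k >= 2 states, got k={self.k}")
        for rec in seqs:
            if rec.states.size and (rec.states.min() < 0 or rec.states.max() >= self.k):
                raise ValueError(
                    f"sequence for subject={rec.subject!r} condition={rec.condition!r} "
                    f"contains states outside [0, {self.k - 1}]"
                )

    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.sequences:
            seen.setdefault(rec.condition, None)
        return tuple(seen)

    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.sequences:
            seen.setdefault(rec.subject, None)
        return tuple(seen)

    def select(self, condition: str) -> tuple[StateSequenceRecord, ...]:
        recs = tuple(r for r in self.sequences if r.condition == condition)
        if not recs:
            raise KeyError(f"no sequences for condition {condition!r}")
        return recs

    def frames(self, condition: str) -> np.ndarray:
        """All frames of one condition, concatenated across subjects."""
        recs = self.select(condition)
        return np.concatenate([r.states for r in recs]) if recs else np.empty(0, np.int64)


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Per-replicate bootstrap estimates of one scalar or array quantity.

    ``values`` has the replicate axis first. ``statuses`` records, per
    replicate, ``"ok"`` or a named failure (e.g. ``"infeasible"``) — failed
    replicates hold NaN and are excluded from ``mean``/``sd``.
    """

    values: np.ndarray
    statuses: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape[0] != len(self.statuses):
            raise DimensionError("one status per replicate required")
        if values.shape[0] < 2:
            raise ValueError("need at least 2 replicates for ensemble summaries")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def ok(self) -> np.ndarray:
        return np.array([s == "ok" for s in self.statuses])

    @property
    def n_failed(self) -> int:
        return int((~self.ok).sum())

    def mean(self) -> np.ndarray | float:
        m = self.values[self.ok].mean(axis=0)
        return float(m) if np.ndim(m) == 0 else m

    def sd(self) -> np.ndarray | float:
        s = self.values[self.ok].std(axis=0, ddof=1)
        return float(s) if np.ndim(s) == 0 else s


@dataclass(frozen=True)
class ClusterModel:
    """Fitted cosine (spherical) k-means model.

    ``centroids`` are unit-norm directions (k x M); ``assignments`` map the
    training frames to their maximum-cosine centroid; ``explained_variance``
    is 1 - within/total dispersion under squared chordal distance.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    explained_variance: float
    inertia: float
    k: int
    seed: int | None = None
    n_iter: int = 0

    def __post_init__(self):
        c = _as_float_array(self.centroids, 2, "centroids")
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "assignments", np.asarray(self.assignments, dtype=np.int64))
        norms = np.linalg.norm(c, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("centroids must be unit-norm")
        if not 0.0 <= self.explained_variance <= 1.0 + 1e-12:
            raise ValueError("explained_variance must lie in [0, 1]")


@dataclass(frozen=True)
class ActivityMatrix:
    """Multivariate activity: channels x frames, with per-frame labels."""

    values: np.ndarray
    subjects: np.ndarray
    conditions: np.ndarray

    def __post_init__(self):
        values = _as_float_array(self.values, 2, "values")
        subjects = np.asarray(self.subjects)
        conditions = np.asarray(self.conditions)
        if values.shape[0] < 2:
            raise DimensionError("need at least 2 channels")
        n = values.shape[1]
        if subjects.shape != (n,) or conditions.shape != (n,):
            raise DimensionError("need one subject and condition label per frame")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "conditions", conditions)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def default_labels(k: int) -> tuple[str, ...]:
    """1-based state labels used in reports."""
    return tuple(str(i + 1) for i in range(k))
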
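"""Ground-truth-known synthetic data for the full pipeline.

Emulates the shape of a multi-subject brain-state study, scaled to desk size:

* a baseline ("rest") condition generated as a first-order Markov chain with
  a known k x k kernel, one sequence per subject, started at stationarity;
* task conditions drawn i.i.d. from per-condition target distributions
  ("tilts") — only their marginals enter any downstream computation, so no
  temporal structure is planted in them;
* activity matrices with one well-separated unit direction per state plus
  isotropic noise, so cosine k-means can recover the states.

:func:`make_planted_hierarchy` builds a rest/easy/hard scenario whose true
bridge costs from rest are strictly ordered and whose easy<->hard costs are
asymmetric, with the exact truth shipped alongside for end-to-end checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bridge import transition_cost
from .errors import DimensionError, NonErgodicKernelError, StateBridgeError
from .types import (
    ActivityMatrix,
    ProbabilityVector,
    StateSequenceRecord,
    StateSequenceSet,
    TransitionMatrix,
)

__all__ = [
    "SyntheticSpec",
    "simulate_state_sequences",
    "simulate_activity",
    "make_planted_hierarchy",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for one synthetic study.

    ``condition_tilts`` maps each task condition to its target distribution;
    the baseline condition follows ``baseline_kernel`` instead. ``true_costs``
    (when set by :func:`make_planted_hierarchy`) holds the exact bridge costs
    between the true condition distributions under the true kernel.
    """

    k: int
    baseline_kernel: TransitionMatrix
    condition_tilts: dict[str, ProbabilityVector]
    n_subjects: int = 40
    frames_per_condition: int = 180
    channel_dim: int = 25
    cluster_concentration: float = 6.0
    baseline_label: str = "rest"
    seed: int = 0
    true_costs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.k != self.baseline_kernel.k:
            raise DimensionError("k does not match baseline kernel size")
        for label, tilt in self.condition_tilts.items():
            if tilt.k != self.k:
                raise DimensionError(f"tilt for {label!r} has k={tilt.k}, expected {self.k}")
        if self.baseline_label in self.condition_tilts:
            raise StateBridgeError("baseline condition must not appear among tilts")
        if self.channel_dim < self.k:
            raise DimensionError(
                f"channel_dim={self.channel_dim} < k={self.k}: cannot place k "
                "well-separated directions"
            )
        if self.n_subjects < 1 or self.frames_per_condition < 2:
            raise ValueError("need n_subjects >= 1 and frames_per_condition >= 2")
        if self.cluster_concentration <= 0:
            raise ValueError("cluster_concentration must be positive")

    def conditions(self) -> tuple[str, ...]:
        return (self.baseline_label, *self.condition_tilts)

    def true_distributions(self) -> dict[str, ProbabilityVector]:
        """Exact per-condition state distributions (rest at stationarity)."""
        out = {self.baseline_label: self.baseline_kernel.stationary()}
        out.update(self.condition_tilts)
        return out


def _sample_chain(
    kernel: np.ndarray, start: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    k = kernel.shape[0]
    cum = np.cumsum(kernel, axis=1)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(k, p=start)
    u = rng.random(n - 1)
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    return np.minimum(states, k - 1)


def simulate_state_sequences(spec: SyntheticSpec, start: str = "stationary") -> StateSequenceSet:
    """Per subject x condition state sequences; seeded and reproducible.

    The baseline condition runs the Markov kernel from its stationary law
    (``start="uniform"`` falls back to a uniform initial state, for kernels
    without a unique stationary distribution); task conditions draw frames
    i.i.d. from their tilt distributions.
    """
    master = np.random.SeedSequence(spec.seed)
    if start == "stationary":
        try:
            init = spec.baseline_kernel.stationary().probs
        except NonErgodicKernelError as err:
            raise NonErgodicKernelError(
                f"{err} — pass start='uniform' to simulate from a uniform initial state"
            ) from err
    elif start == "uniform":
        init = np.full(spec.k, 1.0 / spec.k)
    else:
        raise ValueError(f"unknown start {start!r}")
    records = []
    subj_streams = master.spawn(spec.n_subjects)
    for s, subj_seed in enumerate(subj_streams):
        subject = f"sub{s + 1:03d}"
        cond_streams = subj_seed.spawn(1 + len(spec.condition_tilts))
        rng = np.random.default_rng(cond_streams[0])
        rest = _sample_chain(
            spec.baseline_kernel.kernel, init, spec.frames_per_condition, rng
        )
        records.append(StateSequenceRecord(subject, spec.baseline_label, rest))
        for (label, tilt), cs in zip(spec.condition_tilts.items(), cond_streams[1:]):
            rng = np.random.default_rng(cs)
            frames = rng.choice(spec.k, size=spec.frames_per_condition, p=tilt.probs)
            records.append(StateSequenceRecord(subject, label, frames))
    return StateSequenceSet(sequences=tuple(records), k=spec.k)


def planted_directions(k: int, M: int, rng: np.random.Generator) -> np.ndarray:
    """k mutually orthogonal unit directions in M dimensions (requires M >= k)."""
    if M < k:
        raise DimensionError(f"cannot place {k} well-separated directions in dimension {M}")
    G = rng.standard_normal((M, k))
    Qmat, _ = np.linalg.qr(G)
    return Qmat.T[:k]


def simulate_activity(
    states: StateSequenceSet,
    M: int = 25,
    concentration: float = 6.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[ActivityMatrix, np.ndarray]:
    """Noisy directional activity for every frame of every sequence.

    Each state gets an orthogonal unit centroid direction; each frame is its
    state's centroid plus isotropic Gaussian noise with per-channel standard
    deviation 1/concentration. Returns the activity matrix (channels x
    frames, labels carried through in sequence order) and the true per-frame
    state vector, for recovery scoring.
    """
    if M < 2:
        raise DimensionError("need at least 2 channels")
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)
    centroids = planted_directions(states.k, M, rng)
    cols, subjects, conditions, truth = [], [], [], []
    for rec in states.sequences:
        n = rec.states.size
        noise = rng.standard_normal((n, M)) / concentration
        cols.append(centroids[rec.states] + noise)
        subjects.extend([rec.subject] * n)
        conditions.extend([rec.condition] * n)
        truth.append(rec.states)
    values = np.vstack(cols).T
    return (
        ActivityMatrix(
            values=values, subjects=np.array(subjects), conditions=np.array(conditions)
        ),
        np.concatenate(truth),
    )


def _random_ergodic_kernel(k: int, rng: np.random.Generator, persistence: float = 0.45) -> TransitionMatrix:
    """A well-mixed kernel with diagonal persistence, as resting dynamics."""
    rows = rng.dirichlet(np.full(k, 2.0), size=k)
    kernel = persistence * np.eye(k) + (1.0 - persistence) * rows
    return TransitionMatrix(kernel / kernel.sum(axis=1, keepdims=True))


def _tilt(base: np.ndarray, target: np.ndarray, weight: float) -> ProbabilityVector:
    return ProbabilityVector((1.0 - weight) * base + weight * target)


def make_planted_hierarchy(
    k: int = 8,
    seed: int = 0,
    n_subjects: int = 40,
    frames_per_condition: int = 180,
    channel_dim: int = 25,
    cluster_concentration: float = 6.0,
    easy_weight: float = 0.25,
    hard_weight: float = 0.60,
) -> SyntheticSpec:
    """Rest / easy / hard scenario with strictly ordered true bridge costs.

    The easy and hard conditions tilt the stationary law toward the same
    low-probability corner of the state space, the hard condition more
    strongly, so that (computed exactly with the bridge solver on the true
    kernel) cost(rest->hard) > cost(rest->easy) > 0 and the easy<->hard
    transition is asymmetric in the expected direction. Candidate kernels are
    drawn from deterministic child streams of ``seed`` until every strict
    inequality and the full ordering-consistency relation hold, so the
    returned spec is reproducible and self-certified; the true costs ship in
    ``spec.true_costs``.
    """
    master = np.random.SeedSequence(seed)
    for attempt_seed in master.spawn(64):
        rng = np.random.default_rng(attempt_seed)
        kernel = _random_ergodic_kernel(k, rng)
        pi = kernel.stationary()
        # tilt toward a concentrated target on the rarest states
        target = np.zeros(k)
        rare = np.argsort(pi.probs)[: max(2, k // 4)]
        target[rare] = 1.0 / rare.size
        tilts = {
            "easy": _tilt(pi.probs, target, easy_weight),
            "hard": _tilt(pi.probs, target, hard_weight),
        }
        dists = {"rest": pi, **tilts}
        labels = ("rest", "easy", "hard")
        costs = {
            (a, b): transition_cost(dists[a], dists[b], kernel)
            for a in labels
            for b in labels
            if a != b
        }
        ordered = costs[("rest", "hard")] > costs[("rest", "easy")] > 1e-4
        asymmetric = costs[("easy", "hard")] > costs[("hard", "easy")] + 1e-4
        consistent = _ordering_holds(costs, labels)
        if ordered and asymmetric and consistent:
            return SyntheticSpec(
                k=k,
                baseline_kernel=kernel,
                condition_tilts=tilts,
                n_subjects=n_subjects,
                frames_per_condition=frames_per_condition,
                channel_dim=channel_dim,
                cluster_concentration=cluster_concentration,
                seed=seed,
                true_costs=costs,
            )
    raise StateBridgeError(
        "could not construct a planted hierarchy; try another seed"
    )  # pragma: no cover - construction succeeds for generic seeds


def _ordering_holds(costs: dict[tuple[str, str], float], labels: tuple[str, ...]) -> bool:
    tasks = [c for c in labels if c != "rest"]
    for i, a in enumerate(tasks):
        for b in tasks[i + 1 :]:
            ra, rb = costs[("rest", a)], costs[("rest", b)]
            if ra == rb:
                continue
            hard, easy = (a, b) if ra > rb else (b, a)
            if not costs[(easy, hard)] > costs[(hard, easy)]:
                return False
    return True
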
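"""Empirical distributions, baseline kernels, and trajectory bootstrap.

The study design: the resting condition alone supplies the baseline dynamics
(a one-step joint / transition matrix estimated from consecutive-frame pairs),
while every condition, rest included, supplies a marginal state distribution.
Uncertainty is propagated by trajectory bootstrapping — resampling transition
pairs (within subject only, never across a subject boundary) and single frames
with replacement, re-estimating everything per replicate, and summarizing over
replicates (the reference protocol uses 100).
"""

from __future__ import annotations

import numpy as np

from .bridge import transition_cost
from .errors import StateBridgeError, UnobservedStateError
from .types import (
    BootstrapEnsemble,
    JointEndpointDistribution,
    ProbabilityVector,
    StateSequenceSet,
    TransitionList,
    TransitionMatrix,
)

__all__ = [
    "empirical_distribution",
    "build_transition_list",
    "bootstrap_joint",
    "to_transition_matrix",
    "bootstrap_distribution",
    "bootstrap_costs",
    "bootstrap_cost_table",
]


def empirical_distribution(seqs: StateSequenceSet, condition: str) -> ProbabilityVector:
    """State occupancy frequencies over all frames of one condition."""
    frames = seqs.frames(condition)
    if frames.size == 0:
        raise StateBridgeError(f"condition {condition!r} has no frames")
    counts = np.bincount(frames, minlength=seqs.k)
    return ProbabilityVector.from_counts(counts)


def build_transition_list(seqs: StateSequenceSet, condition: str) -> TransitionList:
    """Consecutive-frame transition pairs, pooled over subjects.

    Each subject sequence of length n contributes exactly n - 1 pairs in
    temporal order; pairs spanning two subjects are excluded by construction.
    """
    subjects, sources, targets = [], [], []
    for rec in seqs.select(condition):
        n = rec.states.size
        if n < 2:
            continue
        subjects.append(np.repeat(rec.subject, n - 1))
        sources.append(rec.states[:-1])
        targets.append(rec.states[1:])
    if subjects:
        return TransitionList(
            subjects=np.concatenate(subjects),
            sources=np.concatenate(sources),
            targets=np.concatenate(targets),
            k=seqs.k,
        )
    return TransitionList(
        subjects=np.empty(0, dtype=object),
        sources=np.empty(0, dtype=np.int64),
        targets=np.empty(0, dtype=np.int64),
        k=seqs.k,
    )


def bootstrap_joint(
    tlist: TransitionList, n_draws: int | None = None, rng: np.random.Generator | None = None
) -> JointEndpointDistribution:
    """One bootstrap replicate of the one-step endpoint joint.

    Draws ``n_draws`` pairs uniformly with replacement from the transition
    list, counts them into a k x k matrix and normalizes by the draw count.
    Defaults to ``n_draws = len(tlist)``, the number of available pairs.
    """
    if len(tlist) == 0:
        raise StateBridgeError("transition list is empty")
    if n_draws is None:
        n_draws = len(tlist)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(tlist), size=n_draws)
    flat = np.bincount(tlist.sources[idx] * tlist.k + tlist.targets[idx], minlength=tlist.k**2)
    return JointEndpointDistribution(flat.reshape(tlist.k, tlist.k) / n_draws, horizon=1)


def to_transition_matrix(joint: JointEndpointDistribution) -> TransitionMatrix:
    """Row-normalize an endpoint joint into a transition matrix."""
    rows = joint.joint.sum(axis=1)
    empty = np.flatnonzero(rows == 0)
    if empty.size:
        raise UnobservedStateError(
            f"state(s) {empty.tolist()} (0-based) never occur as a transition "
            "source; reduce the number of states k or apply smoothing"
        )
    return TransitionMatrix(joint.joint / rows[:, None])


def bootstrap_distribution(
    seqs: StateSequenceSet,
    condition: str,
    n_draws: int | None = None,
    rng: np.random.Generator | None = None,
) -> ProbabilityVector:
    """One bootstrap replicate of a condition's state distribution.

    Resamples single frames uniformly with replacement; defaults to the
    number of available frames.
    """
    frames = seqs.frames(condition)
    if frames.size == 0:
        raise StateBridgeError(f"condition {condition!r} has no frames")
    if n_draws is None:
        n_draws = frames.size
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng)
    draws = frames[rng.integers(0, frames.size, size=n_draws)]
    counts = np.bincount(draws, minlength=seqs.k)
    return ProbabilityVector(counts / n_draws)


def _replicate_streams(seed_seq: np.random.SeedSequence, n: int) -> list[np.random.SeedSequence]:
    return seed_seq.spawn(n)


def bootstrap_costs(
    seqs: StateSequenceSet,
    baseline: str,
    cond_a: str,
    cond_b: str,
    T: int = 1,
    n_replicates: int = 100,
    rng=None,
    n_draws_pairs: int | None = None,
    n_draws_frames: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> BootstrapEnsemble:
    """Bootstrap ensemble of the transition cost cond_a -> cond_b.

    Per replicate: resample the baseline one-step joint (for the kernel) and
    both condition distributions, each from an independent child stream of the
    replicate's seed, then solve the bridge under the resampled kernel. A
    replicate whose resampled marginals are infeasible under its resampled
    kernel is recorded with status ``"infeasible"`` (value NaN), never
    silently dropped.
    """
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    tlist = build_transition_list(seqs, baseline)
    seed_seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    values = np.full(n_replicates, np.nan)
    statuses: list[str] = []
    for r, child in enumerate(_replicate_streams(seed_seq, n_replicates)):
        s_kernel, s_a, s_b = (np.random.default_rng(c) for c in child.spawn(3))
        try:
            kernel = to_transition_matrix(bootstrap_joint(tlist, n_draws_pairs, s_kernel))
            dist_a = bootstrap_distribution(seqs, cond_a, n_draws_frames, s_a)
            dist_b = bootstrap_distribution(seqs, cond_b, n_draws_frames, s_b)
            values[r] = transition_cost(dist_a, dist_b, kernel, T, tol=tol, max_iter=max_iter)
            statuses.append("ok")
        except StateBridgeError:
            statuses.append("infeasible")
    return BootstrapEnsemble(values=values, statuses=tuple(statuses), seed=_entropy_int(seed_seq))


def bootstrap_cost_table(
    seqs: StateSequenceSet,
    baseline: str,
    conditions: list[str] | tuple[str, ...] | None = None,
    T: int = 1,
    n_replicates: int = 100,
    rng=None,
    n_draws_pairs: int | None = None,
    n_draws_frames: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> dict[tuple[str, str], BootstrapEnsemble]:
    """Bootstrap costs for every ordered condition pair, sharing replicates.

    Within one replicate the kernel and each condition's distribution are
    resampled once and reused across all pairs, so that per-replicate cost
    tables are internally consistent. Returns one ensemble per ordered pair
    (a, b) with a != b.
    """
    if conditions is None:
        conditions = seqs.conditions()
    conditions = tuple(conditions)
    if baseline not in conditions:
        raise StateBridgeError(f"baseline condition {baseline!r} not among {conditions}")
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    tlist = build_transition_list(seqs, baseline)
    seed_seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    pairs = [(a, b) for a in conditions for b in conditions if a != b]
    values = {p: np.full(n_replicates, np.nan) for p in pairs}
    statuses: dict[tuple[str, str], list[str]] = {p: [] for p in pairs}
    for r, child in enumerate(_replicate_streams(seed_seq, n_replicates)):
        streams = child.spawn(1 + len(conditions))
        s_kernel = np.random.default_rng(streams[0])
        dists: dict[str, ProbabilityVector | None] = {}
        try:
            kernel = to_transition_matrix(bootstrap_joint(tlist, n_draws_pairs, s_kernel))
        except StateBridgeError:
            kernel = None
        for cond, s in zip(conditions, streams[1:]):
            dists[cond] = bootstrap_distribution(seqs, cond, n_draws_frames, s)
        for a, b in pairs:
            if kernel is None:
                statuses[(a, b)].append("infeasible")
                continue
            try:
                values[(a, b)][r] = transition_cost(
                    dists[a], dists[b], kernel, T, tol=tol, max_iter=max_iter
                )
                statuses[(a, b)].append("ok")
            except StateBridgeError:
                statuses[(a, b)].append("infeasible")
    seed = _entropy_int(seed_seq)
    return {
        p: BootstrapEnsemble(values=values[p], statuses=tuple(statuses[p]), seed=seed)
        for p in pairs
    }


def _entropy_int(seed_seq: np.random.SeedSequence) -> int | None:
    ent = seed_seq.entropy
    return int(ent) if isinstance(ent, (int, np.integer)) else None
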
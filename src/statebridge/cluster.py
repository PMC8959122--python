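"""Coarse-graining of multivariate activity into discrete states.

Whole-record activity patterns (one column vector per time frame) are grouped
into k states by cosine-similarity k-means: frames and centroids live on the
unit sphere and a frame belongs to the centroid with the largest dot product.
Equivalently this minimizes the squared chordal distance ||x - c||^2 =
2 - 2 cos(x, c) after normalization, so the usual Lloyd-style alternation
applies with the centroid update "normalize the member mean".

Two diagnostics guide the choice of k: the explained-variance curve
(1 - within/total dispersion, which saturates near the true number of
directional clusters) and the occupancy check (whether every state appears
in every subject x condition session — too many states leaves some sessions
without them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, StateBridgeError
from .types import ActivityMatrix, ClusterModel, StateSequenceRecord, StateSequenceSet

__all__ = [
    "fit_cosine_kmeans",
    "assign_states",
    "explained_variance_curve",
    "occupancy_check",
    "balance_frames",
    "states_from_assignments",
    "OccupancyReport",
]


def _unit_frames(values: np.ndarray) -> np.ndarray:
    """Columns (frames) scaled to unit norm; transposed to frames x channels."""
    X = np.asarray(values, dtype=float).T
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise StateBridgeError(
            f"frame {bad} is all-zero; cosine geometry is undefined for it"
        )
    return X / norms[:, None]


def _normalize_rows(C: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(C, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return C / norms


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding with squared chordal distance on the sphere."""
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    # squared chordal distance 2 - 2 cos to the nearest chosen centroid
    d2 = 2.0 - 2.0 * (X @ centroids[0])
    for c in range(1, k):
        d2 = np.maximum(d2, 0.0)
        total = d2.sum()
        if total <= 0:  # all frames already coincide with a centroid
            centroids[c] = X[rng.integers(n)]
        else:
            centroids[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, 2.0 - 2.0 * (X @ centroids[c]))
    return centroids


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    """Spherical Lloyd: (centroids, assignments, inertia, n_iter, objective trace).

    Inertia is the total squared chordal dispersion sum_n ||x_n - c_{a(n)}||^2
    = 2 * sum_n (1 - cos); it is nonincreasing across iterations. An emptied
    cluster is reseeded at the frame farthest (lowest cosine) from its current
    centroid.
    """
    k = centroids.shape[0]
    n = X.shape[0]
    assign = np.full(n, -1, dtype=np.int64)
    n_iter = 0
    objective: list[float] = []
    for n_iter in range(1, max_iter + 1):
        sims = X @ centroids.T
        new_assign = np.argmax(sims, axis=1)  # argmax takes lowest index on ties
        objective.append(float(2.0 * (1.0 - sims[np.arange(n), new_assign]).sum()))
        for c in range(k):
            members = new_assign == c
            if not np.any(members):
                worst = int(np.argmin(sims[np.arange(n), new_assign]))
                centroids[c] = X[worst]
                new_assign[worst] = c
                members = new_assign == c
            centroids[c] = X[members].sum(axis=0)
        centroids = _normalize_rows(centroids)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    # final assignment against the final centroids, so the model invariant
    # (every frame at its maximum-cosine centroid) holds exactly
    sims = X @ centroids.T
    assign = np.argmax(sims, axis=1)
    inertia = float(2.0 * (1.0 - sims[np.arange(n), assign]).sum())
    return centroids, assign, inertia, n_iter, objective


def _total_dispersion(X: np.ndarray) -> float:
    """Dispersion about the (normalized) mean direction: the k = 1 inertia."""
    mean = X.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:  # perfectly balanced antipodal data: any direction ties
        mean = np.zeros_like(mean)
        mean[0] = 1.0
    else:
        mean = mean / norm
    return float(2.0 * (1.0 - X @ mean).sum())


def fit_cosine_kmeans(
    data: ActivityMatrix | np.ndarray,
    k: int,
    n_restarts: int = 10,
    rng=None,
    max_iter: int = 300,
) -> ClusterModel:
    """Fit spherical k-means, keeping the best of ``n_restarts`` by inertia.

    Deterministic given the seed: restarts consume child streams of one
    generator in a fixed order.
    """
    values = data.values if isinstance(data, ActivityMatrix) else np.asarray(data)
    X = _unit_frames(values)
    n = X.shape[0]
    if k < 1 or k > n:
        raise DimensionError(f"k must be in [1, n_frames={n}], got {k}")
    seed_seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    best: tuple | None = None
    for child in seed_seq.spawn(n_restarts):
        g = np.random.default_rng(child)
        centroids = _plusplus_init(X, k, g)
        result = _lloyd(X, centroids, max_iter, g)
        if best is None or result[2] < best[2]:
            best = result
    centroids, assign, inertia, n_iter, _ = best
    total = _total_dispersion(X)
    ev = 0.0 if k == 1 else (1.0 - inertia / total if total > 0 else 1.0)
    ev = float(min(max(ev, 0.0), 1.0))
    seed = seed_seq.entropy
    return ClusterModel(
        centroids=centroids,
        assignments=assign,
        explained_variance=ev,
        inertia=inertia,
        k=k,
        seed=int(seed) if isinstance(seed, int) else None,
        n_iter=n_iter,
    )


def assign_states(model: ClusterModel, data: ActivityMatrix | np.ndarray) -> np.ndarray:
    """Map frames to their maximum-cosine centroid (ties -> lowest index)."""
    values = data.values if isinstance(data, ActivityMatrix) else np.asarray(data)
    X = _unit_frames(values)
    if X.shape[1] != model.centroids.shape[1]:
        raise DimensionError(
            f"data has {X.shape[1]} channels but model expects {model.centroids.shape[1]}"
        )
    return np.argmax(X @ model.centroids.T, axis=1)


def explained_variance_curve(
    data: ActivityMatrix | np.ndarray,
    k_min: int = 2,
    k_max: int = 12,
    rng=None,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> list[tuple[int, float]]:
    """Explained variance versus cluster count, for choosing k.

    The curve is nondecreasing in k up to restart noise and plateaus once k
    reaches the number of genuine directional clusters.
    """
    values = data.values if isinstance(data, ActivityMatrix) else np.asarray(data)
    if k_max > values.shape[1]:
        raise DimensionError(f"k_max={k_max} exceeds number of frames {values.shape[1]}")
    seed_seq = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(rng)
    out = []
    for k, child in zip(range(k_min, k_max + 1), seed_seq.spawn(k_max - k_min + 1)):
        model = fit_cosine_kmeans(values, k, n_restarts=n_restarts, rng=child, max_iter=max_iter)
        out.append((k, model.explained_variance))
    return out


@dataclass(frozen=True)
class OccupancyReport:
    """Per-session missing-state table and an overall pass flag."""

    table: pd.DataFrame  # columns: subject, condition, missing_states (tuple)
    passed: bool


def occupancy_check(
    assignments: np.ndarray, subjects: np.ndarray, conditions: np.ndarray, k: int
) -> OccupancyReport:
    """List, per subject x condition session, the states that never occur.

    The overall flag passes only when every state appears in every session —
    the criterion used to cap the number of clusters.
    """
    assignments = np.asarray(assignments)
    subjects = np.asarray(subjects)
    conditions = np.asarray(conditions)
    if not (assignments.shape == subjects.shape == conditions.shape):
        raise DimensionError("assignments, subjects and conditions must align")
    rows = []
    df = pd.DataFrame({"subject": subjects, "condition": conditions, "state": assignments})
    for (subj, cond), grp in df.groupby(["subject", "condition"], sort=True):
        present = np.bincount(grp["state"].to_numpy(), minlength=k) > 0
        missing = tuple(int(s) for s in np.flatnonzero(~present))
        rows.append({"subject": subj, "condition": cond, "missing_states": missing})
    table = pd.DataFrame(rows, columns=["subject", "condition", "missing_states"])
    passed = bool(all(len(m) == 0 for m in table["missing_states"]))
    return OccupancyReport(table=table, passed=passed)


def balance_frames(counts: dict[str, int]) -> dict[str, int]:
    """Equalize per-condition frame counts by truncation to the minimum.

    Returns, per condition, how many of its FIRST frames to keep so that no
    condition's length biases the clustering.
    """
    if not counts:
        raise StateBridgeError("no conditions given")
    if any(c <= 0 for c in counts.values()):
        bad = [lab for lab, c in counts.items() if c <= 0]
        raise StateBridgeError(f"condition(s) {bad} have no frames")
    m = min(counts.values())
    return {label: m for label in counts}


def states_from_assignments(data: ActivityMatrix, assignments: np.ndarray, k: int) -> StateSequenceSet:
    """Package per-frame assignments into per-session state sequences.

    Frames are grouped by (subject, condition) in order of first appearance,
    preserving their temporal order within each session.
    """
    assignments = np.asarray(assignments, dtype=np.int64)
    if assignments.shape != (data.n_frames,):
        raise DimensionError("one assignment per frame required")
    records = []
    seen: dict[tuple[str, str], list[int]] = {}
    for idx in range(data.n_frames):
        key = (str(data.subjects[idx]), str(data.conditions[idx]))
        seen.setdefault(key, []).append(idx)
    for (subj, cond), idxs in seen.items():
        records.append(StateSequenceRecord(subj, cond, assignments[np.asarray(idxs)]))
    return StateSequenceSet(sequences=tuple(records), k=k)
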
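"""Delimited-text and JSON I/O, plus run configuration.

Conventions: matrices and sequences travel as CSV/TSV, models, solutions and
reports as JSON. State files have one row per frame with columns
(subject, condition, frame_index, state); malformed rows are rejected with
their line number. Result JSON carries provenance (seed, config hash,
package version) so any result file can be regenerated from itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MalformedFileError, StateBridgeError
from .types import (
    ActivityMatrix,
    BootstrapEnsemble,
    BridgeSolution,
    JointEndpointDistribution,
    ProbabilityVector,
    StateSequenceRecord,
    StateSequenceSet,
    TransitionMatrix,
    default_labels,
)

__all__ = [
    "RunConfig",
    "load_config",
    "read_probability_vector",
    "read_transition_matrix",
    "read_joint",
    "read_activity",
    "write_activity",
    "read_states",
    "write_states",
    "write_bridge_solution",
    "write_ensemble",
    "write_cost_table",
    "write_json",
]

_STATE_COLUMNS = ("subject", "condition", "frame_index", "state")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide parameter home, loadable from YAML or JSON."""

    k: int = 8
    T: int = 1
    n_replicates: int = 100
    n_draws: int | None = None
    tol: float = 1e-10
    max_iter: int = 100_000
    baseline: str = "rest"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    if not isinstance(data, dict):
        raise MalformedFileError(f"config {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise MalformedFileError(f"config {path} has unknown keys: {sorted(unknown)}")
    return RunConfig(**data)


def _read_grid(path: str | Path) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Numeric CSV/TSV grid with an optional header row of state labels."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    try:
        first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    except Exception as err:
        raise MalformedFileError(f"cannot parse {path}: {err}") from err
    has_header = first.iloc[0].apply(lambda v: isinstance(v, str)).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    labels = tuple(str(c) for c in df.columns) if has_header else None
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        raise MalformedFileError(f"non-numeric entry in {path}: {err}") from err
    return values, labels


def read_probability_vector(path: str | Path) -> ProbabilityVector:
    """One-row delimited file of k probabilities (optional label header)."""
    values, labels = _read_grid(path)
    if values.shape[0] != 1:
        raise MalformedFileError(f"{path} must contain exactly one row, got {values.shape[0]}")
    return ProbabilityVector(values[0], labels)


def read_transition_matrix(path: str | Path) -> TransitionMatrix:
    values, _ = _read_grid(path)
    return TransitionMatrix(values)


def read_joint(path: str | Path, horizon: int = 1) -> JointEndpointDistribution:
    values, _ = _read_grid(path)
    return JointEndpointDistribution(values, horizon=horizon)


def read_activity(values_path: str | Path, manifest_path: str | Path) -> ActivityMatrix:
    """Channels x frames grid plus a JSON manifest of frame blocks.

    The manifest is a list of {subject, condition, start, n_frames} entries
    covering all columns exactly once.
    """
    values, _ = _read_grid(values_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    n = values.shape[1]
    subjects = np.empty(n, dtype=object)
    conditions = np.empty(n, dtype=object)
    covered = np.zeros(n, dtype=bool)
    for entry in manifest:
        start, count = int(entry["start"]), int(entry["n_frames"])
        if start < 0 or start + count > n:
            raise MalformedFileError(
                f"manifest block {entry} exceeds {n} frames in {values_path}"
            )
        subjects[start : start + count] = str(entry["subject"])
        conditions[start : start + count] = str(entry["condition"])
        covered[start : start + count] = True
    if not covered.all():
        raise MalformedFileError("manifest does not cover every frame")
    return ActivityMatrix(
        values=values, subjects=subjects.astype(str), conditions=conditions.astype(str)
    )


def write_activity(data: ActivityMatrix, values_path: str | Path, manifest_path: str | Path) -> None:
    pd.DataFrame(data.values).to_csv(values_path, index=False, header=False)
    manifest = []
    start = 0
    for idx in range(data.n_frames):
        last = idx == data.n_frames - 1
        boundary = last or (
            data.subjects[idx + 1] != data.subjects[idx]
            or data.conditions[idx + 1] != data.conditions[idx]
        )
        if boundary:
            manifest.append(
                {
                    "subject": str(data.subjects[start]),
                    "condition": str(data.conditions[start]),
                    "start": start,
                    "n_frames": idx - start + 1,
                }
            )
            start = idx + 1
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def write_states(seqs: StateSequenceSet, path: str | Path) -> None:
    rows = []
    for rec in seqs.sequences:
        for t, s in enumerate(rec.states):
            rows.append((rec.subject, rec.condition, t, int(s)))
    pd.DataFrame(rows, columns=_STATE_COLUMNS).to_csv(path, index=False)


def read_states(path: str | Path, k: int) -> StateSequenceSet:
    """Read a (subject, condition, frame_index, state) table into sequences.

    Rows are ordered by frame_index within each subject x condition session;
    out-of-range states are rejected with their 1-based file line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise MalformedFileError(f"cannot parse {path}: {err}") from err
    missing = set(_STATE_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedFileError(f"{path} lacks columns {sorted(missing)}", line=1)
    states_numeric = pd.to_numeric(df["state"], errors="coerce")
    bad = states_numeric.isna() | (states_numeric % 1 != 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
        raise MalformedFileError(f"{path}: non-integer state at line {line}", line=line)
    df["state"] = states_numeric.astype(np.int64)
    out_of_range = (df["state"] < 0) | (df["state"] >= k)
    if out_of_range.any():
        line = int(df.index[out_of_range][0]) + 2
        value = int(df.loc[df.index[out_of_range][0], "state"])
        raise MalformedFileError(
            f"{path}: state {value} out of range [0, {k - 1}] at line {line}", line=line
        )
    records = []
    for (subj, cond), grp in df.groupby(["subject", "condition"], sort=False):
        grp = grp.sort_values("frame_index")
        records.append(StateSequenceRecord(str(subj), str(cond), grp["state"].to_numpy()))
    return StateSequenceSet(sequences=tuple(records), k=k)


def _provenance(config: RunConfig | None = None, seed: int | None = None) -> dict:
    from . import __version__

    out: dict = {"statebridge_version": __version__}
    if config is not None:
        out["config"] = dataclasses.asdict(config)
        out["config_hash"] = config.hash()
    if seed is not None:
        out["seed"] = int(seed)
    return out


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonify)
    Path(path).write_text(Path(path).read_text() + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_bridge_solution(
    solution: BridgeSolution,
    path: str | Path,
    pi: ProbabilityVector,
    pi_target: ProbabilityVector,
    config: RunConfig | None = None,
) -> None:
    k = pi.k
    payload = {
        "states": list(pi.labels or default_labels(k)),
        "pi": pi.probs,
        "pi_target": pi_target.probs,
        "T": solution.optimal_joint.horizon,
        "cost_nats": solution.cost,
        "cost_bits": solution.cost_bits(),
        "alpha": solution.alpha,
        "beta": solution.beta,
        "optimal_joint": solution.optimal_joint.joint,
        "iterations": solution.iterations,
        "residual": solution.residual,
        "converged": solution.converged,
        "tol": solution.tol,
        "provenance": _provenance(config),
    }
    write_json(payload, path)


def write_ensemble(ens: BootstrapEnsemble, path: str | Path, config: RunConfig | None = None) -> None:
    payload = {
        "values": ens.values,
        "statuses": list(ens.statuses),
        "n_replicates": ens.n_replicates,
        "n_failed": ens.n_failed,
        "mean": ens.mean(),
        "sd": ens.sd(),
        "master_seed": ens.seed,
        "provenance": _provenance(config),
    }
    write_json(payload, path)


def write_cost_table(table, path_csv: str | Path, path_json: str | Path | None = None,
                     config: RunConfig | None = None) -> None:
    """Cost table as labeled CSV; optional JSON with SDs and provenance."""
    table.to_frame().to_csv(path_csv)
    if path_json is not None:
        payload = {
            "conditions": list(table.conditions),
            "costs_nats": table.costs,
            "sds": table.sds,
            "n_replicates": table.n_replicates,
            "provenance": _provenance(config),
        }
        write_json(payload, path_json)


def export_heatmap(matrix: np.ndarray, labels, path: str | Path, title: str = "") -> None:
    """Simple labeled heatmap (PNG/PDF by extension); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * len(labels),) * 2)
    im = ax.imshow(np.asarray(matrix), cmap="RdBu_r")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
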
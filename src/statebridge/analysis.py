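"""Condition-pair cost tables, asymmetry, ordering consistency, and t tests.

Given bootstrap cost ensembles for every ordered condition pair, this module
builds the mean/SD cost table, the antisymmetric difference matrix
Diff(A, B) = cost(A->B) - cost(B->A), and checks the ordering-consistency
relation: whenever the cost from the baseline to A exceeds the cost from the
baseline to B, the direct transition B->A should also be costlier than A->B.
Significance between two ensembles uses a pooled-variance two-sample t test
(replicates treated as independent samples; with 100 + 100 replicates the
degrees of freedom are 198). No multiple-comparison correction is applied;
reports carry the number of comparisons so users can correct downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, DimensionError, StateBridgeError
from .types import BootstrapEnsemble

__all__ = [
    "CostTable",
    "AsymmetryMatrix",
    "TTestResult",
    "OrderingReport",
    "pairwise_costs",
    "asymmetry_matrix",
    "ordering_consistency",
    "bootstrap_ttest",
]


@dataclass(frozen=True)
class CostTable:
    """Mean and SD bootstrap transition cost for every ordered pair (nats).

    ``costs[a, b]`` is the mean replicate cost of condition a -> condition b.
    The diagonal holds each condition's self-transition cost, which is zero
    only when the condition's distribution equals its own uncontrolled image,
    so no zero-diagonal is assumed anywhere.
    """

    conditions: tuple[str, ...]
    costs: np.ndarray
    sds: np.ndarray
    n_replicates: int
    ensembles: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.conditions)
        costs = np.asarray(self.costs, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if costs.shape != (n, n) or sds.shape != (n, n):
            raise DimensionError("cost/sd matrices must be n x n for n conditions")
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "sds", sds)

    def loc(self, a: str, b: str) -> float:
        return float(self.costs[self.conditions.index(a), self.conditions.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.costs, index=self.conditions, columns=self.conditions)


@dataclass(frozen=True)
class AsymmetryMatrix:
    """Antisymmetric Diff(A, B) = cost(A->B) - cost(B->A), with its ordering."""

    conditions: tuple[str, ...]
    diff: np.ndarray

    def __post_init__(self):
        diff = np.asarray(self.diff, dtype=float)
        n = len(self.conditions)
        if diff.shape != (n, n):
            raise DimensionError("diff must be n x n")
        object.__setattr__(self, "diff", diff)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.diff, index=self.conditions, columns=self.conditions)


def pairwise_costs(ensembles: dict[tuple[str, str], BootstrapEnsemble]) -> CostTable:
    """Assemble per-pair bootstrap ensembles into a mean/SD cost table.

    Conditions are taken in order of first appearance among the pair keys.
    Missing self-pairs (a, a) get NaN entries; all ensembles must share the
    replicate count.
    """
    if not ensembles:
        raise StateBridgeError("no ensembles given")
    conditions: dict[str, None] = {}
    for a, b in ensembles:
        conditions.setdefault(a, None)
        conditions.setdefault(b, None)
    conds = tuple(conditions)
    counts = {e.n_replicates for e in ensembles.values()}
    if len(counts) != 1:
        raise StateBridgeError(f"mismatched replicate counts across pairs: {sorted(counts)}")
    n = len(conds)
    costs = np.full((n, n), np.nan)
    sds = np.full((n, n), np.nan)
    for (a, b), ens in ensembles.items():
        i, j = conds.index(a), conds.index(b)
        costs[i, j] = ens.mean()
        sds[i, j] = ens.sd()
    return CostTable(
        conditions=conds,
        costs=costs,
        sds=sds,
        n_replicates=counts.pop(),
        ensembles=dict(ensembles),
    )


def asymmetry_matrix(table: CostTable, baseline: str | None = None) -> AsymmetryMatrix:
    """Antisymmetric cost-difference matrix Diff = costs - costs^T.

    When ``baseline`` is given, rows/columns are rearranged in ascending
    order of the cost from the baseline (the baseline itself first), the
    convention under which a consistent cost hierarchy shows up as an
    all-positive upper triangle.
    """
    conds = list(table.conditions)
    costs = table.costs
    if baseline is not None:
        if baseline not in conds:
            raise StateBridgeError(f"baseline {baseline!r} not in table")
        b = conds.index(baseline)
        others = [i for i in range(len(conds)) if i != b]
        order = [b] + sorted(others, key=lambda i: costs[b, i])
        conds = [conds[i] for i in order]
        costs = costs[np.ix_(order, order)]
    diff = costs - costs.T
    np.fill_diagonal(diff, 0.0)
    return AsymmetryMatrix(conditions=tuple(conds), diff=diff)


@dataclass(frozen=True)
class OrderingReport:
    """Outcome of the ordering-consistency check against a baseline."""

    baseline: str
    n_pairs: int
    n_consistent: int
    violations: tuple[tuple[str, str], ...]

    @property
    def fraction(self) -> float:
        return self.n_consistent / self.n_pairs if self.n_pairs else float("nan")


def ordering_consistency(table: CostTable, baseline: str) -> OrderingReport:
    """Check cost(baseline->A) > cost(baseline->B)  =>  cost(B->A) > cost(A->B).

    Every unordered non-baseline pair with strictly different baseline costs
    is examined once; ties contribute no pair. Violating pairs are reported
    as (A, B) with A the condition costlier to reach from the baseline.
    """
    if baseline not in table.conditions:
        raise StateBridgeError(f"baseline {baseline!r} not in table")
    conds = [c for c in table.conditions if c != baseline]
    n_pairs = 0
    n_ok = 0
    violations = []
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            ra, rb = table.loc(baseline, a), table.loc(baseline, b)
            if ra == rb:
                continue
            hard, easy = (a, b) if ra > rb else (b, a)
            n_pairs += 1
            if table.loc(easy, hard) > table.loc(hard, easy):
                n_ok += 1
            else:
                violations.append((hard, easy))
    return OrderingReport(
        baseline=baseline, n_pairs=n_pairs, n_consistent=n_ok, violations=tuple(violations)
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    side: str
    n_a: int
    n_b: int
    note: str = (
        "bootstrap replicates treated as independent samples (anti-conservative); "
        "no multiple-testing correction applied"
    )


def bootstrap_ttest(costs_a, costs_b, side: str = "greater") -> TTestResult:
    """Pooled-variance two-sample t test between two replicate cost vectors.

    t is positive when mean(costs_a) > mean(costs_b); df = n_a + n_b - 2.
    ``side``: "greater" tests mean_a > mean_b, "less" the reverse,
    "two-sided" the difference. Identical samples with internal variance give
    t = 0 and one-sided p = 0.5; two constant samples have no variance to
    pool and raise :class:`DegenerateVarianceError`.
    """
    a = np.asarray(costs_a, dtype=float)
    b = np.asarray(costs_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise DimensionError("need two 1-D replicate vectors of length >= 2")
    if side not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown side {side!r}")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        raise DegenerateVarianceError("both samples are constant; t is undefined")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    if side == "greater":
        p = float(stats.t.sf(t, df))
    elif side == "less":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, side=side, n_a=na, n_b=nb)
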
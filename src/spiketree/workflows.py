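"""Group-search procedures over the encoded interval table.

Five analyses, all built on the same fit/score cycle (snap undersampling,
cost-sensitive tree, complete-set MCC):

* **direct** — one model on the full unit set (single seed or multi-seed);
  its primary group (units with variable importance > 0) is the first
  connectivity estimate.
* **individual** — one single-attribute model per unit, ranked by
  complete-set MCC; monosynaptic partners of the target surface at the top.
* **combinatory** — exhaustive wrapper search over all 2^n - 1 nonempty
  unit subsets (guarded to small n); units are scored by how often they
  appear in the top percentile of subsets ranked by MCC, and the most
  frequent ones form the "relevant group".
* **iterative** — backward elimination: drop the unit with the worst
  individual MCC each epoch and track the full-model MCC; the "critical
  point" is the smallest group still within 0.01 of the best MCC.
* **recursive** — repeatedly split the unit set into the model's primary
  group (importance > 0) and the remainder, recursing into both, so
  relevant units concentrate in the upper branches at logarithmic cost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .c5tree import CostMatrix, EncodedTable, FitConfig
from .evaluation import (
    MetricsResult,
    MultiSeedResult,
    RunResult,
    SnapPartition,
    run_multi_seed,
    run_once,
    snap_sample,
)
from .intervals import IntervalTable

__all__ = [
    "GroupRanking",
    "IterativeTrajectory",
    "RecursiveNode",
    "direct_analysis",
    "individual_analysis",
    "count_subsets",
    "combinatory_analysis",
    "iterative_analysis",
    "recursive_analysis",
]

COMBINATORY_GUARD = 16


def _encoded(table) -> EncodedTable:
    return table if isinstance(table, EncodedTable) else EncodedTable(table, None)


# --------------------------------------------------------------------------
# direct & individual
# --------------------------------------------------------------------------


def direct_analysis(
    table,
    units: list[str] | None = None,
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    seeds: int | list[int] = 0,
    ratio: float = 4.0,
    master_seed: int | None = None,
) -> RunResult | MultiSeedResult:
    """One model on the chosen unit set.

    ``seeds`` may be a single snap seed (returns :class:`RunResult`) or a
    repetition count with ``master_seed`` (returns :class:`MultiSeedResult`).
    """
    enc = _encoded(table)
    if isinstance(seeds, int) and master_seed is None:
        return run_once(enc, units=units, costs=costs, cfg=cfg, rng_seed=seeds, ratio=ratio)
    n = seeds if isinstance(seeds, int) else len(seeds)
    return run_multi_seed(
        enc, units=units, costs=costs, cfg=cfg, n_seeds=n,
        master_seed=master_seed or 0, ratio=ratio,
    )


def individual_analysis(
    table,
    units: list[str] | None = None,
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    rng_seed: int = 0,
    ratio: float = 4.0,
    partition: SnapPartition | None = None,
) -> list[tuple[str, MetricsResult]]:
    """One single-attribute model per unit; complete-set metrics, ranked.

    All units share one snap partition so their MCCs are comparable.
    Returns ``(unit, metrics)`` pairs sorted by descending complete-set MCC
    (ties: ascending unit order).
    """
    enc = _encoded(table)
    units = list(units) if units is not None else list(enc.attributes)
    if not units:
        raise ValueError("individual analysis needs at least one unit")
    if partition is None:
        partition = snap_sample(enc, ratio=ratio, rng_seed=rng_seed)  # type: ignore[arg-type]
    results = []
    for u in units:
        r = run_once(
            enc, units=[u], costs=costs, cfg=cfg, rng_seed=rng_seed,
            ratio=ratio, partition=partition,
        )
        results.append((u, r.metrics["complete"]))
    order = {u: i for i, u in enumerate(units)}
    results.sort(key=lambda kv: (-kv[1].mcc, order[kv[0]]))
    return results


# --------------------------------------------------------------------------
# combinatory
# --------------------------------------------------------------------------


def count_subsets(n: int) -> int:
    """Number of nonempty unit subsets: sum over r of C(n, r) = 2^n - 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2**n - 1


@dataclass
class GroupRanking:
    """All nonempty subsets ranked by complete-set MCC, plus the frequency
    with which each unit appears in the top percentile of that ranking."""

    entries: list[tuple[tuple[str, ...], float]]     # (subset, mcc), descending
    percentile_cutoff: float
    frequency: dict[str, int]
    relevant_group: set[str]
    n_top: int
    seed: int


def combinatory_analysis(
    table,
    units: list[str],
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    rng_seed: int = 0,
    ratio: float = 4.0,
    cutoff: float = 0.01,
    guard: int = COMBINATORY_GUARD,
    share_partition: bool = True,
) -> GroupRanking:
    """Fit one model per nonempty subset of ``units`` and rank by MCC.

    All subsets share one snap partition per seed (so MCCs are comparable;
    set ``share_partition=False`` to re-sample per subset).  The ranking is
    descending by complete-set MCC with ties broken by smaller subset size,
    then lexicographic unit order.  Units appearing in at least half as
    many top-percentile subsets as the most frequent unit form the
    relevant group.
    """
    units = list(units)
    n = len(units)
    if n > guard:
        raise ValueError(
            f"combinatory search over {n} units means {count_subsets(n)} fits; "
            f"the guard is {guard} — consider the iterative or recursive analysis"
        )
    enc = _encoded(table)
    partition = snap_sample(enc, ratio=ratio, rng_seed=rng_seed)  # type: ignore[arg-type]
    pos = {u: i for i, u in enumerate(units)}
    entries = []
    for mask in range(1, 2**n):
        subset = tuple(u for u in units if mask & (1 << pos[u]))
        part = (
            partition
            if share_partition
            else snap_sample(enc, ratio=ratio, rng_seed=rng_seed + mask)  # type: ignore[arg-type]
        )
        r = run_once(enc, units=list(subset), costs=costs, cfg=cfg,
                     rng_seed=rng_seed, ratio=ratio, partition=part)
        entries.append((subset, r.metrics["complete"].mcc))
    entries.sort(key=lambda e: (-e[1], len(e[0]), e[0]))

    n_top = math.ceil(cutoff * len(entries))
    frequency = {u: 0 for u in units}
    for subset, _ in entries[:n_top]:
        for u in subset:
            frequency[u] += 1
    max_freq = max(frequency.values())
    relevant = {u for u, f in frequency.items() if max_freq > 0 and f >= 0.5 * max_freq}
    return GroupRanking(
        entries=entries,
        percentile_cutoff=cutoff,
        frequency=frequency,
        relevant_group=relevant,
        n_top=n_top,
        seed=int(rng_seed),
    )


# --------------------------------------------------------------------------
# iterative
# --------------------------------------------------------------------------


@dataclass
class IterativeTrajectory:
    """Backward-elimination trace: one step per remaining-subset size."""

    steps: list[tuple[tuple[str, ...], MetricsResult]]
    critical_point: int          # index of the critical step
    removed_order: list[str]

    @property
    def critical_subset(self) -> tuple[str, ...]:
        return self.steps[self.critical_point][0]


def iterative_analysis(
    table,
    units: list[str] | None = None,
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    rng_seed: int = 0,
    ratio: float = 4.0,
    prefilter: bool = False,
    mcc_tolerance: float = 0.01,
) -> IterativeTrajectory:
    """Rank units by individual MCC, then drop the worst one per epoch.

    Records the complete-set metrics of the full model at every epoch.  The
    critical point is the smallest subset whose MCC is within
    ``mcc_tolerance`` of the trajectory maximum.  With ``prefilter`` units
    with individual MCC <= 0 are excluded before the first epoch.  A fit
    failure at an epoch is recorded as all-zero metrics and the elimination
    continues.
    """
    enc = _encoded(table)
    units = list(units) if units is not None else list(enc.attributes)
    if len(units) < 2:
        raise ValueError("iterative analysis needs at least 2 units")
    ranked = individual_analysis(
        table=enc, units=units, costs=costs, cfg=cfg, rng_seed=rng_seed, ratio=ratio
    )
    if prefilter:
        kept = [u for u, m in ranked if m.mcc > 0]
        if len(kept) >= 2:
            ranked = [(u, m) for u, m in ranked if u in set(kept)]
        else:
            warnings.warn("prefilter would leave < 2 units; keeping all")
    order = [u for u, _ in ranked]          # best to worst

    steps: list[tuple[tuple[str, ...], MetricsResult]] = []
    removed: list[str] = []
    current = list(order)
    while current:
        try:
            r = run_once(enc, units=current, costs=costs, cfg=cfg,
                         rng_seed=rng_seed, ratio=ratio)
            metrics = r.metrics["complete"]
        except ValueError:
            metrics = MetricsResult(precision=0.0, recall=0.0, mcc=0.0)
        steps.append((tuple(current), metrics))
        if len(current) == 1:
            break
        worst = current[-1]                  # lowest individual MCC remaining
        removed.append(worst)
        current = current[:-1]

    best_mcc = max(m.mcc for _, m in steps)
    eligible = [i for i, (_, m) in enumerate(steps) if m.mcc >= best_mcc - mcc_tolerance]
    critical = min(eligible, key=lambda i: (len(steps[i][0]), i))  # smallest group wins
    return IterativeTrajectory(steps=steps, critical_point=critical, removed_order=removed)


# --------------------------------------------------------------------------
# recursive
# --------------------------------------------------------------------------


@dataclass
class RecursiveNode:
    """Node of the recursive importance-split tree."""

    units: tuple[str, ...]
    result: RunResult | None           # None marks a fit failure
    primary: "RecursiveNode | None" = None
    secondary: "RecursiveNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.primary is None and self.secondary is None

    def leaves(self) -> list["RecursiveNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in (self.primary, self.secondary):
            if child is not None:
                out.extend(child.leaves())
        return out

    def walk(self):
        yield self
        for child in (self.primary, self.secondary):
            if child is not None:
                yield from child.walk()


def recursive_analysis(
    table,
    units: list[str] | None = None,
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    rng_seed: int = 0,
    ratio: float = 4.0,
    max_depth: int = 32,
) -> RecursiveNode:
    """Recursively split units into importance>0 and importance=0 groups.

    Each node fits a model on its unit subset; the children partition the
    subset into the model's primary group and the remainder, and both are
    analysed in turn.  Recursion stops at singletons, at fit failures
    (single-leaf models), and at ``max_depth``.  When every unit has
    positive importance the split falls back to the importance median
    (strictly-above-median units form the primary child).
    """
    enc = _encoded(table)
    units = tuple(units) if units is not None else tuple(enc.attributes)
    if not units:
        raise ValueError("recursive analysis needs at least one unit")

    def analyse(subset: tuple[str, ...], depth: int) -> RecursiveNode:
        try:
            r = run_once(enc, units=list(subset), costs=costs, cfg=cfg,
                         rng_seed=rng_seed, ratio=ratio)
        except ValueError:
            return RecursiveNode(units=subset, result=None)
        node = RecursiveNode(units=subset, result=r)
        if len(subset) == 1 or depth >= max_depth or r.model.is_stump:
            return node
        imp = r.model.importance
        primary = [u for u in subset if imp.get(u, 0.0) > 0]
        secondary = [u for u in subset if imp.get(u, 0.0) <= 0]
        if not secondary:
            med = float(np.median([imp[u] for u in subset]))
            primary = [u for u in subset if imp[u] > med]
            secondary = [u for u in subset if imp[u] <= med]
        if not primary or not secondary:   # unsplittable (all importances tied)
            return node
        node.primary = analyse(tuple(primary), depth + 1)
        node.secondary = analyse(tuple(secondary), depth + 1)
        return node

    return analyse(units, 0)
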
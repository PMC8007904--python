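"""Cost-sensitive categorical decision trees of the C4.5/C5.0 family.

A from-scratch learner for purely categorical attributes (the interval
codes ``"0"``, ``"A"``, ``"BBD"`` ... are atomic categories, never
decomposed), with the pieces of the classic algorithm that matter for this
pipeline:

* multiway splits chosen by **gain ratio** among attributes whose
  information gain is at least the average gain of the usable candidates;
* **pessimistic (error-based) pruning** with the standard confidence-limit
  estimate (default CF = 0.25), collapse-only;
* a **misclassification cost matrix**: leaf classes minimize expected cost
  (with the default costs a leaf predicts firing whenever
  ``3.5 * positives > 1.0 * negatives``), and pruning compares expected
  costs rather than raw errors;
* C5.0-style **variable importance** ("usage"): the percentage of training
  cases whose prediction path encounters a split on the attribute;
* optional **boosting** (``trials > 1``) by AdaBoost-style case reweighting
  with a cost-weighted committee vote;
* **rule extraction** (one rule per leaf, exactly equivalent to the tree).

Unseen categories at prediction time route to the branch that received the
most training cases, so predictions never fail on new codes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaincinv

from .intervals import IntervalTable

__all__ = [
    "CostMatrix",
    "FitConfig",
    "Node",
    "TreeModel",
    "Rule",
    "fit_tree",
    "predict",
    "variable_importance",
    "primary_group",
    "extract_rules",
    "apply_rules",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs; correct classifications cost 0."""

    fn_cost: float = 3.5
    fp_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.fn_cost < 0 or self.fp_cost < 0:
            raise ValueError("costs must be non-negative")

    def leaf_class(self, w0: float, w1: float) -> int:
        """Minimum-expected-cost class for a leaf with (neg, pos) case weight.

        Predicting 0 costs ``fn_cost`` per positive; predicting 1 costs
        ``fp_cost`` per negative.  Ties break toward class 0.
        """
        return 1 if w1 * self.fn_cost > w0 * self.fp_cost else 0


@dataclass(frozen=True)
class FitConfig:
    trials: int = 1
    prune_confidence: float = 0.25
    min_cases_per_branch: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not (0.0 < self.prune_confidence < 1.0):
            raise ValueError("prune_confidence must lie in (0, 1)")


@dataclass
class Node:
    """Tree node: a leaf, or a multiway split with one branch per category."""

    attr: int | None = None                  # attribute index; None for leaves
    children: dict[int, "Node"] = field(default_factory=dict)  # category -> child
    fallback: int | None = None              # category of the best-populated branch
    klass: int = 0                           # leaf class (min expected cost)
    w0: float = 0.0                          # training case weight, class 0
    w1: float = 0.0                          # training case weight, class 1

    @property
    def is_leaf(self) -> bool:
        return self.attr is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children.values())


@dataclass
class TreeModel:
    """A fitted tree or boosted committee over categorical interval codes."""

    trees: list[tuple[Node, float]]          # (root, committee weight)
    attributes: list[str]
    categories: dict[str, list[str]]         # per attribute, category labels
    costs: CostMatrix
    cfg: FitConfig
    n_training_cases: int
    importance: dict[str, float] = field(default_factory=dict)

    @property
    def is_stump(self) -> bool:
        """True when no tree contains a single split ("could not fit")."""
        return all(root.is_leaf for root, _ in self.trees)

    # -- serialization -----------------------------------------------------
    FORMAT_VERSION = 1

    def to_dict(self) -> dict:
        def node_dict(n: Node) -> dict:
            d = {"klass": n.klass, "w0": n.w0, "w1": n.w1}
            if not n.is_leaf:
                d["attr"] = n.attr
                d["fallback"] = n.fallback
                d["children"] = {str(c): node_dict(ch) for c, ch in n.children.items()}
            return d

        return {
            "format_version": self.FORMAT_VERSION,
            "attributes": self.attributes,
            "categories": self.categories,
            "costs": {"fn_cost": self.costs.fn_cost, "fp_cost": self.costs.fp_cost},
            "cfg": {
                "trials": self.cfg.trials,
                "prune_confidence": self.cfg.prune_confidence,
                "min_cases_per_branch": self.cfg.min_cases_per_branch,
                "rng_seed": self.cfg.rng_seed,
            },
            "n_training_cases": self.n_training_cases,
            "importance": self.importance,
            "trees": [{"weight": w, "root": node_dict(r)} for r, w in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        if d.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")

        def build(nd: dict) -> Node:
            node = Node(klass=int(nd["klass"]), w0=float(nd["w0"]), w1=float(nd["w1"]))
            if "attr" in nd:
                node.attr = int(nd["attr"])
                node.fallback = int(nd["fallback"])
                node.children = {int(c): build(ch) for c, ch in nd["children"].items()}
            return node

        return cls(
            trees=[(build(t["root"]), float(t["weight"])) for t in d["trees"]],
            attributes=list(d["attributes"]),
            categories={a: list(c) for a, c in d["categories"].items()},
            costs=CostMatrix(**d["costs"]),
            cfg=FitConfig(**d["cfg"]),
            n_training_cases=int(d["n_training_cases"]),
            importance={a: float(v) for a, v in d["importance"].items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "TreeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# encoding
# --------------------------------------------------------------------------


class EncodedTable:
    """Integer-encoded view of an interval table, shareable across many fits.

    Encoding the full table once and fitting on row subsets is what makes
    the exhaustive combinatory search (thousands of fits) affordable.
    """

    def __init__(self, table: IntervalTable, attributes: list[str] | None = None):
        self.attributes = list(attributes) if attributes is not None else list(table.units)
        self.y = table.y.astype(np.int8)
        self.n = len(self.y)
        self.categories: dict[str, list[str]] = {}
        cols = []
        for a in self.attributes:
            codes, cats = pd.factorize(table.data[a], sort=True)
            self.categories[a] = [str(c) for c in cats]
            cols.append(codes.astype(np.int32))
        self.X = np.column_stack(cols) if cols else np.empty((self.n, 0), dtype=np.int32)
        self.n_cats = np.array([len(self.categories[a]) for a in self.attributes])

    def column_subset(self, attrs: list[str]) -> np.ndarray:
        idx = [self.attributes.index(a) for a in attrs]
        return np.asarray(idx, dtype=np.intp)


def _encode_frame(frame: pd.DataFrame, attributes: list[str], categories: dict[str, list[str]]):
    """Map a string-code frame onto a model's integer encoding (-1 = unseen)."""
    missing = [a for a in attributes if a not in frame.columns]
    if missing:
        raise KeyError(f"missing attribute column(s): {missing}")
    cols = []
    for a in attributes:
        mapping = {c: i for i, c in enumerate(categories[a])}
        cols.append(frame[a].map(mapping).fillna(-1).to_numpy(dtype=np.int32))
    return np.column_stack(cols) if cols else np.empty((len(frame), 0), dtype=np.int32)


# --------------------------------------------------------------------------
# growing
# --------------------------------------------------------------------------


def _entropy(w0: float, w1: float) -> float:
    n = w0 + w1
    if n <= 0 or w0 <= 0 or w1 <= 0:
        return 0.0
    p = w1 / n
    return -(p * math.log2(p) + (1.0 - p) * math.log2(1.0 - p))


def _best_split(X, y, w, idx, attr_ids, n_cats, min_cases):
    """Choose the split attribute at a node, C4.5 style.

    Among attributes with a usable split (>= 2 populated branches, at least
    two of them holding ``min_cases`` or more) and positive information
    gain, keep those whose gain is at least the average gain of the usable
    candidates, and of these return the one with the highest gain ratio
    (ties: first attribute in table order).
    """
    wi = w[idx]
    yi = y[idx]
    W = wi.sum()
    w1 = float(wi[yi == 1].sum())
    parent_h = _entropy(W - w1, w1)
    gains, ratios, usable = {}, {}, []
    for a in attr_ids:
        cats = X[idx, a]
        nc = n_cats[a]
        tot = np.bincount(cats, weights=wi, minlength=nc)
        pos = np.bincount(cats, weights=wi * yi, minlength=nc)
        nz = tot > 0
        if int(nz.sum()) < 2 or int((tot >= min_cases).sum()) < 2:
            continue
        cond_h = 0.0
        split_info = 0.0
        for wc, pc in zip(tot[nz], pos[nz]):
            frac = wc / W
            cond_h += frac * _entropy(wc - pc, pc)
            split_info -= frac * math.log2(frac)
        gain = parent_h - cond_h
        if gain <= _EPS or split_info <= _EPS:
            continue
        usable.append(a)
        gains[a] = gain
        ratios[a] = gain / split_info
    if not usable:
        return None
    avg_gain = sum(gains[a] for a in usable) / len(usable)
    best = None
    for a in usable:  # ascending attribute order -> deterministic tie-break
        if gains[a] >= avg_gain - _EPS and (best is None or ratios[a] > ratios[best] + _EPS):
            best = a
    return best


def _grow(X, y, w, idx, attr_ids, n_cats, costs: CostMatrix, cfg: FitConfig) -> Node:
    wi = w[idx]
    yi = y[idx]
    w1 = float(wi[yi == 1].sum())
    w0 = float(wi.sum() - w1)
    leaf = Node(klass=costs.leaf_class(w0, w1), w0=w0, w1=w1)
    if w0 <= 0 or w1 <= 0 or len(idx) < 2 * cfg.min_cases_per_branch or not attr_ids:
        return leaf
    a = _best_split(X, y, w, idx, attr_ids, n_cats, cfg.min_cases_per_branch)
    if a is None:
        return leaf
    node = Node(attr=a, klass=leaf.klass, w0=w0, w1=w1)
    cats = X[idx, a]
    sub_attrs = [b for b in attr_ids if b != a]  # categorical splits exhaust the attribute
    best_cat, best_weight = None, -1.0
    for c in np.unique(cats):
        sel = idx[cats == c]
        node.children[int(c)] = _grow(X, y, w, sel, sub_attrs, n_cats, costs, cfg)
        wc = float(w[sel].sum())
        if wc > best_weight:
            best_cat, best_weight = int(c), wc
    node.fallback = best_cat
    return node


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------


def _ucf(e: float, n: float, cf: float) -> float:
    """C4.5 upper confidence limit on the error rate of a leaf.

    The value U such that observing at most ``e`` errors in ``n`` cases has
    probability ``cf`` under a binomial with rate U.
    """
    if n <= 0:
        return 1.0
    if e >= n:
        return 1.0
    return float(1.0 - betaincinv(n - e, e + 1.0, cf))


def _pessimistic_errors(w0: float, w1: float, cf: float) -> float:
    """Upper-confidence estimate of the errors a leaf will make.

    Classic C4.5 estimate against the majority class.  Pruning is
    deliberately cost-blind: the tree's *structure* is decided exactly as
    without a cost matrix, and costs act only on leaf-class assignment and
    prediction.  Costing the speculative error bound asymmetrically either
    collapses perfectly predictive subtrees toward all-positive leaves (if
    the leaf's own class is used) or prunes away every weak-but-real split
    whose leaf flips to the expensive class (if majority errors are costed)
    — both pathologies of mixing the confidence bound with the cost matrix.
    """
    n = w0 + w1
    return n * _ucf(min(w0, w1), n, cf)


def _prune(node: Node, costs: CostMatrix, cf: float) -> tuple[Node, float]:
    if node.is_leaf:
        return node, _pessimistic_errors(node.w0, node.w1, cf)
    subtree_est = 0.0
    for c, ch in list(node.children.items()):
        node.children[c], ch_est = _prune(ch, costs, cf)
        subtree_est += ch_est
    leaf_est = _pessimistic_errors(node.w0, node.w1, cf)
    if leaf_est <= subtree_est + 0.1:
        leaf = Node(klass=costs.leaf_class(node.w0, node.w1), w0=node.w0, w1=node.w1)
        return leaf, leaf_est
    return node, subtree_est


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def fit_tree(
    table: IntervalTable | EncodedTable,
    costs: CostMatrix | None = None,
    cfg: FitConfig | None = None,
    attributes: list[str] | None = None,
    rows: np.ndarray | None = None,
) -> TreeModel:
    """Fit a cost-sensitive tree (or boosted committee) on interval rows.

    ``table`` may be an :class:`~spiketree.intervals.IntervalTable` or a
    pre-built :class:`EncodedTable`; ``attributes`` restricts the predictor
    units, ``rows`` restricts the training rows (index array).  Single-class
    input yields a degenerate single-leaf model with a warning.
    """
    costs = costs or CostMatrix()
    cfg = cfg or FitConfig()
    enc = table if isinstance(table, EncodedTable) else EncodedTable(table, attributes)
    if attributes is None:
        attr_cols = np.arange(len(enc.attributes), dtype=np.intp)
        attr_names = list(enc.attributes)
    else:
        attr_cols = enc.column_subset(attributes)
        attr_names = list(attributes)
    idx = np.arange(enc.n, dtype=np.intp) if rows is None else np.asarray(rows, dtype=np.intp)
    if idx.size < 2:
        raise ValueError("need at least 2 training rows")
    y = enc.y
    if y[idx].min() == y[idx].max():
        warnings.warn("single-class training input; degenerate single-leaf model")

    # local view: column j of X is attr_names[j]; trees store local indices
    X = enc.X[:, attr_cols] if len(attr_names) else np.empty((enc.n, 0), dtype=np.int32)
    n_cats = enc.n_cats[attr_cols]
    attr_ids = list(range(len(attr_names)))
    weights = np.ones(enc.n, dtype=np.float64)
    trees: list[tuple[Node, float]] = []
    for _trial in range(cfg.trials):
        root = _grow(X, y, weights, idx, attr_ids, n_cats, costs, cfg)
        root, _ = _prune(root, costs, cfg.prune_confidence)
        if cfg.trials == 1:
            trees.append((root, 1.0))
            break
        pred = _route_predict(root, X, idx)
        wrong = pred != y[idx]
        err = float(weights[idx][wrong].sum() / weights[idx].sum())
        if err <= _EPS or err >= 0.5:
            if not trees:
                trees.append((root, 1.0))
            break
        beta = err / (1.0 - err)
        alpha = math.log(1.0 / beta)
        trees.append((root, alpha))
        w_new = weights[idx].copy()
        w_new[~wrong] *= beta
        w_new *= idx.size / w_new.sum()
        weights[idx] = w_new

    model = TreeModel(
        trees=trees,
        attributes=attr_names,
        categories={a: enc.categories[a] for a in attr_names},
        costs=costs,
        cfg=cfg,
        n_training_cases=int(idx.size),
    )
    model.importance = _usage_importance(model, X, idx)
    return model


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def _route_predict(root: Node, X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Predict classes for rows ``idx`` of an encoded matrix under one tree."""
    out = np.empty(idx.size, dtype=np.int8)
    stack = [(root, np.arange(idx.size, dtype=np.intp))]
    while stack:
        node, pos = stack.pop()
        if node.is_leaf:
            out[pos] = node.klass
            continue
        cats = X[idx[pos], node.attr]
        routed = np.zeros(pos.size, dtype=bool)
        for c, child in node.children.items():
            mask = cats == c
            if mask.any():
                stack.append((child, pos[mask]))
                routed |= mask
        if not routed.all():  # unseen categories -> best-populated branch
            stack.append((node.children[node.fallback], pos[~routed]))
    return out


def predict(model: TreeModel, rows, attr_cols: np.ndarray | None = None) -> np.ndarray:
    """Predict class bits for rows (cost-weighted committee vote).

    ``rows`` may be an IntervalTable, a DataFrame of code strings, or an
    already-encoded integer matrix whose columns follow
    ``model.attributes`` (use ``attr_cols`` to locate them in a wider
    matrix from a shared :class:`EncodedTable`).
    """
    if isinstance(rows, IntervalTable):
        X = _encode_frame(rows.data, model.attributes, model.categories)
    elif isinstance(rows, pd.DataFrame):
        X = _encode_frame(rows, model.attributes, model.categories)
    else:
        X = np.asarray(rows)
        if attr_cols is not None:
            X = X[:, attr_cols]
    idx = np.arange(X.shape[0], dtype=np.intp)
    v1 = np.zeros(X.shape[0])
    total = 0.0
    for root, alpha in model.trees:
        pred = _route_predict(root, X, idx)
        v1 += alpha * pred
        total += alpha
    v0 = total - v1
    return (v1 * model.costs.fn_cost > v0 * model.costs.fp_cost).astype(np.int8)


# --------------------------------------------------------------------------
# importance, groups, rules
# --------------------------------------------------------------------------


def _usage_importance(model, Xl: np.ndarray, idx: np.ndarray) -> dict[str, float]:
    """C5.0 'usage': % of training cases meeting >= 1 split on the attribute.

    Each case counts once per attribute (at the shallowest split on its
    path); committees average the per-trial percentages.
    """
    totals = {a: 0.0 for a in model.attributes}
    for root, _alpha in model.trees:
        hits = {a: 0.0 for a in model.attributes}

        def walk(node: Node, pos: np.ndarray, seen: frozenset):
            if node.is_leaf or pos.size == 0:
                return
            name = model.attributes[node.attr]
            if name not in seen:
                hits[name] += pos.size
                seen = seen | {name}
            cats = Xl[idx[pos], node.attr]
            routed = np.zeros(pos.size, dtype=bool)
            for c, child in node.children.items():
                mask = cats == c
                if mask.any():
                    walk(child, pos[mask], seen)
                    routed |= mask
            if not routed.all():
                walk(node.children[node.fallback], pos[~routed], seen)

        walk(root, np.arange(idx.size, dtype=np.intp), frozenset())
        for a in model.attributes:
            totals[a] += 100.0 * hits[a] / idx.size
    k = len(model.trees)
    return {a: totals[a] / k for a in model.attributes}


def variable_importance(model: TreeModel) -> dict[str, float]:
    """Per-attribute usage percentage in [0, 100]; 0 for unused attributes."""
    return dict(model.importance)


def primary_group(model: TreeModel) -> set[str]:
    """Attributes actually used to build rules (importance > 0)."""
    return {a for a, v in model.importance.items() if v > 0}


@dataclass(frozen=True)
class RuleTest:
    """One branch condition: the attribute's code equals ``category``, or —
    when this branch doubles as the unseen-category fallback — the code
    matches none of the sibling branch categories."""

    attr: str
    category: str
    is_fallback: bool
    siblings: frozenset

    def passes(self, value: str) -> bool:
        if value == self.category:
            return True
        return self.is_fallback and value not in self.siblings

    def __str__(self) -> str:
        fb = " (or any unlisted code)" if self.is_fallback else ""
        return f"{self.attr}={self.category}{fb}"


@dataclass(frozen=True)
class Rule:
    """Root-to-leaf path: a conjunction of category tests plus a class."""

    tests: tuple[RuleTest, ...]
    klass: int
    coverage: float

    def matches(self, row: dict) -> bool:
        return all(t.passes(row[t.attr]) for t in self.tests)

    def describe(self) -> str:
        cond = " AND ".join(str(t) for t in self.tests) if self.tests else "TRUE"
        return f"IF {cond} THEN class={self.klass}  [{self.coverage:.0f} cases]"


def extract_rules(model: TreeModel) -> list[Rule]:
    """One rule per leaf of a single tree; exactly equivalent to :func:`predict`."""
    if len(model.trees) > 1:
        raise ValueError("rule extraction is only supported for trials=1 models")
    root = model.trees[0][0]
    rules: list[Rule] = []

    def walk(node: Node, tests: list[RuleTest]):
        if node.is_leaf:
            rules.append(Rule(tuple(tests), node.klass, node.w0 + node.w1))
            return
        name = model.attributes[node.attr]
        cat_names = model.categories[name]
        branch_names = {c: cat_names[c] for c in node.children}
        for c, child in node.children.items():
            siblings = frozenset(v for k, v in branch_names.items() if k != c)
            test = RuleTest(name, branch_names[c], c == node.fallback, siblings)
            walk(child, tests + [test])

    walk(root, [])
    return rules


def apply_rules(rules: list[Rule], frame: pd.DataFrame) -> np.ndarray:
    """Classify rows by the first matching rule (tree rules partition space)."""
    out = np.empty(len(frame), dtype=np.int8)
    records = frame.to_dict("records")
    for i, row in enumerate(records):
        for r in rules:
            if r.matches(row):
                out[i] = r.klass
                break
        else:  # pragma: no cover - rules from a tree always cover
            out[i] = 0
    return out
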
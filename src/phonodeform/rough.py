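"""Rule induction in the (a1, a2) plane: Pawlak decision systems,
maximal-discernibility discretization, LEM2 covering rules, and a
C4.5-style decision tree.

The screening decision ("does this patient have a laryngopathy?") is made
from two numeric deformation coefficients per patient. A decision system in
Pawlak's sense is the table S = (U, A, d): cases U, descriptive attributes
A = {a1, a2}, and a binary decision d in {no, yes}. Rule induction proceeds
either by Boolean-reasoning discretization followed by LEM2 covering, or by
growing an entropy-based binary decision tree directly on the numeric
attributes.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DecisionSystem",
    "Cut",
    "Interval",
    "DecisionRule",
    "TreeNode",
    "DecisionTree",
    "ClassificationReport",
    "InconsistentTableError",
    "boundary_cuts",
    "md_discretize",
    "lem2",
    "c45_tree",
    "tree_to_rules",
    "classify",
    "training_report",
    "LEM2Classifier",
    "C45DecisionTreeClassifier",
]

UNCOVERED = "uncovered"


class InconsistentTableError(ValueError):
    """Identical attribute values with different decision labels."""


@dataclass(frozen=True)
class DecisionSystem:
    """A Pawlak decision table S = (U, A, d)."""

    case_ids: tuple[str, ...]
    attributes: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]  # one row per case, A order
    decisions: tuple[str, ...]
    decision_domain: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.case_ids)
        if len(set(self.case_ids)) != n:
            raise ValueError("case_ids must be unique")
        if len(self.values) != n or len(self.decisions) != n:
            raise ValueError("values and decisions must match case count")
        for row in self.values:
            if len(row) != len(self.attributes):
                raise ValueError("every case needs a value for every attribute")
        if not self.decision_domain:
            seen: list[str] = []
            for d in self.decisions:
                if d not in seen:
                    seen.append(d)
            object.__setattr__(self, "decision_domain", tuple(seen))
        if not set(self.decisions) <= set(self.decision_domain):
            raise ValueError("decision outside decision_domain")

    def __len__(self) -> int:
        return len(self.case_ids)

    def value(self, case_index: int, attribute: str) -> float:
        return self.values[case_index][self.attributes.index(attribute)]

    def subset(self, indices) -> "DecisionSystem":
        indices = list(indices)
        return DecisionSystem(
            tuple(self.case_ids[i] for i in indices),
            self.attributes,
            tuple(self.values[i] for i in indices),
            tuple(self.decisions[i] for i in indices),
            self.decision_domain,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.values), columns=list(self.attributes))
        df.insert(0, "case_id", list(self.case_ids))
        df["decision"] = list(self.decisions)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DecisionSystem":
        attrs = [c for c in df.columns if c not in ("case_id", "decision")]
        return cls(
            tuple(str(c) for c in df["case_id"]),
            tuple(attrs),
            tuple(tuple(float(v) for v in row) for row in df[attrs].to_numpy()),
            tuple(str(d) for d in df["decision"]),
        )


@dataclass(frozen=True)
class Cut:
    """A discretization threshold on one numeric attribute."""

    attribute: str
    threshold: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class Interval:
    """A numeric interval with explicit endpoint openness."""

    lo: float = -math.inf
    hi: float = math.inf
    lo_open: bool = True
    hi_open: bool = True

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("empty interval")

    def contains(self, x: float) -> bool:
        if self.lo_open:
            if not x > self.lo:
                return False
        elif not x >= self.lo:
            return False
        if self.hi_open:
            return x < self.hi
        return x <= self.hi

    def intersect(self, other: "Interval") -> "Interval":
        if other.lo > self.lo or (other.lo == self.lo and other.lo_open):
            lo, lo_open = other.lo, other.lo_open
        else:
            lo, lo_open = self.lo, self.lo_open
        if other.hi < self.hi or (other.hi == self.hi and other.hi_open):
            hi, hi_open = other.hi, other.hi_open
        else:
            hi, hi_open = self.hi, self.hi_open
        return Interval(lo, hi, lo_open, hi_open)

    def __str__(self) -> str:
        lo = "-inf" if self.lo == -math.inf else f"{self.lo:g}"
        hi = "inf" if self.hi == math.inf else f"{self.hi:g}"
        return f"{'(' if self.lo_open else '['}{lo}, {hi}{')' if self.hi_open else ']'}"


@dataclass(frozen=True)
class DecisionRule:
    """IF <interval conditions> THEN <decision>, with its training support."""

    conditions: tuple[tuple[str, Interval], ...]
    decision: str
    support: tuple[str, ...] = ()

    def matches(self, features: dict) -> bool:
        for attribute, interval in self.conditions:
            if attribute not in features:
                raise KeyError(f"missing attribute: {attribute!r}")
            if not interval.contains(float(features[attribute])):
                return False
        return True

    def __str__(self) -> str:
        if not self.conditions:
            cond = "TRUE"
        else:
            cond = " AND ".join(
                f"{a} in {interval}" for a, interval in self.conditions
            )
        return f"IF {cond}, THEN d = {self.decision}"

    def to_json_dict(self) -> dict:
        return {
            "conditions": [
                {
                    "attribute": a,
                    "lo": i.lo,
                    "hi": i.hi,
                    "lo_open": i.lo_open,
                    "hi_open": i.hi_open,
                }
                for a, i in self.conditions
            ],
            "decision": self.decision,
            "support": list(self.support),
        }


@dataclass(frozen=True)
class TreeNode:
    """Leaf (label + training-case count) or internal split node."""

    label: str | None = None
    n_cases: int = 0
    attribute: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # attribute <= threshold
    right: "TreeNode | None" = None  # attribute > threshold

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def to_json_dict(self) -> dict:
        if self.is_leaf:
            return {"label": self.label, "n_cases": self.n_cases}
        return {
            "attribute": self.attribute,
            "threshold": self.threshold,
            "le": self.left.to_json_dict(),
            "gt": self.right.to_json_dict(),
        }


@dataclass(frozen=True)
class DecisionTree:
    root: TreeNode
    attributes: tuple[str, ...]
    n_training_cases: int

    def predict_one(self, features: dict) -> str:
        node = self.root
        while not node.is_leaf:
            if node.attribute not in features:
                raise KeyError(f"missing attribute: {node.attribute!r}")
            x = float(features[node.attribute])
            node = node.left if x <= node.threshold else node.right
        return node.label

    def to_json(self) -> str:
        return json.dumps(
            {
                "attributes": list(self.attributes),
                "n_training_cases": self.n_training_cases,
                "root": self.root.to_json_dict(),
            },
            indent=2,
        )


@dataclass(frozen=True)
class ClassificationReport:
    predictions: tuple[str, ...]  # per-case label or "uncovered"
    actual: tuple[str, ...]

    @property
    def uncovered_count(self) -> int:
        return sum(1 for p in self.predictions if p == UNCOVERED)

    @property
    def error_rate(self) -> float:
        """Percent misclassified among covered cases (0 if none covered)."""
        covered = [
            (p, a)
            for p, a in zip(self.predictions, self.actual)
            if p != UNCOVERED
        ]
        if not covered:
            warnings.warn("no case was covered; error rate defined as 0")
            return 0.0
        wrong = sum(1 for p, a in covered if p != a)
        return 100.0 * wrong / len(covered)


# ---------------------------------------------------------------------------
# Discretization


def boundary_cuts(ds: DecisionSystem, attribute: str) -> list[Cut]:
    """Midpoint cuts between consecutive distinct attribute values whose
    value-groups are not pure groups of one and the same label."""
    if attribute not in ds.attributes:
        raise KeyError(f"unknown attribute: {attribute!r}")
    groups: dict[float, set[str]] = {}
    for i in range(len(ds)):
        groups.setdefault(ds.value(i, attribute), set()).add(ds.decisions[i])
    values = sorted(groups)
    cuts = []
    for v1, v2 in itertools.pairwise(values):
        labels = groups[v1] | groups[v2]
        if len(labels) > 1:
            cuts.append(Cut(attribute, (v1 + v2) / 2.0))
    return cuts


def _region_key(row, attrs, cuts_by_attr):
    """Discretized signature of a case under the chosen cuts."""
    key = []
    for attribute, value in zip(attrs, row):
        thresholds = cuts_by_attr.get(attribute, ())
        key.append(sum(value > t for t in thresholds))
    return tuple(key)


def md_discretize(ds: DecisionSystem) -> list[Cut]:
    """Greedy maximal-discernibility discretization (Boolean reasoning).

    Repeatedly picks the cut that discerns the most still-undiscerned pairs
    of differently labeled cases. Candidate cuts are the class-boundary
    midpoints computed *within* each region (equivalence class of the cuts
    chosen so far) that still mixes labels; this is what makes later cuts
    adapt to the subproblem that remains. Ties break by attribute
    declaration order, then by the lower threshold.
    """
    if len(set(ds.decisions)) < 2:
        return []
    chosen: list[Cut] = []
    while True:
        cuts_by_attr: dict[str, list[float]] = {}
        for cut in chosen:
            cuts_by_attr.setdefault(cut.attribute, []).append(cut.threshold)
        regions: dict[tuple, list[int]] = {}
        for i in range(len(ds)):
            key = _region_key(ds.values[i], ds.attributes, cuts_by_attr)
            regions.setdefault(key, []).append(i)
        mixed = [
            idx for idx in regions.values()
            if len({ds.decisions[i] for i in idx}) > 1
        ]
        if not mixed:
            return chosen
        best = None  # (count, attr_order, threshold, cut)
        for idx in mixed:
            sub = ds.subset(idx)
            for a_order, attribute in enumerate(ds.attributes):
                for cut in boundary_cuts(sub, attribute):
                    count = 0
                    for region_idx in mixed:
                        below = [
                            i
                            for i in region_idx
                            if ds.value(i, cut.attribute) <= cut.threshold
                        ]
                        above = [i for i in region_idx if i not in below]
                        count += sum(
                            1
                            for i in below
                            for j in above
                            if ds.decisions[i] != ds.decisions[j]
                        )
                    key = (-count, a_order, cut.threshold)
                    if count > 0 and (best is None or key < best[0]):
                        best = (key, cut)
        if best is None:
            offending = next(
                idx for idx in mixed
                if any(
                    ds.values[i] == ds.values[j]
                    for i, j in itertools.combinations(idx, 2)
                    if ds.decisions[i] != ds.decisions[j]
                )
            )
            ids = [ds.case_ids[i] for i in offending]
            raise InconsistentTableError(
                f"cases {ids} share attribute values but differ in decision"
            )
        chosen.append(best[1])


def _intervals_from_cuts(
    attribute: str, thresholds: list[float]
) -> list[Interval]:
    """Open intervals delimited by the sorted cut thresholds."""
    points = [-math.inf, *sorted(thresholds), math.inf]
    return [Interval(lo, hi) for lo, hi in itertools.pairwise(points)]


# ---------------------------------------------------------------------------
# LEM2


def lem2(
    ds: DecisionSystem,
    cuts: list[Cut],
    coverage_fraction: float = 0.9,
) -> list[DecisionRule]:
    """LEM2 covering rule induction over the discretized blocks.

    For each decision concept, rules are grown greedily: the attribute-
    interval pair covering the most cases of the current goal is added
    (ties: smallest block, then attribute order, then lower interval) until
    the rule's block is consistent with the concept; redundant conditions
    are then pruned. Rule growing for a concept stops once at least
    ``coverage_fraction`` of the concept is covered, which tolerates
    outlying cases instead of fabricating single-case rules for them.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    cuts_by_attr: dict[str, list[float]] = {}
    for cut in cuts:
        cuts_by_attr.setdefault(cut.attribute, []).append(cut.threshold)
    # candidate (attribute, interval) pairs and their blocks (case indices)
    pairs: list[tuple[int, str, Interval, frozenset[int]]] = []
    for a_order, attribute in enumerate(ds.attributes):
        intervals = _intervals_from_cuts(
            attribute, cuts_by_attr.get(attribute, [])
        )
        for interval in intervals:
            block = frozenset(
                i
                for i in range(len(ds))
                if interval.contains(ds.value(i, attribute))
            )
            pairs.append((a_order, attribute, interval, block))
    rules: list[DecisionRule] = []
    for label in ds.decision_domain:
        concept = frozenset(
            i for i in range(len(ds)) if ds.decisions[i] == label
        )
        if not concept:
            continue
        uncovered = set(concept)
        needed = math.ceil(coverage_fraction * len(concept))
        while len(concept) - len(uncovered) < needed and uncovered:
            goal = set(uncovered)
            chosen: list[tuple[int, str, Interval, frozenset[int]]] = []
            block = frozenset(range(len(ds)))
            while not block <= concept:
                best = None
                for pair in pairs:
                    a_order, attribute, interval, pair_block = pair
                    if any(attribute == c[1] and interval == c[2] for c in chosen):
                        continue
                    gain = len(pair_block & goal)
                    if gain == 0:
                        continue
                    key = (-gain, len(pair_block), a_order, interval.lo)
                    if best is None or key < best[0]:
                        best = (key, pair)
                if best is None:
                    raise InconsistentTableError(
                        "cannot cover concept "
                        f"{label!r}: no block separates the remaining cases "
                        f"{sorted(ds.case_ids[i] for i in goal)}"
                    )
                chosen.append(best[1])
                block = block & best[1][3]
                goal = goal & best[1][3]
            # prune redundant conditions
            pruned = list(chosen)
            for cond in list(pruned):
                trial = [c for c in pruned if c is not cond]
                if not trial:
                    continue
                trial_block = frozenset(range(len(ds)))
                for c in trial:
                    trial_block = trial_block & c[3]
                if trial_block <= concept:
                    pruned = trial
                    block = trial_block
            conditions = _merge_conditions(pruned)
            rules.append(
                DecisionRule(
                    conditions=conditions,
                    decision=label,
                    support=tuple(sorted(ds.case_ids[i] for i in block)),
                )
            )
            uncovered -= block
    return rules


def _merge_conditions(
    chosen: list[tuple[int, str, Interval, frozenset[int]]]
) -> tuple[tuple[str, Interval], ...]:
    """Intersect same-attribute intervals, preserving attribute order."""
    by_attr: dict[str, Interval] = {}
    order: list[str] = []
    for _, attribute, interval, _ in sorted(chosen, key=lambda c: c[0]):
        if attribute in by_attr:
            by_attr[attribute] = by_attr[attribute].intersect(interval)
        else:
            by_attr[attribute] = interval
            order.append(attribute)
    return tuple((a, by_attr[a]) for a in order)


# ---------------------------------------------------------------------------
# C4.5-style decision tree


def _entropy(labels) -> float:
    counts = np.unique(np.asarray(labels), return_counts=True)[1]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def c45_tree(ds: DecisionSystem, min_leaf: int = 2) -> DecisionTree:
    """Grow an unpruned binary decision tree by information gain.

    At each node, candidate splits are the class-boundary midpoints of the
    node's cases on each attribute; the gain-optimal one is chosen (ties by
    attribute order, then lower threshold). The *recorded* threshold is the
    largest attribute value in the full training set not exceeding the
    chosen midpoint — the classical C4.5 convention, which keeps printed
    thresholds at observed data values. Recursion stops on pure nodes and on
    nodes with fewer than ``min_leaf`` cases.
    """
    if len(ds) == 0:
        raise ValueError("empty decision system")
    all_values = {
        attribute: sorted(ds.value(i, attribute) for i in range(len(ds)))
        for attribute in ds.attributes
    }

    def snap(attribute: str, midpoint: float) -> float:
        eligible = [v for v in all_values[attribute] if v <= midpoint]
        return max(eligible) if eligible else midpoint

    def majority(indices) -> str:
        counts = {label: 0 for label in ds.decision_domain}
        for i in indices:
            counts[ds.decisions[i]] += 1
        return max(ds.decision_domain, key=lambda lab: counts[lab])

    def grow(indices: list[int]) -> TreeNode:
        labels = [ds.decisions[i] for i in indices]
        if len(set(labels)) == 1 or len(indices) < min_leaf:
            return TreeNode(label=majority(indices), n_cases=len(indices))
        sub = ds.subset(indices)
        parent_entropy = _entropy(labels)
        best = None  # (key, attribute, midpoint, below, above)
        for a_order, attribute in enumerate(ds.attributes):
            for cut in boundary_cuts(sub, attribute):
                below = [
                    i for i in indices if ds.value(i, attribute) <= cut.threshold
                ]
                above = [i for i in indices if i not in below]
                child_entropy = (
                    len(below) * _entropy([ds.decisions[i] for i in below])
                    + len(above) * _entropy([ds.decisions[i] for i in above])
                ) / len(indices)
                gain = parent_entropy - child_entropy
                key = (-gain, a_order, cut.threshold)
                if best is None or key < best[0]:
                    best = (key, attribute, cut.threshold, below, above)
        if best is None:  # no boundary cut: identical values, mixed labels
            return TreeNode(label=majority(indices), n_cases=len(indices))
        _, attribute, midpoint, below, above = best
        return TreeNode(
            attribute=attribute,
            threshold=snap(attribute, midpoint),
            left=grow(below),
            right=grow(above),
        )

    return DecisionTree(grow(list(range(len(ds)))), ds.attributes, len(ds))


def tree_to_rules(tree: DecisionTree) -> list[DecisionRule]:
    """One rule per leaf: the conjunction of the tests on the root path.

    A ``<=`` branch contributes a (-inf, t] constraint, a ``>`` branch a
    (t, inf) constraint; same-attribute constraints are intersected.
    """
    rules: list[DecisionRule] = []

    def walk(node: TreeNode, path: list[tuple[str, Interval]]):
        if node.is_leaf:
            merged: dict[str, Interval] = {}
            order: list[str] = []
            for attribute, interval in path:
                if attribute in merged:
                    merged[attribute] = merged[attribute].intersect(interval)
                else:
                    merged[attribute] = interval
                    order.append(attribute)
            rules.append(
                DecisionRule(
                    conditions=tuple((a, merged[a]) for a in order),
                    decision=node.label,
                )
            )
            return
        walk(
            node.left,
            path + [(node.attribute, Interval(hi=node.threshold, hi_open=False))],
        )
        walk(
            node.right,
            path + [(node.attribute, Interval(lo=node.threshold, lo_open=True))],
        )

    walk(tree.root, [])
    return rules


# ---------------------------------------------------------------------------
# Classification


def classify(rules_or_tree, features: dict) -> str:
    """Apply LEM2-style rules (first match wins; may be uncovered) or a
    decision tree (always covers) to one case's attribute values."""
    if isinstance(rules_or_tree, DecisionTree):
        return rules_or_tree.predict_one(features)
    for rule in rules_or_tree:
        for attribute, _ in rule.conditions:
            if attribute not in features:
                raise KeyError(f"missing attribute: {attribute!r}")
    for rule in rules_or_tree:
        if rule.matches(features):
            return rule.decision
    return UNCOVERED


def training_report(rules_or_tree, ds: DecisionSystem) -> ClassificationReport:
    """Apply a classifier back to every case of a decision system."""
    predictions = tuple(
        classify(rules_or_tree, dict(zip(ds.attributes, ds.values[i])))
        for i in range(len(ds))
    )
    return ClassificationReport(predictions, ds.decisions)


# ---------------------------------------------------------------------------
# Scikit-learn-style estimators


class _RuleClassifierBase:
    """Shared fit plumbing: assemble a DecisionSystem from X, y."""

    feature_names: tuple[str, ...] | None

    def _build_ds(self, X, y) -> DecisionSystem:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        names = self.feature_names or tuple(
            f"x{j}" for j in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        return DecisionSystem(
            tuple(f"case_{i}" for i in range(X.shape[0])),
            tuple(names),
            tuple(tuple(row) for row in X),
            tuple(str(label) for label in y),
        )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"unknown parameter: {key!r}")
            setattr(self, key, value)
        return self


class LEM2Classifier(_RuleClassifierBase):
    """Rough-set rule classifier: MD discretization + LEM2 covering rules.

    Fitted attributes: ``cuts_`` (discretization thresholds), ``rules_``
    (the induced interval rules) and ``classes_``. ``predict`` returns the
    first matching rule's decision per case, or "uncovered" when no rule
    fires.
    """

    _param_names = ("coverage_fraction", "feature_names")

    def __init__(self, coverage_fraction: float = 0.9, feature_names=None):
        self.coverage_fraction = coverage_fraction
        self.feature_names = feature_names

    def fit(self, X, y) -> "LEM2Classifier":
        ds = self._build_ds(X, y)
        self.decision_system_ = ds
        self.cuts_ = md_discretize(ds)
        self.rules_ = lem2(ds, self.cuts_, self.coverage_fraction)
        self.classes_ = np.asarray(ds.decision_domain)
        self.feature_names_ = ds.attributes
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.asarray(
            [
                classify(self.rules_, dict(zip(self.feature_names_, row)))
                for row in X
            ],
            dtype=object,
        )

    def score(self, X, y) -> float:
        """Accuracy counting uncovered cases as errors."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))


class C45DecisionTreeClassifier(_RuleClassifierBase):
    """Entropy-based binary decision tree with observed-value thresholds.

    Fitted attributes: ``tree_`` and ``rules_`` (one rule per leaf).
    """

    _param_names = ("min_leaf", "feature_names")

    def __init__(self, min_leaf: int = 2, feature_names=None):
        self.min_leaf = min_leaf
        self.feature_names = feature_names

    def fit(self, X, y) -> "C45DecisionTreeClassifier":
        ds = self._build_ds(X, y)
        self.decision_system_ = ds
        self.tree_ = c45_tree(ds, self.min_leaf)
        self.rules_ = tree_to_rules(self.tree_)
        self.classes_ = np.asarray(ds.decision_domain)
        self.feature_names_ = ds.attributes
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.asarray(
            [
                self.tree_.predict_one(dict(zip(self.feature_names_, row)))
                for row in X
            ],
            dtype=object,
        )

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))
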
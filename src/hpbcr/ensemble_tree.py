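"""Entropy decision trees (C4.5 style) and a 10-tree bagged ensemble.

The tree splits on gain ratio, handles interval features by threshold
(midpoints between sorted distinct values, restricted to candidates
with at least average information gain) and categorical features by
multiway split, and is pruned bottom-up with the pessimistic
(confidence-bound) error estimate at the C4.5 default confidence 0.25.

Feature importances enter through a :class:`FeatureTransform`: a binary
inclusion mask over categorical features and a weight in [0, 1] per
interval feature. A weight multiplies the feature's split *score*
(weight x gain ratio), never its values — a monotone value rescaling
cannot alter an order-based tree, so down-weighting must act in the
split competition. Weight 0 is exactly feature removal.

The ensemble is plain Breiman bagging: 10 bootstrap resamples of size n
with replacement, one grown-and-pruned tree each, unweighted majority
vote with ties resolved to the positive (recurrence) class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from scipy.stats import norm

from .cohort import CohortTable

__all__ = [
    "FeatureTransform",
    "EncodedMatrix",
    "TreeNode",
    "BaggedTreeModel",
    "entropy",
    "best_split",
    "grow_tree",
    "prune_tree",
    "bagged_fit",
    "bagged_predict",
    "encode_cohort",
    "rules_text",
]

DEFAULT_N_TREES = 10
DEFAULT_MIN_LEAF = 2
DEFAULT_PRUNE_CONFIDENCE = 0.25
_GAIN_EPS = 1e-12


@dataclass
class FeatureTransform:
    """PSO-optimizable inclusion mask + interval feature weights."""

    categorical_names: list
    interval_names: list
    categorical_mask: np.ndarray
    interval_weights: np.ndarray

    def __post_init__(self) -> None:
        self.categorical_mask = np.asarray(self.categorical_mask, dtype=bool)
        self.interval_weights = np.asarray(self.interval_weights, dtype=float)
        if len(self.categorical_mask) != len(self.categorical_names):
            raise ValueError("mask length mismatch")
        if len(self.interval_weights) != len(self.interval_names):
            raise ValueError("weight length mismatch")
        if ((self.interval_weights < 0) | (self.interval_weights > 1)).any():
            raise ValueError("interval weights must lie in [0, 1]")

    @classmethod
    def full(cls, categorical_names, interval_names) -> "FeatureTransform":
        """All categorical features included, all weights 1."""
        return cls(list(categorical_names), list(interval_names),
                   np.ones(len(categorical_names), dtype=bool),
                   np.ones(len(interval_names)))

    @property
    def is_degenerate(self) -> bool:
        return not (self.categorical_mask.any() or (self.interval_weights > 0).any())

    def active_features(self) -> list:
        out = [n for n, m in zip(self.categorical_names, self.categorical_mask) if m]
        out += [n for n, w in zip(self.interval_names, self.interval_weights) if w > 0]
        return out

    def to_dict(self) -> dict:
        return {
            "categorical": {n: bool(m) for n, m in
                            zip(self.categorical_names, self.categorical_mask)},
            "interval_weights": {n: float(w) for n, w in
                                 zip(self.interval_names, self.interval_weights)},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureTransform":
        cat = doc["categorical"]
        wts = doc["interval_weights"]
        return cls(list(cat), list(wts),
                   np.array([cat[k] for k in cat], dtype=bool),
                   np.array([wts[k] for k in wts], dtype=float))


@dataclass
class EncodedMatrix:
    """Numeric view of a cohort for tree fitting.

    Interval features as a float matrix, categorical features as integer
    codes into each feature's category list.
    """

    x_num: np.ndarray          # (n, p_num) float
    x_cat: np.ndarray          # (n, p_cat) int
    y: np.ndarray              # (n,) 0/1
    num_names: list
    cat_names: list
    cat_categories: list       # list of category-label lists, per cat feature

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "EncodedMatrix":
        idx = np.asarray(idx)
        return EncodedMatrix(self.x_num[idx], self.x_cat[idx], self.y[idx],
                             self.num_names, self.cat_names, self.cat_categories)


def encode_cohort(cohort: CohortTable, categorical_names, interval_names) -> EncodedMatrix:
    n = cohort.n
    x_num = np.empty((n, len(interval_names)), dtype=float)
    for j, name in enumerate(interval_names):
        x_num[:, j] = cohort.df[name].to_numpy(dtype=float)
    x_cat = np.empty((n, len(categorical_names)), dtype=np.int64)
    cat_categories = []
    for j, name in enumerate(categorical_names):
        spec = cohort.spec(name)
        cats = list(spec.categories)
        cat_categories.append(cats)
        lut = {c: i for i, c in enumerate(cats)}
        x_cat[:, j] = [lut[str(v)] for v in cohort.df[name]]
    return EncodedMatrix(x_num, x_cat, cohort.outcome.astype(int),
                         list(interval_names), list(categorical_names),
                         cat_categories)


def entropy(class_counts) -> float:
    """Shannon entropy in bits of a two-class count pair."""
    c = np.asarray(class_counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total < 1:
        raise ValueError("empty node has no entropy")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum()) + 0.0


_LN2 = math.log(2.0)


def _entropy_counts(n1, n):
    """n * H(n1/n) in bits, elementwise from counts (0 log 0 = 0)."""
    n1 = np.asarray(n1, dtype=float)
    n = np.asarray(n, dtype=float)
    return (xlogy(n, n) - xlogy(n1, n1) - xlogy(n - n1, n - n1)) / _LN2


@dataclass
class Split:
    feature: str
    kind: str                   # 'numeric' | 'categorical'
    score: float                # weight x gain ratio
    gain_ratio: float
    gain: float
    threshold: float = math.nan
    categories: list = field(default_factory=list)  # codes, categorical only
    column: int = -1


def _best_numeric_split(v: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best threshold by gain ratio among candidates with >= mean gain."""
    n = len(y)
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    cum1 = np.cumsum(ys)
    tot1 = cum1[-1]
    left_n = np.arange(1, n, dtype=float)
    left1 = cum1[:-1].astype(float)
    ok = (vs[1:] != vs[:-1]) & (left_n >= min_leaf) & (n - left_n >= min_leaf)
    if not ok.any():
        return None
    h0 = _entropy_counts(tot1, n)  # n * H(root)
    gain = (h0 - _entropy_counts(left1, left_n)
            - _entropy_counts(tot1 - left1, n - left_n)) / n
    gain = np.where(ok, gain, -np.inf)
    mean_gain = gain[ok].mean()
    cand = ok & (gain >= mean_gain - _GAIN_EPS) & (gain > _GAIN_EPS)
    if not cand.any():
        return None
    split_info = _entropy_counts(left_n, float(n)) / n
    ratio = np.where(cand & (split_info > _GAIN_EPS), gain / split_info, -np.inf)
    j = int(np.argmax(ratio))
    if not np.isfinite(ratio[j]):
        return None
    thr = 0.5 * (vs[j] + vs[j + 1])
    return float(thr), float(ratio[j]), float(gain[j])


def _best_categorical_split(codes: np.ndarray, y: np.ndarray, n_categories: int):
    """Multiway split on the observed categories."""
    n = len(y)
    nk = np.bincount(codes, minlength=n_categories).astype(float)
    nk1 = np.bincount(codes, weights=y, minlength=n_categories)
    present = nk > 0
    if present.sum() < 2:
        return None
    nk, nk1 = nk[present], nk1[present]
    gain = (_entropy_counts(y.sum(), n) - _entropy_counts(nk1, nk).sum()) / n
    if gain <= _GAIN_EPS:
        return None
    p = nk / n
    split_info = float(-(p * np.log2(p)).sum())
    if split_info <= _GAIN_EPS:
        return None
    cats = [int(c) for c in np.flatnonzero(present)]
    return cats, gain / split_info, gain


def best_split(enc: EncodedMatrix, transform: FeatureTransform,
               min_leaf: int = DEFAULT_MIN_LEAF) -> Split | None:
    """Highest weighted-score split over all admissible features.

    Ties break toward the earlier feature (categorical block first),
    keeping growth deterministic.
    """
    best: Split | None = None
    y = enc.y
    n1 = int(y.sum())
    if n1 == 0 or n1 == enc.n or enc.n < 2:
        return None
    for j, name in enumerate(enc.cat_names):
        if not transform.categorical_mask[j]:
            continue
        res = _best_categorical_split(enc.x_cat[:, j], y, len(enc.cat_categories[j]))
        if res is None:
            continue
        cats, ratio, gain = res
        score = ratio  # mask passed -> weight 1
        if best is None or score > best.score + _GAIN_EPS:
            best = Split(feature=name, kind="categorical", score=score,
                         gain_ratio=ratio, gain=gain, categories=cats, column=j)
    for j, name in enumerate(enc.num_names):
        w = transform.interval_weights[j]
        if w <= 0:
            continue
        res = _best_numeric_split(enc.x_num[:, j], y, min_leaf)
        if res is None:
            continue
        thr, ratio, gain = res
        score = w * ratio
        if best is None or score > best.score + _GAIN_EPS:
            best = Split(feature=name, kind="numeric", score=score,
                         gain_ratio=ratio, gain=gain, threshold=thr, column=j)
    return best


@dataclass
class TreeNode:
    """Internal node or leaf of a fitted tree."""

    class_counts: tuple                 # (n_class0, n_class1) training counts
    kind: str = "leaf"                  # 'leaf' | 'internal'
    feature: str | None = None
    split_kind: str | None = None       # 'numeric' | 'categorical'
    column: int = -1
    threshold: float = math.nan
    categories: list = field(default_factory=list)  # child codes, categorical
    children: list = field(default_factory=list)

    @property
    def predicted_class(self) -> int:
        c0, c1 = self.class_counts
        return 1 if c1 >= c0 else 0

    @property
    def n(self) -> int:
        return int(sum(self.class_counts))

    def node_count(self) -> int:
        return 1 + sum(ch.node_count() for ch in self.children)

    def to_dict(self) -> dict:
        doc = {"class_counts": list(self.class_counts), "kind": self.kind}
        if self.kind == "internal":
            doc.update(feature=self.feature, split_kind=self.split_kind,
                       column=self.column, categories=list(self.categories),
                       children=[c.to_dict() for c in self.children])
            if self.split_kind == "numeric":
                doc["threshold"] = self.threshold
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "TreeNode":
        node = cls(class_counts=tuple(doc["class_counts"]), kind=doc["kind"])
        if doc["kind"] == "internal":
            node.feature = doc["feature"]
            node.split_kind = doc["split_kind"]
            node.column = doc["column"]
            node.categories = list(doc.get("categories", []))
            node.threshold = doc.get("threshold", math.nan)
            node.children = [cls.from_dict(c) for c in doc["children"]]
        return node


def _counts(y: np.ndarray) -> tuple:
    c1 = int(y.sum())
    return (len(y) - c1, c1)


def grow_tree(enc: EncodedMatrix, transform: FeatureTransform,
              min_leaf: int = DEFAULT_MIN_LEAF) -> TreeNode:
    """Recursive greedy growth on the weighted gain-ratio score.

    Stops on purity, when no split has positive score, or when the node
    holds fewer than ``2 * min_leaf`` rows (no admissible child).
    """
    if enc.n < 1:
        raise ValueError("cannot grow a tree on zero rows")
    node = TreeNode(class_counts=_counts(enc.y))
    if node.class_counts[0] == 0 or node.class_counts[1] == 0:
        return node
    if enc.n < 2 * min_leaf:
        return node
    split = best_split(enc, transform, min_leaf)
    if split is None or split.score <= _GAIN_EPS:
        return node
    if split.kind == "numeric":
        mask = enc.x_num[:, split.column] <= split.threshold
        parts = [np.flatnonzero(mask), np.flatnonzero(~mask)]
        cats: list = []
    else:
        codes = enc.x_cat[:, split.column]
        cats = split.categories
        parts = [np.flatnonzero(codes == c) for c in cats]
    if any(len(p) == 0 for p in parts):
        return node
    node.kind = "internal"
    node.feature = split.feature
    node.split_kind = split.kind
    node.column = split.column
    node.threshold = split.threshold
    node.categories = list(cats)
    node.children = [grow_tree(enc.subset(p), transform, min_leaf) for p in parts]
    return node


def _pessimistic_errors(err: float, n: float, z: float) -> float:
    """C4.5 upper-confidence-bound estimate of the error *count* at a leaf."""
    if n <= 0:
        return 0.0
    f = err / n
    z2 = z * z
    ucb = (f + z2 / (2 * n) + z * math.sqrt(f / n - f * f / n + z2 / (4 * n * n)))
    ucb /= 1 + z2 / n
    return n * ucb


def prune_tree(root: TreeNode, confidence: float = DEFAULT_PRUNE_CONFIDENCE) -> TreeNode:
    """Bottom-up pessimistic-error pruning (in place; root returned).

    A subtree collapses to a leaf when the leaf's upper-bound error
    estimate does not exceed the sum of its children's. Node count never
    increases.
    """
    z = float(norm.ppf(1.0 - confidence))

    def walk(node: TreeNode) -> float:
        n = node.n
        leaf_err = _pessimistic_errors(n - max(node.class_counts), n, z)
        if node.kind == "leaf":
            return leaf_err
        subtree_err = sum(walk(ch) for ch in node.children)
        if leaf_err <= subtree_err + 1e-12:
            node.kind = "leaf"
            node.children = []
            node.feature = None
            node.split_kind = None
            node.categories = []
            node.threshold = math.nan
            return leaf_err
        return subtree_err

    walk(root)
    return root


def _predict_one(node: TreeNode, x_num: np.ndarray, x_cat: np.ndarray) -> int:
    while node.kind == "internal":
        if node.split_kind == "numeric":
            node = node.children[0 if x_num[node.column] <= node.threshold else 1]
        else:
            code = x_cat[node.column]
            if code in node.categories:
                node = node.children[node.categories.index(code)]
            else:
                # unseen category: follow the heaviest-trained child
                node = max(node.children, key=lambda c: c.n)
    return node.predicted_class


def tree_predict(root: TreeNode, enc: EncodedMatrix) -> np.ndarray:
    return np.array([_predict_one(root, enc.x_num[i], enc.x_cat[i])
                     for i in range(enc.n)], dtype=int)


@dataclass
class BaggedTreeModel:
    """Bootstrap-aggregated pruned entropy trees with majority vote."""

    trees: list
    bootstrap_seeds: list
    transform: FeatureTransform
    num_names: list
    cat_names: list
    cat_categories: list
    oob_indices: list = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_json(self, **kwargs) -> str:
        doc = {
            "trees": [t.to_dict() for t in self.trees],
            "bootstrap_seeds": [int(s) for s in self.bootstrap_seeds],
            "transform": self.transform.to_dict(),
            "num_names": self.num_names,
            "cat_names": self.cat_names,
            "cat_categories": self.cat_categories,
        }
        return json.dumps(doc, sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "BaggedTreeModel":
        doc = json.loads(text)
        return cls(trees=[TreeNode.from_dict(t) for t in doc["trees"]],
                   bootstrap_seeds=doc["bootstrap_seeds"],
                   transform=FeatureTransform.from_dict(doc["transform"]),
                   num_names=doc["num_names"], cat_names=doc["cat_names"],
                   cat_categories=doc["cat_categories"])


def bagged_fit(enc: EncodedMatrix, transform: FeatureTransform,
               n_trees: int = DEFAULT_N_TREES, seed: int = 0,
               min_leaf: int = DEFAULT_MIN_LEAF,
               keep_oob: bool = False) -> BaggedTreeModel:
    """Fit ``n_trees`` grown-and-pruned trees on bootstrap resamples."""
    if enc.n < 10:
        raise ValueError("need at least 10 training rows")
    if len(np.unique(enc.y)) < 2:
        raise ValueError("training data must contain both classes")
    if transform.is_degenerate:
        raise ValueError("degenerate transform: no active feature")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    trees, oob = [], []
    for s in seeds:
        boot_rng = np.random.default_rng(int(s))
        idx = boot_rng.integers(0, enc.n, size=enc.n)
        sub = enc.subset(idx)
        if len(np.unique(sub.y)) < 2:  # resample a single-class bootstrap
            idx = boot_rng.integers(0, enc.n, size=enc.n)
            sub = enc.subset(idx)
        tree = prune_tree(grow_tree(sub, transform, min_leaf))
        trees.append(tree)
        if keep_oob:
            oob.append(np.setdiff1d(np.arange(enc.n), idx))
    return BaggedTreeModel(trees=trees, bootstrap_seeds=[int(s) for s in seeds],
                           transform=transform, num_names=list(enc.num_names),
                           cat_names=list(enc.cat_names),
                           cat_categories=list(enc.cat_categories),
                           oob_indices=oob)


def bagged_predict(model: BaggedTreeModel, enc: EncodedMatrix) -> np.ndarray:
    """Unweighted majority vote; a tie predicts recurrence (class 1)."""
    votes = np.zeros(enc.n, dtype=int)
    for tree in model.trees:
        votes += tree_predict(tree, enc)
    return (2 * votes >= model.n_trees).astype(int)


def oob_predict(model: BaggedTreeModel, enc: EncodedMatrix) -> np.ndarray:
    """Out-of-bag majority vote; rows in every bag fall back to the full vote."""
    if not model.oob_indices:
        raise ValueError("model was fitted without keep_oob=True")
    votes = np.zeros(enc.n, dtype=float)
    counts = np.zeros(enc.n, dtype=int)
    for tree, oob in zip(model.trees, model.oob_indices):
        if len(oob) == 0:
            continue
        pred = tree_predict(tree, enc.subset(oob))
        votes[oob] += pred
        counts[oob] += 1
    full = bagged_predict(model, enc)
    out = np.where(counts > 0, (2 * votes >= counts).astype(int), full)
    return out.astype(int)


def _rule_lines(node: TreeNode, model: BaggedTreeModel, conds: list, out: list) -> None:
    if node.kind == "leaf":
        label = "recurrence" if node.predicted_class == 1 else "no recurrence"
        body = " AND ".join(conds) if conds else "TRUE"
        c0, c1 = node.class_counts
        out.append(f"IF {body} THEN {label}  [{c1}+/{c0}-]")
        return
    if node.split_kind == "numeric":
        name = model.num_names[node.column]
        branches = [(f"{name} <= {node.threshold:g}", node.children[0]),
                    (f"{name} > {node.threshold:g}", node.children[1])]
    else:
        name = model.cat_names[node.column]
        cats = model.cat_categories[node.column]
        branches = [(f"{name} = {cats[c]}", ch)
                    for c, ch in zip(node.categories, node.children)]
    for cond, child in branches:
        _rule_lines(child, model, conds + [cond], out)


def rules_text(model: BaggedTreeModel) -> str:
    """Human-readable if/then rules, one block per bagged tree."""
    blocks = []
    for t, tree in enumerate(model.trees):
        lines: list = []
        _rule_lines(tree, model, [], lines)
        blocks.append(f"# Tree {t + 1}\n" + "\n".join(lines))
    return "\n\n".join(blocks)
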
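"""Cost-sensitive random forest for somatic-variant classification.

The ensemble is a bagged collection of unpruned entropy-split decision
trees.  Class imbalance is handled by cost-sensitive instance weights: each
tree is grown on a bootstrap sample of the training set drawn with
replacement with probability proportional to instance weight, so upweighted
(typically false-positive) instances dominate the resamples.  At each node,
floor(log2(M)) + 1 of the M usable features are candidate split attributes.
The out-of-bag (oob) error — the majority-vote error over trees whose
bootstrap excluded each instance — is recorded as an internal estimate of
generalization error.

Feature relevance is measured by information gain (class-entropy reduction
under an IG-maximizing binary threshold for continuous features); features
are ranked by IG and the model can optionally be restricted to the top-k.

Class labels are the strings ``"TP"`` (true somatic variant) and ``"FP"``
(sequencing-error artifact).  Prediction is by majority vote; the reported
class probability is the vote fraction of the winning class, hence always in
[0.5, 1], and exact ties resolve conservatively to FP.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, BackgroundMedians

LABELS = ("FP", "TP")  # index = numeric class code


@dataclass
class TrainingInstance:
    """One labeled candidate: its feature vector, class and weight."""

    features: dict[str, float]
    label: str  # "TP" or "FP"
    weight: float = 1.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be 'TP' or 'FP', got {self.label!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class Prediction:
    label: str
    probability: float  # vote fraction for the assigned label, in [0.5, 1]


@dataclass
class ForestModel:
    """A trained ensemble plus the metadata needed to reapply it.

    Trees are stored as flat node arrays (children, split feature index into
    ``selected_features``, threshold, leaf class) so that a saved and a
    freshly trained model predict through the identical code path.
    """

    trees: list[dict[str, np.ndarray]]
    n_trees: int
    features_per_node: int
    selected_features: list[str]
    feature_ig: dict[str, float]
    oob_error: float
    seed: int
    class_costs: tuple[float, float]  # (cost_fp, cost_fn)
    background: BackgroundMedians | None = None

    FORMAT_VERSION = 1

    # -- prediction --------------------------------------------------------

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting TP for each row of X
        (columns ordered as ``selected_features``)."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        votes = np.zeros(len(X), dtype=np.int64)
        for tree in self.trees:
            votes += _tree_apply(tree, X)
        return votes / len(self.trees)

    def save(self, path) -> None:
        """Persist as a versioned, self-describing JSON archive."""
        doc = {
            "format": "snvforest-model",
            "version": self.FORMAT_VERSION,
            "n_trees": self.n_trees,
            "features_per_node": self.features_per_node,
            "selected_features": self.selected_features,
            "feature_ig": {k: self.feature_ig[k] for k in sorted(self.feature_ig)},
            "oob_error": self.oob_error,
            "seed": self.seed,
            "class_costs": list(self.class_costs),
            "background": None if self.background is None else {
                "medians": {k: self.background.medians[k]
                            for k in sorted(self.background.medians)},
                "n_positions": self.background.n_positions,
                "seed": self.background.seed,
            },
            "trees": [{k: v.tolist() for k, v in tree.items()}
                      for tree in self.trees],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True, separators=(",", ":"))

    @classmethod
    def load(cls, path) -> "ForestModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "snvforest-model":
            raise ValueError(f"{path} is not a snvforest model archive")
        if doc.get("version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('version')}")
        trees = []
        for t in doc["trees"]:
            trees.append({
                "left": np.asarray(t["left"], dtype=np.int64),
                "right": np.asarray(t["right"], dtype=np.int64),
                "feature": np.asarray(t["feature"], dtype=np.int64),
                "threshold": np.asarray(t["threshold"], dtype=np.float64),
                "klass": np.asarray(t["klass"], dtype=np.int64),
            })
        bg = doc.get("background")
        background = None if bg is None else BackgroundMedians(
            bg["medians"], bg["n_positions"], bg["seed"])
        return cls(trees=trees, n_trees=doc["n_trees"],
                   features_per_node=doc["features_per_node"],
                   selected_features=list(doc["selected_features"]),
                   feature_ig=dict(doc["feature_ig"]),
                   oob_error=doc["oob_error"], seed=doc["seed"],
                   class_costs=tuple(doc["class_costs"]),
                   background=background)


def _tree_apply(tree: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Vectorized descent of one flat tree; returns the leaf class code per row."""
    nodes = np.zeros(len(X), dtype=np.int64)
    left, right = tree["left"], tree["right"]
    feature, threshold = tree["feature"], tree["threshold"]
    while True:
        l = left[nodes]
        internal = l >= 0
        if not internal.any():
            break
        idx = np.flatnonzero(internal)
        sub = nodes[idx]
        go_left = X[idx, feature[sub]] <= threshold[sub]
        nodes[idx] = np.where(go_left, left[sub], right[sub])
    return tree["klass"][nodes]


# ---------------------------------------------------------------------------
# Information gain


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(feature_values: Sequence[float],
                     labels: Sequence[int] | Sequence[str],
                     weights: Sequence[float] | None = None) -> float:
    """Information gain of a feature with respect to the class, in bits.

    Continuous features are discretized by the IG-maximizing binary
    threshold (midpoints between consecutive distinct sorted values); the
    returned value is H(labels) - H(labels | split), which is non-negative
    and bounded by H(labels).  A constant feature or single-class labels
    give exactly 0.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    y = _encode_labels(labels)
    if len(x) != len(y):
        raise ValueError("feature_values and labels must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 instances")
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=np.float64)

    order = np.argsort(x, kind="mergesort")
    xs, ys, ws = x[order], y[order], w[order]
    total_pos = float(ws[ys == 1].sum())
    total = float(ws.sum())
    h_root = _entropy(np.array([total - total_pos, total_pos]))
    if h_root == 0.0:
        return 0.0

    # prefix weights of each class along the sorted order
    cum_w = np.cumsum(ws)
    cum_pos = np.cumsum(ws * ys)
    # candidate cut after index i wherever the value changes
    change = np.flatnonzero(np.diff(xs) > 0)
    if change.size == 0:
        return 0.0  # constant feature
    wl = cum_w[change]
    pl = cum_pos[change]
    h_left = _entropy_vec(wl - pl, pl)
    h_right = _entropy_vec((total - wl) - (total_pos - pl), total_pos - pl)
    cond = (wl / total) * h_left + ((total - wl) / total) * h_right
    return float(max(0.0, h_root - cond.min()))


def _entropy_vec(neg: np.ndarray, pos: np.ndarray) -> np.ndarray:
    tot = neg + pos
    with np.errstate(divide="ignore", invalid="ignore"):
        pn = np.where(tot > 0, neg / np.maximum(tot, 1e-300), 0.0)
        pp = np.where(tot > 0, pos / np.maximum(tot, 1e-300), 0.0)
        h = -(np.where(pn > 0, pn * np.log2(pn), 0.0)
              + np.where(pp > 0, pp * np.log2(pp), 0.0))
    return h


def _encode_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return np.array([1 if l == "TP" else 0 for l in arr], dtype=np.int64)
    return arr.astype(np.int64)


def rank_features(instances: Sequence[TrainingInstance],
                  feature_names: Sequence[str] | None = None,
                  top_k: int | None = None) -> list[tuple[str, float]]:
    """Rank features by information gain, descending; ties break by name."""
    X, y, w, names = _to_arrays(instances, feature_names)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking requires both classes")
    scored = [(name, information_gain(X[:, j], y, w))
              for j, name in enumerate(names)]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_k] if top_k else scored


# ---------------------------------------------------------------------------
# Training-set transforms


def apply_costs(instances: Iterable[TrainingInstance],
                cost_fp: float, cost_fn: float) -> list[TrainingInstance]:
    """Scale FP-class weights by ``cost_fp`` and TP-class weights by
    ``cost_fn`` (the cost of misclassifying each class)."""
    if cost_fp <= 0 or cost_fn <= 0:
        raise ValueError("costs must be positive")
    return [TrainingInstance(i.features, i.label,
                             i.weight * (cost_fp if i.label == "FP" else cost_fn))
            for i in instances]


def filter_vaf_interval(instances: Sequence[TrainingInstance],
                        lo: float, hi: float) -> list[TrainingInstance]:
    """Keep instances whose tumor VAF feature lies in [lo, hi]."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("require 0 <= lo < hi <= 1")
    kept = [i for i in instances if lo <= i.features["tumor_vaf"] <= hi]
    if not kept:
        raise ValueError(
            f"no instances with tumor VAF in [{lo}, {hi}]; widen the interval")
    return kept


def _to_arrays(instances: Sequence[TrainingInstance],
               feature_names: Sequence[str] | None = None):
    names = list(feature_names) if feature_names else [
        n for n in FEATURE_NAMES if n in instances[0].features]
    if not names:
        names = sorted(instances[0].features)
    X = np.empty((len(instances), len(names)), dtype=np.float64)
    y = np.empty(len(instances), dtype=np.int64)
    w = np.empty(len(instances), dtype=np.float64)
    for i, inst in enumerate(instances):
        try:
            X[i] = [inst.features[n] for n in names]
        except KeyError as e:
            raise KeyError(f"instance {i} is missing feature {e.args[0]!r}") from None
        y[i] = 1 if inst.label == "TP" else 0
        w[i] = inst.weight
    return X, y, w, names


def features_per_node(n_features: int) -> int:
    """floor(log2(M)) + 1 candidate split attributes per node."""
    return int(math.floor(math.log2(n_features))) + 1


# ---------------------------------------------------------------------------
# Training, prediction, cross-validation


def train_forest(instances: Sequence[TrainingInstance],
                 n_trees: int = 300, seed: int = 0,
                 costs: tuple[float, float] = (1.0, 1.0),
                 top_k: int | None = None,
                 background: BackgroundMedians | None = None) -> ForestModel:
    """Grow the cost-sensitive bagged ensemble.

    ``costs`` = (cost_fp, cost_fn) multiplies the per-class instance weights
    before the weighted bootstrap, so the resamples each tree sees reflect
    the asymmetric misclassification costs.  Deterministic given identical
    instances, seed and hyperparameters.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(instances) < 10:
        raise ValueError("need at least 10 training instances")
    weighted = apply_costs(instances, *costs)
    X_all, y, w, names = _to_arrays(weighted)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both TP and FP instances")

    ranked = rank_features(weighted, feature_names=names, top_k=top_k)
    selected = [name for name, _ in ranked]
    ig_scores = {name: ig for name, ig in ranked}
    sel_idx = [names.index(name) for name in selected]
    X = np.ascontiguousarray(X_all[:, sel_idx])

    m = len(selected)
    k = features_per_node(m)
    n = len(X)
    p = w / w.sum()

    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)

    trees: list[dict[str, np.ndarray]] = []
    oob_votes = np.zeros((n, 2), dtype=np.int64)
    for t in range(n_trees):
        trng = np.random.default_rng(int(tree_seeds[t]))
        idx = trng.choice(n, size=n, replace=True, p=p)
        counts = np.bincount(idx, minlength=n)
        in_bag = counts > 0
        clf = DecisionTreeClassifier(criterion="entropy", max_features=k,
                                     random_state=int(tree_seeds[t]))
        clf.fit(X[in_bag], y[in_bag], sample_weight=counts[in_bag].astype(np.float64))
        tree = _flatten_sklearn_tree(clf)
        trees.append(tree)
        oob = ~in_bag
        if oob.any():
            pred = _tree_apply(tree, X[oob])
            oob_votes[np.flatnonzero(oob), pred] += 1

    covered = oob_votes.sum(axis=1) > 0
    if covered.any():
        # ties count as errors for TP instances (tie resolves to FP)
        oob_pred = (oob_votes[covered, 1] > oob_votes[covered, 0]).astype(np.int64)
        oob_error = float(np.mean(oob_pred != y[covered]))
    else:
        oob_error = float("nan")

    return ForestModel(trees=trees, n_trees=n_trees, features_per_node=k,
                       selected_features=selected, feature_ig=ig_scores,
                       oob_error=oob_error, seed=seed, class_costs=tuple(costs),
                       background=background)


def _flatten_sklearn_tree(clf: DecisionTreeClassifier) -> dict[str, np.ndarray]:
    t = clf.tree_
    value = t.value.reshape(t.node_count, -1)
    if value.shape[1] == 1:
        # single-class bootstrap cannot happen (both classes enforced), but
        # guard: map to the only class present
        klass = np.full(t.node_count, int(clf.classes_[0]), dtype=np.int64)
    else:
        # ties inside an impure leaf resolve to FP (class 0)
        klass_local = (value[:, 1] > value[:, 0]).astype(np.int64)
        klass = np.asarray(clf.classes_, dtype=np.int64)[klass_local]
    return {
        "left": t.children_left.astype(np.int64),
        "right": t.children_right.astype(np.int64),
        "feature": np.maximum(t.feature, 0).astype(np.int64),
        "threshold": t.threshold.astype(np.float64),
        "klass": klass,
    }


def predict(model: ForestModel, fv: dict[str, float]) -> Prediction:
    """Classify one feature vector by majority vote.

    The probability is the vote fraction of the winning class (in [0.5, 1]);
    an exact 50/50 split resolves to FP.  A feature missing from ``fv``
    raises ``KeyError`` naming it.
    """
    row = np.empty((1, len(model.selected_features)))
    for j, name in enumerate(model.selected_features):
        if name not in fv:
            raise KeyError(f"feature vector is missing feature {name!r}")
        row[0, j] = fv[name]
    frac_tp = float(model.vote_fractions(row)[0])
    if frac_tp > 0.5:
        return Prediction("TP", frac_tp)
    return Prediction("FP", 1.0 - frac_tp)


def predict_batch(model: ForestModel,
                  fvs: Sequence[dict[str, float]]) -> tuple[list[str], np.ndarray]:
    """Vectorized prediction; returns (labels, TP vote fractions)."""
    X = np.empty((len(fvs), len(model.selected_features)))
    for i, fv in enumerate(fvs):
        for j, name in enumerate(model.selected_features):
            if name not in fv:
                raise KeyError(f"feature vector {i} is missing feature {name!r}")
            X[i, j] = fv[name]
    frac = model.vote_fractions(X)
    labels = ["TP" if f > 0.5 else "FP" for f in frac]
    return labels, frac


def cross_validate(instances: Sequence[TrainingInstance], k: int = 10,
                   seed: int = 0, n_trees: int = 300,
                   costs: tuple[float, float] = (1.0, 1.0),
                   top_k: int | None = None):
    """Stratified k-fold cross-validation of the forest.

    Pools the out-of-fold TP vote fractions over all folds and summarises
    them through :func:`snvforest.evaluation.roc_pr_curves`.  Deterministic
    given the seed.
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import roc_pr_curves

    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.array([1 if i.label == "TP" else 0 for i in instances])
    minority = int(min((y == 1).sum(), (y == 0).sum()))
    if k > minority:
        raise ValueError(
            f"k={k} exceeds the minority class count ({minority})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(instances))
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        fold_model = train_forest([instances[i] for i in train_idx],
                                  n_trees=n_trees, seed=seed, costs=costs,
                                  top_k=top_k)
        _, frac = predict_batch(fold_model,
                                [instances[i].features for i in test_idx])
        scores[test_idx] = frac
    return roc_pr_curves(scores, y)
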
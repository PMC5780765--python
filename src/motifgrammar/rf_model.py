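"""Multi-class random forest on motif counts, with out-of-bag (OOB) error,
scaled permutation importance (mean decrease accuracy, MDA) and the
two-round training procedure (negative-MDA feature removal, then a small
grid over the per-split feature count minimising OOB error).

The forest follows the classical classification recipe: each of the
(default 500) trees is grown on a bootstrap sample of size n, every split
considers a fresh random subset of features, splits maximise the Gini
impurity decrease, and trees are grown to purity with minimum node size 1.
Aggregation is by majority vote; the fraction of trees voting for each
class is the per-class score used downstream for one-vs-rest ROC analysis.

Trees are grown by a numba-compiled histogram splitter specialised to
small-integer count features: feature values are mapped once to dense codes
of their sorted unique values, so a node evaluates every possible threshold
of a candidate feature from one class-histogram pass.  Split thresholds are
recorded as midpoints between the adjacent observed values in the node, so
a split on a count feature always falls strictly between two attainable
counts.  Each tree records its bootstrap and OOB sample indices, and its
split paths (feature, threshold, children, leaf class counts) are plain
arrays that rule mining can walk directly.

Importance follows the permutation (MDA) definition: for every tree, the
accuracy on that tree's OOB samples is measured before and after permuting
one feature's values among those samples; the raw MDA of a feature is the
mean accuracy drop over all trees (trees not using the feature contribute a
drop of 0).  Raw MDAs are then scaled by the standard deviation of the MDA
values of all features, giving the "scaled MDA" on which the reporting
threshold of 6 operates.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .motif_scanner import MotifCountMatrix

log = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
#: scaled-MDA reporting threshold for the cell-type specific motif shortlist
MDA_SHORTLIST_THRESHOLD = 6.0

__all__ = [
    "ForestModel",
    "ImportanceTable",
    "train_forest",
    "oob_error",
    "permutation_importance",
    "two_round_train",
    "class_vote_scores",
    "predict_classes",
    "DEFAULT_N_TREES",
    "MDA_SHORTLIST_THRESHOLD",
]


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _grow_tree(codes, y, n_classes, boot, mtry, nbins, seed):
    """Grow one Gini decision tree to purity on bootstrap sample ``boot``.

    ``codes[i, f]`` is the dense code of sample i's value of feature f
    (code order = value order).  Returns parallel node arrays; leaves have
    feature == -1.  ``c_lo``/``c_hi`` are the codes adjacent to the split:
    samples with code <= c_lo go left, the node's smallest right-side code
    is c_hi.
    """
    np.random.seed(seed)
    n = boot.size
    p = codes.shape[1]
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int32)
    c_lo = np.zeros(max_nodes, np.int32)
    c_hi = np.zeros(max_nodes, np.int32)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    value = np.zeros((max_nodes, n_classes), np.float64)

    idx = boot.copy()
    stack_node = np.empty(max_nodes, np.int32)
    stack_s = np.empty(max_nodes, np.int32)
    stack_e = np.empty(max_nodes, np.int32)
    top = 0
    stack_node[top] = 0
    stack_s[top] = 0
    stack_e[top] = n
    top += 1
    node_count = 1

    max_bins = 0
    for f in range(p):
        if nbins[f] > max_bins:
            max_bins = nbins[f]
    hist = np.zeros((max_bins, n_classes), np.float64)
    lbuf = np.zeros(n_classes, np.float64)
    featbuf = np.empty(p, np.int32)

    while top > 0:
        top -= 1
        node = stack_node[top]
        s = stack_s[top]
        e = stack_e[top]
        n_node = e - s

        ncount = np.zeros(n_classes, np.float64)
        for i in range(s, e):
            ncount[y[idx[i]]] += 1.0
        value[node] = ncount

        nonzero = 0
        for c in range(n_classes):
            if ncount[c] > 0:
                nonzero += 1
        if nonzero <= 1 or n_node < 2:
            continue  # pure (or singleton) leaf

        parent_proxy = 0.0
        for c in range(n_classes):
            parent_proxy += ncount[c] * ncount[c]
        parent_proxy /= n_node

        best_gain = 1e-10  # require a strictly positive impurity decrease
        best_f = -1
        best_lo = -1
        best_hi = -1

        for j in range(p):
            featbuf[j] = j
        kmax = mtry if mtry < p else p
        for k in range(kmax):
            r = k + np.random.randint(0, p - k)
            f = featbuf[r]
            featbuf[r] = featbuf[k]
            featbuf[k] = f

            nb = nbins[f]
            for b in range(nb):
                for c in range(n_classes):
                    hist[b, c] = 0.0
            for i in range(s, e):
                hist[codes[idx[i], f], y[idx[i]]] += 1.0

            for c in range(n_classes):
                lbuf[c] = 0.0
            nl = 0.0
            prev = -1
            for b in range(nb):
                tot_b = 0.0
                for c in range(n_classes):
                    tot_b += hist[b, c]
                if tot_b == 0.0:
                    continue
                if prev >= 0:
                    # candidate split: codes <= prev vs >= b
                    nr = n_node - nl
                    lp = 0.0
                    rp = 0.0
                    for c in range(n_classes):
                        lc = lbuf[c]
                        rc = ncount[c] - lc
                        lp += lc * lc
                        rp += rc * rc
                    gain = lp / nl + rp / nr - parent_proxy
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_lo = prev
                        best_hi = b
                for c in range(n_classes):
                    lbuf[c] += hist[b, c]
                nl += tot_b
                prev = b

        if best_f < 0:
            continue  # no candidate feature splits this node: impure leaf

        i = s
        for t in range(s, e):
            if codes[idx[t], best_f] <= best_lo:
                tmp = idx[i]
                idx[i] = idx[t]
                idx[t] = tmp
                i += 1
        mid = i

        feature[node] = best_f
        c_lo[node] = best_lo
        c_hi[node] = best_hi
        left[node] = node_count
        right[node] = node_count + 1
        stack_node[top] = node_count
        stack_s[top] = s
        stack_e[top] = mid
        top += 1
        stack_node[top] = node_count + 1
        stack_s[top] = mid
        stack_e[top] = e
        top += 1
        node_count += 2

    return (
        feature[:node_count].copy(),
        c_lo[:node_count].copy(),
        c_hi[:node_count].copy(),
        left[:node_count].copy(),
        right[:node_count].copy(),
        value[:node_count].copy(),
    )


@njit(cache=True)
def _predict_tree(feature, threshold, left, right, leaf_class, X, out):
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = leaf_class[node]


@njit(cache=True)
def _tree_importance(feature, threshold, left, right, leaf_class,
                     Xoob, yoob, used, seed, drops):
    """Accumulate per-feature OOB accuracy drops for one tree into ``drops``.

    ``Xoob`` is a private copy (columns are permuted in place and restored).
    Features not used by the tree are skipped (permuting them cannot change
    any prediction, so their drop is exactly 0), and after a permutation
    only samples whose baseline decision path tested the permuted feature
    are re-walked — the rest keep their baseline prediction.
    """
    np.random.seed(seed)
    n, p = Xoob.shape
    if n == 0:
        return
    pred = np.empty(n, np.int32)
    touched = np.zeros((n, p), np.uint8)
    base = 0
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            f = feature[node]
            touched[i, f] = 1
            if Xoob[i, f] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        pred[i] = leaf_class[node]
        if pred[i] == yoob[i]:
            base += 1
    saved = np.empty(n, np.float64)
    for f in range(p):
        if used[f] == 0:
            continue
        perm = np.random.permutation(n)
        for i in range(n):
            saved[i] = Xoob[i, f]
        for i in range(n):
            Xoob[i, f] = saved[perm[i]]
        good = base
        for i in range(n):
            if touched[i, f] == 0:
                continue
            node = 0
            while feature[node] >= 0:
                if Xoob[i, feature[node]] <= threshold[node]:
                    node = left[node]
                else:
                    node = right[node]
            c = leaf_class[node]
            if c != pred[i]:
                if pred[i] == yoob[i]:
                    good -= 1
                elif c == yoob[i]:
                    good += 1
        drops[f] += (base - good) / n
        for i in range(n):
            Xoob[i, f] = saved[i]


# --------------------------------------------------------------------------
# model containers
# --------------------------------------------------------------------------

@dataclass
class Tree:
    """One decision tree as parallel node arrays (feature == -1 marks a leaf)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray  # per-node class counts (bootstrap sample)

    @property
    def leaf_class(self) -> np.ndarray:
        return np.argmax(self.value, axis=1).astype(np.int32)

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    def used_features(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])


@dataclass
class ForestModel:
    """A trained forest with per-tree bootstrap/OOB bookkeeping."""

    trees: list[Tree]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    feature_names: list[str]
    class_names: list[str]
    features_per_split: int
    seed: int
    n_training_samples: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # -- prediction ---------------------------------------------------------

    def _aligned(self, X: MotifCountMatrix) -> np.ndarray:
        if X.motif_names != self.feature_names:
            aligned = X.subset_motifs(self.feature_names)
            return np.ascontiguousarray(aligned.counts, dtype=np.float64)
        return np.ascontiguousarray(X.counts, dtype=np.float64)

    def tree_predictions(self, Xf: np.ndarray) -> np.ndarray:
        """(n_trees, n_samples) predicted class indices."""
        out = np.empty((self.n_trees, Xf.shape[0]), dtype=np.int32)
        for t, tr in enumerate(self.trees):
            _predict_tree(
                tr.feature, tr.threshold, tr.left, tr.right, tr.leaf_class,
                Xf, out[t],
            )
        return out

    def vote_matrix(self, X: MotifCountMatrix) -> np.ndarray:
        """(n_samples, n_classes) fraction of trees voting for each class."""
        Xf = self._aligned(X)
        preds = self.tree_predictions(Xf)
        n, k = Xf.shape[0], len(self.class_names)
        votes = np.zeros((n, k), dtype=np.float64)
        for t in range(self.n_trees):
            votes[np.arange(n), preds[t]] += 1.0
        return votes / self.n_trees

    def predict(self, X: MotifCountMatrix) -> list[str]:
        votes = self.vote_matrix(X)
        return [self.class_names[i] for i in votes.argmax(axis=1)]

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path, meta: dict | None = None) -> None:
        obj = {
            "meta": meta or {},
            "feature_names": self.feature_names,
            "class_names": self.class_names,
            "features_per_split": self.features_per_split,
            "seed": self.seed,
            "n_training_samples": self.n_training_samples,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
            "bootstrap_indices": [b.tolist() for b in self.bootstrap_indices],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "ForestModel":
        with open(path) as fh:
            obj = json.load(fh)
        n = obj["n_training_samples"]
        trees = [
            Tree(
                feature=np.array(t["feature"], np.int32),
                threshold=np.array(t["threshold"], np.float64),
                left=np.array(t["left"], np.int32),
                right=np.array(t["right"], np.int32),
                value=np.array(t["value"], np.float64),
            )
            for t in obj["trees"]
        ]
        boots = [np.array(b, np.int64) for b in obj["bootstrap_indices"]]
        oobs = [_oob_from_bootstrap(b, n) for b in boots]
        return cls(
            trees=trees,
            bootstrap_indices=boots,
            oob_indices=oobs,
            feature_names=list(obj["feature_names"]),
            class_names=list(obj["class_names"]),
            features_per_split=int(obj["features_per_split"]),
            seed=int(obj["seed"]),
            n_training_samples=n,
        )


@dataclass
class ImportanceTable:
    """Per-motif raw and scaled mean decrease accuracy (MDA)."""

    motif_names: list[str]
    raw_mda: np.ndarray
    scaled_mda: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "motif": self.motif_names,
                "raw_mda": self.raw_mda,
                "scaled_mda": self.scaled_mda,
            }
        )
        return df.sort_values("scaled_mda", ascending=False, kind="mergesort").reset_index(
            drop=True
        )

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def shortlist(self, threshold: float = MDA_SHORTLIST_THRESHOLD) -> list[str]:
        """Motifs with scaled MDA above the reporting threshold, sorted."""
        order = np.argsort(-self.scaled_mda, kind="mergesort")
        return [
            self.motif_names[i] for i in order if self.scaled_mda[i] > threshold
        ]

    def ranking(self) -> list[str]:
        order = np.argsort(-self.scaled_mda, kind="mergesort")
        return [self.motif_names[i] for i in order]


# --------------------------------------------------------------------------
# training and evaluation
# --------------------------------------------------------------------------

def _oob_from_bootstrap(boot: np.ndarray, n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    mask[boot] = False
    return np.where(mask)[0]


def _encode_labels(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    class_names = sorted(set(labels))
    lookup = {c: i for i, c in enumerate(class_names)}
    return np.array([lookup[l] for l in labels], dtype=np.int32), class_names


def _feature_codes(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Map each feature column to dense codes of its sorted unique values."""
    n, p = counts.shape
    codes = np.empty((n, p), dtype=np.int32)
    nbins = np.empty(p, dtype=np.int64)
    uniques: list[np.ndarray] = []
    for f in range(p):
        u, inv = np.unique(counts[:, f], return_inverse=True)
        codes[:, f] = inv
        nbins[f] = u.size
        uniques.append(u.astype(np.float64))
    return codes, nbins, uniques


def resolve_features_per_split(p: int, features_per_split) -> int:
    if features_per_split == "auto" or features_per_split is None:
        return max(1, int(math.floor(math.sqrt(p))))
    m = int(features_per_split)
    if m < 1:
        raise ValueError("features_per_split must be >= 1")
    return min(m, p)


def train_forest(
    X: MotifCountMatrix,
    n_trees: int = DEFAULT_N_TREES,
    features_per_split="auto",
    seed: int = 0,
) -> ForestModel:
    """Train a bagged Gini forest on a motif-count matrix.

    Deterministic given ``seed``: bootstrap draws, per-node feature subsets
    and all tie-breaks are fixed.  ``features_per_split='auto'`` uses
    floor(sqrt(#features)).
    """
    y, class_names = _encode_labels(X.labels)
    if len(class_names) < 2:
        raise ValueError("training requires at least 2 classes")
    counts_per_class = np.bincount(y)
    if (counts_per_class < 2).any():
        small = [class_names[i] for i in np.where(counts_per_class < 2)[0]]
        log.warning("classes with fewer than 2 samples: %s", small)
    n, p = X.counts.shape
    mtry = resolve_features_per_split(p, features_per_split)

    codes, nbins, uniques = _feature_codes(X.counts)
    rs = np.random.RandomState(seed)
    tree_seeds = rs.randint(0, 2**31 - 1, size=n_trees)
    boots = [rs.randint(0, n, size=n).astype(np.int64) for _ in range(n_trees)]

    trees: list[Tree] = []
    oobs: list[np.ndarray] = []
    for t in range(n_trees):
        feat, c_lo, c_hi, left, right, value = _grow_tree(
            codes, y, len(class_names), boots[t], mtry, nbins, tree_seeds[t]
        )
        thr = np.zeros(feat.size, dtype=np.float64)
        internal = np.where(feat >= 0)[0]
        for node in internal:
            u = uniques[feat[node]]
            thr[node] = 0.5 * (u[c_lo[node]] + u[c_hi[node]])
        trees.append(Tree(feature=feat, threshold=thr, left=left, right=right, value=value))
        oobs.append(_oob_from_bootstrap(boots[t], n))

    return ForestModel(
        trees=trees,
        bootstrap_indices=boots,
        oob_indices=oobs,
        feature_names=list(X.motif_names),
        class_names=class_names,
        features_per_split=mtry,
        seed=seed,
        n_training_samples=n,
    )


def oob_error(model: ForestModel, X: MotifCountMatrix) -> float:
    """Misclassified fraction under out-of-bag majority vote.

    Each sample is predicted only by the trees for which it was not drawn
    into the bootstrap; samples OOB for no tree are excluded.  Vote ties go
    to the first class in sorted order (deterministic).
    """
    if X.n_samples != model.n_training_samples:
        raise ValueError("oob_error requires the matrix the model was trained on")
    y, class_names = _encode_labels(X.labels)
    if class_names != model.class_names:
        raise ValueError("label set differs from the model's classes")
    Xf = model._aligned(X)
    k = len(model.class_names)
    votes = np.zeros((X.n_samples, k), dtype=np.int64)
    pred = np.empty(X.n_samples, dtype=np.int32)
    for t, tr in enumerate(model.trees):
        oob = model.oob_indices[t]
        if oob.size == 0:
            continue
        Xo = np.ascontiguousarray(Xf[oob])
        out = np.empty(oob.size, dtype=np.int32)
        _predict_tree(tr.feature, tr.threshold, tr.left, tr.right, tr.leaf_class, Xo, out)
        votes[oob, out] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        return float("nan")
    hard = votes.argmax(axis=1)
    return float((hard[covered] != y[covered]).mean())


def permutation_importance(
    model: ForestModel, X: MotifCountMatrix, seed: int = 0
) -> ImportanceTable:
    """Permutation MDA, scaled by the sd of MDA over all features.

    For each tree and feature used by that tree, the feature's values are
    permuted among the tree's OOB samples and the OOB accuracy drop
    recorded; the raw MDA is the mean drop over all trees.  Scaled MDA
    divides by the standard deviation (ddof=1) of the raw MDAs across
    features; if that sd is 0 the scaled values are reported as 0 with a
    warning.
    """
    if X.n_samples != model.n_training_samples:
        raise ValueError("importance requires the matrix the model was trained on")
    y, class_names = _encode_labels(X.labels)
    if class_names != model.class_names:
        raise ValueError("label set differs from the model's classes")
    Xf = model._aligned(X)
    p = len(model.feature_names)
    drops = np.zeros(p, dtype=np.float64)
    rs = np.random.RandomState(seed)
    tree_seeds = rs.randint(0, 2**31 - 1, size=model.n_trees)
    for t, tr in enumerate(model.trees):
        oob = model.oob_indices[t]
        if oob.size == 0:
            continue
        used = np.zeros(p, dtype=np.uint8)
        used[tr.used_features()] = 1
        Xo = np.ascontiguousarray(Xf[oob])
        _tree_importance(
            tr.feature, tr.threshold, tr.left, tr.right, tr.leaf_class,
            Xo, y[oob], used, tree_seeds[t], drops,
        )
    raw = drops / model.n_trees
    sd = float(np.std(raw, ddof=1)) if p > 1 else 0.0
    if sd > 0:
        scaled = raw / sd
    else:
        warnings.warn(
            "standard deviation of raw MDA is 0; scaled MDA reported as 0",
            stacklevel=2,
        )
        scaled = np.zeros_like(raw)
    return ImportanceTable(
        motif_names=list(model.feature_names), raw_mda=raw, scaled_mda=scaled
    )


def two_round_train(
    X: MotifCountMatrix,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    compute_final_importance: bool = True,
) -> tuple[ForestModel, ImportanceTable | None]:
    """Two-round forest training with feature pruning and mtry tuning.

    Round 1 trains with ``features_per_split='auto'`` and removes every
    feature whose raw MDA is negative.  Round 2, on the reduced matrix,
    evaluates features_per_split in {max(1, floor(m/2)), m, min(p, 2m)}
    with m = floor(sqrt(#remaining features)), keeps the value with the
    smallest OOB error (ties to the smaller value), and returns that forest
    together with its importance table (unless ``compute_final_importance``
    is False, in which case the second element is None).
    """
    rs = np.random.RandomState(seed)
    s_round1, s_imp1, s_tune, s_imp2 = rs.randint(0, 2**31 - 1, size=4)

    model1 = train_forest(X, n_trees=n_trees, features_per_split="auto", seed=int(s_round1))
    imp1 = permutation_importance(model1, X, seed=int(s_imp1))
    keep = [m for m, r in zip(imp1.motif_names, imp1.raw_mda) if r >= 0]
    if not keep:
        raise ValueError(
            "round 1 removed every feature (all raw MDAs negative); "
            "review the MDA-based removal threshold for this dataset"
        )
    if len(keep) <= 1:
        log.warning("only %d feature(s) survived round-1 MDA pruning", len(keep))
    X2 = X.subset_motifs(keep)

    p2 = len(keep)
    m = max(1, int(math.floor(math.sqrt(p2))))
    grid = sorted({max(1, m // 2), m, min(p2, 2 * m)})
    best = None
    for mtry in grid:
        cand = train_forest(X2, n_trees=n_trees, features_per_split=mtry, seed=int(s_tune))
        err = oob_error(cand, X2)
        log.debug("tuning: features_per_split=%d OOB error=%.4f", mtry, err)
        if best is None or err < best[0]:  # strict: ties keep the smaller mtry
            best = (err, mtry, cand)
    _, _, model2 = best

    imp2 = (
        permutation_importance(model2, X2, seed=int(s_imp2))
        if compute_final_importance
        else None
    )
    return model2, imp2


def class_vote_scores(model: ForestModel, X_new: MotifCountMatrix) -> np.ndarray:
    """(samples, classes) matrix of vote fractions; each row sums to 1.

    ``X_new`` must contain the model's feature set (columns are aligned by
    motif name; missing motifs raise).
    """
    return model.vote_matrix(X_new)


def predict_classes(model: ForestModel, X_new: MotifCountMatrix) -> list[str]:
    """Hard predictions = argmax of the vote fractions."""
    return model.predict(X_new)
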
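"""Classifier evaluation: repeated stratified cross-validation, one-vs-rest
AUROC from forest vote fractions, per-class F1, and the window-size sweep.

The AUROC treats the fraction of trees voting for a class as the score of a
binary (that class vs rest) classifier and equals the normalised
Mann-Whitney U statistic, ties counting 1/2.  F1 is
``2 * precision * recall / (precision + recall)`` per class, 0 when both are 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .motif_scanner import MotifCountMatrix, build_count_matrix
from .peaks_io import fetch_sequences, make_windows
from .rf_model import class_vote_scores, two_round_train

log = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "stratified_fold_assignment",
    "cross_validate",
    "one_vs_rest_auroc",
    "per_class_f1",
    "window_size_sweep",
]


@dataclass
class CVResult:
    """Pooled per-repeat metrics of a repeated stratified k-fold CV."""

    class_names: list[str]
    auroc: np.ndarray  # (repeats, classes)
    f1: np.ndarray  # (repeats, classes)
    error: np.ndarray  # (repeats,) multiclass misclassification rate
    fold_assignments: np.ndarray  # (repeats, samples)
    seeds: list[int]

    @property
    def n_repeats(self) -> int:
        return self.auroc.shape[0]

    def mean_auroc(self) -> dict[str, float]:
        return dict(zip(self.class_names, self.auroc.mean(axis=0)))

    def mean_f1(self) -> dict[str, float]:
        return dict(zip(self.class_names, self.f1.mean(axis=0)))

    def to_frame(self) -> pd.DataFrame:
        """Tidy (repeat, class, metric, value) table."""
        rows = []
        for r in range(self.n_repeats):
            for c, cls in enumerate(self.class_names):
                rows.append((r, cls, "auroc", self.auroc[r, c]))
                rows.append((r, cls, "f1", self.f1[r, c]))
            rows.append((r, "(all)", "error", self.error[r]))
        return pd.DataFrame(rows, columns=["repeat", "class", "metric", "value"])

    def summary(self) -> dict:
        """Mean and sd per class over repeats (the error-bar presentation)."""
        return {
            "classes": self.class_names,
            "auroc_mean": self.auroc.mean(axis=0).tolist(),
            "auroc_sd": self.auroc.std(axis=0, ddof=1).tolist()
            if self.n_repeats > 1
            else [0.0] * len(self.class_names),
            "f1_mean": self.f1.mean(axis=0).tolist(),
            "f1_sd": self.f1.std(axis=0, ddof=1).tolist()
            if self.n_repeats > 1
            else [0.0] * len(self.class_names),
            "error_mean": float(self.error.mean()),
            "repeats": self.n_repeats,
            "seeds": self.seeds,
        }

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def stratified_fold_assignment(
    labels: list[str], folds: int, rng: np.random.RandomState
) -> np.ndarray:
    """Fold index per sample; each class is shuffled then dealt round-robin,
    so per-fold class proportions deviate from global by at most 1 sample."""
    labels_arr = np.asarray(labels)
    assign = np.empty(len(labels), dtype=np.int64)
    for cls in sorted(set(labels)):
        idx = np.where(labels_arr == cls)[0]
        if idx.size < folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} samples, fewer than {folds} folds"
            )
        perm = rng.permutation(idx.size)
        assign[idx[perm]] = np.arange(idx.size) % folds
    return assign


def one_vs_rest_auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUROC of ``scores`` for the positive class given binary ``truth``.

    Rank-based (normalised Mann-Whitney U); tied scores contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: one of the classes is absent")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def per_class_f1(predictions: list[str], truth: list[str]) -> dict[str, float]:
    """One-vs-rest F1 per class; 0 when precision + recall == 0."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    out: dict[str, float] = {}
    for cls in sorted(set(truth)):
        tp = int(((pred == cls) & (true == cls)).sum())
        fp = int(((pred == cls) & (true != cls)).sum())
        fn = int(((pred != cls) & (true == cls)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        out[cls] = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
    return out


def cross_validate(
    X: MotifCountMatrix,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> CVResult:
    """Repeated stratified k-fold CV of the full two-round training pipeline.

    Per repeat ``r`` (seeded ``seed + r``): stratified folds are drawn; for
    each fold the model is trained on the remaining folds with
    :func:`two_round_train` (feature selection happens inside the fold, so
    no held-out information leaks into it) and vote fractions are computed
    on the held-out fold.  Held-out votes are pooled within the repeat and
    per-class AUROC / F1 and the multiclass error computed on the pool.
    """
    class_names = X.class_names
    if len(class_names) < 2:
        raise ValueError("cross-validation requires at least 2 classes")
    n = X.n_samples
    k = len(class_names)
    auroc = np.zeros((repeats, k))
    f1 = np.zeros((repeats, k))
    error = np.zeros(repeats)
    assignments = np.zeros((repeats, n), dtype=np.int64)
    seeds = [seed + r for r in range(repeats)]
    truth = np.asarray(X.labels)

    for r in range(repeats):
        rs = np.random.RandomState(seeds[r])
        assign = stratified_fold_assignment(X.labels, folds, rs)
        assignments[r] = assign
        fold_seeds = rs.randint(0, 2**31 - 1, size=folds)
        pooled = np.zeros((n, k))
        for fold in range(folds):
            test_idx = np.where(assign == fold)[0]
            train_idx = np.where(assign != fold)[0]
            model, _ = two_round_train(
                X.subset_samples(train_idx),
                seed=int(fold_seeds[fold]),
                n_trees=n_trees,
                compute_final_importance=False,
            )
            votes = class_vote_scores(model, X.subset_samples(test_idx))
            # the fold model's classes always cover the stratified test fold
            cols = [model.class_names.index(c) for c in class_names]
            pooled[test_idx] = votes[:, cols]
        for c, cls in enumerate(class_names):
            auroc[r, c] = one_vs_rest_auroc(pooled[:, c], truth == cls)
        hard = [class_names[i] for i in pooled.argmax(axis=1)]
        f1_map = per_class_f1(hard, X.labels)
        f1[r] = [f1_map[c] for c in class_names]
        error[r] = float((np.asarray(hard) != truth).mean())
        log.info(
            "CV repeat %d/%d: error=%.4f mean AUROC=%.4f",
            r + 1, repeats, error[r], auroc[r].mean(),
        )

    return CVResult(
        class_names=class_names,
        auroc=auroc,
        f1=f1,
        error=error,
        fold_assignments=assignments,
        seeds=seeds,
    )


def window_size_sweep(
    peaks,
    genome,
    db,
    flank_grid: list[int],
    contig_lengths: dict[str, int] | None = None,
    repeats: int = 2,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[pd.DataFrame, int]:
    """Cross-validate the pipeline at each window half-width in ``flank_grid``.

    For each flank the windows are rebuilt around the peak centres, their
    sequences rescanned, and a repeated stratified CV run; the recommended
    flank is the argmax of the mean per-class F1 (ties to the smaller
    flank).  Returns (per-flank tidy summary, recommended flank).
    """
    if not flank_grid:
        raise ValueError("flank_grid must be nonempty")
    rows = []
    best: tuple[float, int] | None = None
    for flank in sorted(flank_grid):
        windows = make_windows(peaks, flank, contig_lengths=contig_lengths)
        seqs = fetch_sequences(windows, genome)
        X = build_count_matrix(seqs, db)
        cv = cross_validate(X, repeats=repeats, folds=folds, seed=seed, n_trees=n_trees)
        mean_f1 = float(cv.f1.mean())
        mean_auroc = float(cv.auroc.mean())
        rows.append(
            {
                "flank": flank,
                "window_length": 2 * flank,
                "mean_f1": mean_f1,
                "mean_auroc": mean_auroc,
                "mean_error": float(cv.error.mean()),
                "n_windows": len(windows),
            }
        )
        log.info("sweep flank=%d: mean F1=%.4f", flank, mean_f1)
        if best is None or mean_f1 > best[0]:  # strict: ties keep smaller flank
            best = (mean_f1, flank)
    return pd.DataFrame(rows), best[1]
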
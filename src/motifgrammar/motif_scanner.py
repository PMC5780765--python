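"""PWM scanning of window sequences and assembly of the motif-count matrix.

Every offset on both strands of each window is scored with the natural-log
log-odds matrix of each PWM; an occurrence is an (offset, strand) pair whose
score reaches the PWM's detection threshold.  Overlapping hits all count, a
palindrome matching both strands at one offset counts twice, and any window
containing an N base can never be a hit.  The resulting samples x motifs
count matrix is the interchange object between scanning and modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .motif_db import (
    DEFAULT_PSEUDOCOUNT,
    UNIFORM_BACKGROUND,
    MotifDatabase,
    PWM,
    logodds_matrix,
)

log = logging.getLogger(__name__)

__all__ = [
    "MotifCountMatrix",
    "encode_sequence",
    "score_at",
    "count_occurrences",
    "build_count_matrix",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N (case-insensitive) as int8 codes 0..4."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = _BASE_INDEX[ch]
        except KeyError:
            raise ValueError(f"unexpected base {ch!r} at position {i}") from None
    return out


def _scoring_matrices(
    pwm: PWM, background: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse-strand) scoring matrices with an N column of -inf.

    Scoring the minus strand at forward offset o sums, over forward window
    positions j, the forward matrix entry for the complement base at the
    mirrored motif position — i.e. a reverse-complemented scoring matrix
    applied to the forward sequence.
    """
    lo = logodds_matrix(pwm, background, pseudocount)
    w = lo.shape[0]
    fwd = np.full((w, 5), -np.inf)
    fwd[:, :4] = lo
    rev = np.full((w, 5), -np.inf)
    rev[:, :4] = lo[::-1, ::-1]
    return fwd, rev


def _strand_scores(mat: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores at every offset for one strand; ``codes`` is (n_seqs, L) int8."""
    w = mat.shape[0]
    n_off = codes.shape[1] - w + 1
    acc = np.zeros((codes.shape[0], n_off))
    for i in range(w):
        acc += mat[i][codes[:, i : i + n_off]]
    return acc


def score_at(
    pwm: PWM,
    sequence: str,
    offset: int,
    strand: str,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Log-odds score of one (offset, strand) placement.

    On the minus strand the reverse complement of the window is scored.
    A window containing N scores -inf.
    """
    w = pwm.width
    if not 0 <= offset <= len(sequence) - w:
        raise ValueError(
            f"offset {offset} out of range for width-{w} motif on "
            f"length-{len(sequence)} sequence"
        )
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    codes = encode_sequence(sequence[offset : offset + w])
    window = codes if strand == "+" else _COMPLEMENT_CODE[codes[::-1]]
    lo = logodds_matrix(pwm, background, pseudocount)
    total = 0.0
    for i in range(w):
        b = window[i]
        if b == 4:
            return float("-inf")
        total += lo[i, b]
    return total


def count_occurrences(
    pwm: PWM,
    sequence: str,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> int:
    """Number of (offset, strand) pairs scoring >= the detection threshold."""
    if len(sequence) < pwm.width:
        return 0
    codes = encode_sequence(sequence)[None, :]
    fwd, rev = _scoring_matrices(pwm, background, pseudocount)
    thr = pwm.detection_threshold
    n = int((_strand_scores(fwd, codes) >= thr).sum())
    n += int((_strand_scores(rev, codes) >= thr).sum())
    return n


@dataclass
class MotifCountMatrix:
    """samples x motifs occurrence counts with per-sample class labels."""

    counts: np.ndarray
    sample_ids: list[str]
    motif_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length must match count rows")
        if len(self.motif_names) != m:
            raise ValueError("motif_names length must match count columns")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_motifs(self) -> int:
        return self.counts.shape[1]

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels))

    def subset_samples(self, idx: np.ndarray) -> "MotifCountMatrix":
        idx = np.asarray(idx)
        return MotifCountMatrix(
            counts=self.counts[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            motif_names=list(self.motif_names),
            labels=[self.labels[i] for i in idx],
        )

    def subset_motifs(self, names: list[str]) -> "MotifCountMatrix":
        pos = {m: j for j, m in enumerate(self.motif_names)}
        missing = [m for m in names if m not in pos]
        if missing:
            raise KeyError(f"motifs absent from matrix: {missing[:5]}")
        cols = [pos[m] for m in names]
        return MotifCountMatrix(
            counts=self.counts[:, cols],
            sample_ids=list(self.sample_ids),
            motif_names=list(names),
            labels=list(self.labels),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.motif_names)
        df.insert(0, "cell_type", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifCountMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        if df.columns[0] != "sample_id" or df.columns[1] != "cell_type":
            raise ValueError(
                "count-matrix TSV must start with sample_id and cell_type columns"
            )
        return cls(
            counts=df.iloc[:, 2:].to_numpy(dtype=np.int64),
            sample_ids=df["sample_id"].astype(str).tolist(),
            motif_names=list(df.columns[2:]),
            labels=df["cell_type"].astype(str).tolist(),
        )


def build_count_matrix(
    sequences,
    db: MotifDatabase,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MotifCountMatrix:
    """Count every motif in every sequence (all offsets, both strands).

    ``sequences`` is a list of objects with ``id``, ``sequence`` and
    ``cell_type`` attributes (:class:`~motifgrammar.peaks_io.LabelledSequence`),
    all of equal length.
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    if len(db) == 0:
        raise ValueError("empty motif database")
    lengths = {len(s.sequence) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)[:5]}")
    L = lengths.pop()

    codes = np.empty((len(sequences), L), dtype=np.int8)
    for i, s in enumerate(sequences):
        codes[i] = encode_sequence(s.sequence)

    counts = np.zeros((len(sequences), len(db)), dtype=np.int64)
    for j, pwm in enumerate(db):
        if pwm.width > L:
            continue
        fwd, rev = _scoring_matrices(pwm, background, pseudocount)
        thr = pwm.detection_threshold
        counts[:, j] = (_strand_scores(fwd, codes) >= thr).sum(axis=1)
        counts[:, j] += (_strand_scores(rev, codes) >= thr).sum(axis=1)

    return MotifCountMatrix(
        counts=counts,
        sample_ids=[s.id for s in sequences],
        motif_names=db.names,
        labels=[s.cell_type for s in sequences],
    )
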
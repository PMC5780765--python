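"""Shared fixtures: the planted benchmark (study conditions) and small helpers.

The benchmark fixtures are session-scoped because several tests interrogate
different aspects of the same study: 5 classes x 300 windows of 240 bp over
a 50-motif database, classes 1-4 requiring >= 3 copies of their own motif
and class 5 requiring one copy each of two motifs, decoys at 0.5 per window.
All seeds are fixed constants.
"""

from __future__ import annotations

import numpy as np
import pytest

from motifgrammar.motif_scanner import MotifCountMatrix, build_count_matrix
from motifgrammar.rf_model import permutation_importance, two_round_train
from motifgrammar.synthetic_data import (
    default_benchmark,
    generate_dataset,
    null_dataset,
)

BENCH_DB_SEED = 7
BENCH_DATA_SEED = 11
BENCH_TRAIN_SEED = 13
BENCH_CV_SEED = 17


@pytest.fixture(scope="session")
def benchmark():
    """(grammar, database, dataset) of the default planted benchmark."""
    grammar, db = default_benchmark(seed=BENCH_DB_SEED)
    ds = generate_dataset(grammar, db, n_per_class=300, seed=BENCH_DATA_SEED)
    return grammar, db, ds


@pytest.fixture(scope="session")
def benchmark_counts(benchmark) -> MotifCountMatrix:
    _, db, ds = benchmark
    return build_count_matrix(ds.sequences, db)


@pytest.fixture(scope="session")
def benchmark_model(benchmark_counts):
    """Two-round forest trained on the full benchmark + its importance table."""
    model, imp = two_round_train(benchmark_counts, seed=BENCH_TRAIN_SEED)
    return model, imp


@pytest.fixture(scope="session")
def null_benchmark(benchmark):
    """Matched null dataset and its count matrix (labels carry no signal)."""
    grammar, db, _ = benchmark
    ds = null_dataset(grammar, db, n_per_class=300, seed=BENCH_DATA_SEED + 1)
    return ds, build_count_matrix(ds.sequences, db)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_matrix(counts, labels, motif_names=None) -> MotifCountMatrix:
    counts = np.asarray(counts)
    if motif_names is None:
        motif_names = [f"M{j:02d}" for j in range(counts.shape[1])]
    return MotifCountMatrix(
        counts=counts,
        sample_ids=[f"s{i}" for i in range(counts.shape[0])],
        motif_names=list(motif_names),
        labels=list(labels),
    )
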
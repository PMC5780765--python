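"""Forest training, OOB error, permutation importance and two-round training."""

import numpy as np
import pytest

from motifgrammar.rf_model import (
    ForestModel,
    class_vote_scores,
    oob_error,
    permutation_importance,
    train_forest,
    two_round_train,
)

from .conftest import toy_matrix


def planted_matrix(rng, n_per_class=150, p=30, n_classes=3, lam=0.5, strength=3):
    """Class i carries feature i elevated by ~strength; the rest is Poisson noise."""
    n = n_per_class * n_classes
    X = rng.poisson(lam, size=(n, p))
    labels = []
    for c in range(n_classes):
        rows = slice(c * n_per_class, (c + 1) * n_per_class)
        X[rows, c] += rng.integers(strength, strength + 2, size=n_per_class)
        labels += [f"c{c}"] * n_per_class
    return toy_matrix(X, labels)


def test_default_forest_has_500_trees_and_auto_mtry(rng):
    X = planted_matrix(rng, n_per_class=15, p=9)
    m = train_forest(X, n_trees=500, seed=0)
    assert m.n_trees == 500
    assert m.features_per_split == 3  # floor(sqrt(9))


def test_auto_mtry_for_large_feature_count():
    from motifgrammar.rf_model import resolve_features_per_split

    assert resolve_features_per_split(2067, "auto") == 45


def test_training_is_deterministic_given_seed(rng):
    X = planted_matrix(rng, n_per_class=30, p=12)
    a = train_forest(X, n_trees=30, seed=42)
    b = train_forest(X, n_trees=30, seed=42)
    for ta, tb in zip(a.trees, b.trees):
        np.testing.assert_array_equal(ta.feature, tb.feature)
        np.testing.assert_array_equal(ta.threshold, tb.threshold)
    np.testing.assert_array_equal(a.vote_matrix(X), b.vote_matrix(X))
    c = train_forest(X, n_trees=30, seed=43)
    assert any(
        not np.array_equal(ta.feature, tc.feature) for ta, tc in zip(a.trees, c.trees)
    )


def test_single_class_input_rejected(rng):
    X = toy_matrix(rng.poisson(1, (10, 4)), ["only"] * 10)
    with pytest.raises(ValueError, match="2 classes"):
        train_forest(X, n_trees=5, seed=0)


def test_bootstrap_and_oob_partition_samples(rng):
    X = planted_matrix(rng, n_per_class=25, p=8)
    m = train_forest(X, n_trees=20, seed=1)
    n = X.n_samples
    for boot, oob in zip(m.bootstrap_indices, m.oob_indices):
        assert boot.size == n
        in_bag = set(boot.tolist())
        assert in_bag.isdisjoint(oob.tolist())
        assert in_bag | set(oob.tolist()) == set(range(n))


def test_oob_error_zero_on_separable_toy():
    counts = np.array([[0]] * 30 + [[10]] * 30)
    X = toy_matrix(counts, ["a"] * 30 + ["b"] * 30)
    m = train_forest(X, n_trees=100, seed=0)
    assert oob_error(m, X) == 0.0


def test_oob_error_chance_level_on_permuted_labels(rng):
    """Label-permuted balanced two-class data: OOB error ~ 0.5 (the chance
    level is the independent oracle here)."""
    X = toy_matrix(rng.poisson(2.0, size=(500, 20)), ["a", "b"] * 250)
    m = train_forest(X, n_trees=500, seed=3)
    assert oob_error(m, X) == pytest.approx(0.5, abs=0.05)


def test_oob_error_curve_flattens_by_500_trees(rng):
    X = planted_matrix(rng, n_per_class=100, p=20, strength=2)
    e250 = oob_error(train_forest(X, n_trees=250, seed=5), X)
    e500 = oob_error(train_forest(X, n_trees=500, seed=5), X)
    assert abs(e500 - e250) < 0.02


def test_vote_rows_sum_to_one_and_match_hard_prediction(rng):
    X = planted_matrix(rng, n_per_class=40, p=10)
    m = train_forest(X, n_trees=50, seed=2)
    votes = class_vote_scores(m, X)
    np.testing.assert_allclose(votes.sum(axis=1), 1.0, atol=1e-12)
    hard = m.predict(X)
    assert [m.class_names[i] for i in votes.argmax(axis=1)] == hard


def test_unanimous_vote_gives_unit_row():
    counts = np.array([[0]] * 20 + [[10]] * 20)
    X = toy_matrix(counts, ["a"] * 20 + ["b"] * 20)
    m = train_forest(X, n_trees=50, seed=0)
    probe = toy_matrix(np.array([[0], [10]]), ["a", "b"])
    votes = class_vote_scores(m, probe)
    np.testing.assert_array_equal(votes, [[1.0, 0.0], [0.0, 1.0]])


def test_vote_scores_feature_mismatch_raises(rng):
    X = planted_matrix(rng, n_per_class=20, p=6)
    m = train_forest(X, n_trees=10, seed=0)
    other = toy_matrix(np.zeros((3, 2), dtype=int), ["a", "b", "c"],
                       motif_names=["Z1", "Z2"])
    with pytest.raises(KeyError):
        class_vote_scores(m, other)


def test_constant_feature_has_zero_raw_mda(rng):
    X = planted_matrix(rng, n_per_class=50, p=8)
    X.counts[:, 7] = 4  # constant column: permutation is a no-op
    m = train_forest(X, n_trees=100, seed=4)
    imp = permutation_importance(m, X, seed=0)
    assert imp.raw_mda[7] == 0.0


def test_planted_motif_has_top_scaled_mda(rng):
    """Class defined by 'count of M00 >= 3' must put M00 at importance rank 1."""
    n = 300
    X = rng.poisson(0.3, size=(n, 25))
    labels = ["pos" if rng.random() < 0.5 else "neg" for _ in range(n)]
    for i, l in enumerate(labels):
        X[i, 0] = rng.integers(3, 6) if l == "pos" else rng.integers(0, 3)
    M = toy_matrix(X, labels)
    m = train_forest(M, n_trees=200, seed=6)
    imp = permutation_importance(m, M, seed=7)
    assert imp.ranking()[0] == "M00"
    assert imp.scaled_mda.max() == imp.scaled_mda[0]


def test_two_round_drops_negative_mda_features(rng):
    X = planted_matrix(rng, n_per_class=100, p=50, strength=3)
    model1 = train_forest(X, n_trees=500, seed=8)
    model2, imp2 = two_round_train(X, seed=8)
    assert set(model2.feature_names) <= set(X.motif_names)
    # informative features always survive
    assert {"M00", "M01", "M02"} <= set(model2.feature_names)
    assert imp2 is not None
    X2 = X.subset_motifs(model2.feature_names)
    assert oob_error(model2, X2) <= oob_error(model1, X) + 0.02


def test_two_round_on_pure_noise_is_flagged_or_degenerate(rng):
    X = toy_matrix(rng.poisson(1.0, size=(60, 10)), ["a", "b"] * 30)
    try:
        model, _ = two_round_train(X, seed=9, n_trees=50)
    except ValueError:
        return  # every feature dropped: acceptable degenerate outcome
    assert len(model.feature_names) >= 1


def test_model_json_roundtrip_preserves_predictions(tmp_path, rng):
    X = planted_matrix(rng, n_per_class=25, p=8)
    m = train_forest(X, n_trees=20, seed=10)
    path = tmp_path / "model.json"
    m.to_json(path)
    m2 = ForestModel.from_json(path)
    assert m2.class_names == m.class_names
    assert m2.feature_names == m.feature_names
    np.testing.assert_array_equal(m.vote_matrix(X), m2.vote_matrix(X))
    np.testing.assert_array_equal(
        np.concatenate(m.oob_indices), np.concatenate(m2.oob_indices)
    )


def test_accuracy_parity_with_sklearn_forest(rng):
    """Independent cross-check: on a planted problem our forest and sklearn's
    reach the same (near-perfect) held-out accuracy."""
    from sklearn.ensemble import RandomForestClassifier

    train = planted_matrix(rng, n_per_class=100, p=15)
    test = planted_matrix(rng, n_per_class=50, p=15)
    ours = train_forest(train, n_trees=200, seed=11)
    acc_ours = np.mean(np.asarray(ours.predict(test)) == np.asarray(test.labels))
    skl = RandomForestClassifier(n_estimators=200, random_state=11)
    skl.fit(train.counts, train.labels)
    acc_skl = skl.score(test.counts, test.labels)
    assert acc_ours >= 0.95
    assert abs(acc_ours - acc_skl) < 0.03
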
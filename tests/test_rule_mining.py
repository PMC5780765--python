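"""Rule extraction, integerization, metrics vs brute force, pruning,
selection and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifgrammar.rf_model import ForestModel, Tree, train_forest
from motifgrammar.rule_mining import (
    Condition,
    Rule,
    RuleSet,
    extract_rules,
    filter_rules,
    integerize,
    mine_grammar,
    prune_rule,
    render_rules,
    rule_metrics,
    select_rules,
)

from .conftest import toy_matrix


def single_split_model(motifs=("MA", "MB"), threshold=2.5):
    tree = Tree(
        feature=np.array([0, -1, -1], np.int32),
        threshold=np.array([threshold, 0, 0], np.float64),
        left=np.array([1, -1, -1], np.int32),
        right=np.array([2, -1, -1], np.int32),
        value=np.array([[5, 5], [5, 0], [0, 5]], np.float64),
    )
    return ForestModel(
        trees=[tree],
        bootstrap_indices=[np.arange(4)],
        oob_indices=[np.array([], dtype=np.int64)],
        feature_names=list(motifs),
        class_names=["x", "y"],
        features_per_split=1,
        seed=0,
        n_training_samples=4,
    )


@pytest.mark.parametrize(
    "op,thr,expected",
    [
        ("<=", 2.5, ("<=", 2)),
        (">", 2.5, (">=", 3)),
        ("<=", 0.5, ("<=", 0)),
        (">", 0.5, (">=", 1)),
        ("<=", 3.0, ("<=", 3)),
    ],
)
def test_integerize(op, thr, expected):
    assert integerize(op, thr) == expected


@settings(derandomize=True, max_examples=300)
@given(
    x=st.integers(min_value=0, max_value=50),
    thr=st.floats(min_value=0.0, max_value=50.0,
                  allow_nan=False, allow_infinity=False),
)
def test_integerized_conditions_are_equivalent_on_integer_counts(x, thr):
    """For any integer count x, the integerised condition accepts x exactly
    when the original real-valued split test does."""
    op_le, t_le = integerize("<=", thr)
    assert (x <= thr) == (x <= t_le)
    op_ge, t_ge = integerize(">", thr)
    assert (x > thr) == (x >= t_ge)


def test_extract_rules_from_single_split():
    rules = extract_rules(single_split_model())
    keys = {r.key() for r in rules}
    assert keys == {
        (("MA", "<=", 2),),
        (("MA", ">=", 3),),
    }


def test_deep_paths_truncated_to_six_conditions():
    # chain of 7 splits on distinct features, all left children internal
    k = 7
    feature = np.array(list(range(k)) + [-1] * (k + 1), np.int32)
    threshold = np.array([0.5] * k + [0.0] * (k + 1), np.float64)
    left = np.array([k + i for i in range(k)] + [-1] * (k + 1), np.int32)
    right = np.array(list(range(1, k)) + [2 * k] + [-1] * (k + 1), np.int32)
    value = np.ones((2 * k + 1, 2), np.float64)
    model = ForestModel(
        trees=[Tree(feature, threshold, left, right, value)],
        bootstrap_indices=[np.arange(2)],
        oob_indices=[np.array([], dtype=np.int64)],
        feature_names=[f"M{i}" for i in range(k)],
        class_names=["x", "y"],
        features_per_split=1,
        seed=0,
        n_training_samples=2,
    )
    rules = extract_rules(model)
    assert max(r.length for r in rules) <= 6


def test_conflicting_bounds_mark_rule_unsatisfiable():
    from motifgrammar.rule_mining import _merge_conditions

    conds = [Condition("MA", ">=", 3), Condition("MA", "<=", 1)]
    _, ok = _merge_conditions(conds)
    assert not ok
    # an unsatisfiable rule covers nothing: frequency 0, error 1
    rule = Rule(conditions=conds, satisfiable=False)
    measured = rule_metrics(rule, _random_matrix()[0])
    assert (measured.frequency, measured.error) == (0.0, 1.0)


def _random_matrix(seed=0, n=40, p=5):
    rng = np.random.default_rng(seed)
    X = toy_matrix(rng.poisson(2.0, (n, p)), list(rng.choice(["a", "b", "c"], n)))
    return X, rng


def _random_rule(rng, motifs):
    k = int(rng.integers(1, 4))
    chosen = rng.choice(len(motifs), size=k, replace=False)
    return Rule(
        conditions=[
            Condition(motifs[j], "<=" if rng.random() < 0.5 else ">=",
                      int(rng.integers(0, 5)))
            for j in chosen
        ]
    )


def brute_force_metrics(rule, X):
    """Row-by-row oracle for frequency/outcome/error."""
    covered = []
    for i in range(X.n_samples):
        ok = True
        for c in rule.conditions:
            v = X.counts[i, X.motif_names.index(c.motif)]
            ok &= v <= c.threshold if c.op == "<=" else v >= c.threshold
        if ok:
            covered.append(X.labels[i])
    if not covered:
        return None, 0.0, 1.0
    classes = sorted(set(covered))
    best = max(classes, key=lambda c: (covered.count(c), ))
    # alphabetical tie-break: max on count only, ties resolved by sorted order
    top = max(covered.count(c) for c in classes)
    best = [c for c in classes if covered.count(c) == top][0]
    freq = len(covered) / X.n_samples
    err = 1.0 - top / len(covered)
    return best, freq, err


def test_rule_metrics_match_bruteforce_recounts():
    X, rng = _random_matrix(seed=3)
    for _ in range(200):
        rule = _random_rule(rng, X.motif_names)
        measured = rule_metrics(rule, X)
        outcome, freq, err = brute_force_metrics(rule, X)
        assert measured.outcome == outcome
        assert measured.frequency == pytest.approx(freq, abs=0)
        assert measured.error == pytest.approx(err, abs=1e-15)


def test_rule_metrics_trivial_cases():
    X = toy_matrix(np.array([[5], [6], [7]]), ["a", "a", "a"])
    full = rule_metrics(Rule([Condition("M00", ">=", 0)]), X)
    assert (full.frequency, full.error, full.outcome) == (1.0, 0.0, "a")
    empty = rule_metrics(Rule([Condition("M00", ">=", 99)]), X)
    assert (empty.frequency, empty.error, empty.outcome) == (0.0, 1.0, None)


def test_prune_removes_redundant_condition():
    X = toy_matrix(
        np.array([[0, 3], [0, 4], [5, 0], [6, 1]]), ["a", "a", "b", "b"]
    )
    # either condition alone is perfect for 'a': one of them must be pruned.
    # conditions are visited last-to-first, so M01>=3 is dropped first and
    # the surviving single condition is M00<=4
    rule = rule_metrics(
        Rule([Condition("M00", "<=", 4), Condition("M01", ">=", 3)]), X
    )
    pruned = prune_rule(rule, X, max_decay=0.05)
    assert pruned.length == 1
    assert pruned.conditions[0].motif == "M00"
    assert pruned.error == 0.0


def test_prune_never_empties_a_rule():
    X, rng = _random_matrix(seed=4)
    rule = rule_metrics(Rule([Condition("M00", ">=", 0)]), X)  # always true
    pruned = prune_rule(rule, X)
    assert pruned.length == 1


def test_prune_respects_decay_bound_on_random_instances():
    X, rng = _random_matrix(seed=5, n=60)
    for _ in range(50):
        rule = rule_metrics(_random_rule(rng, X.motif_names), X)
        pruned = prune_rule(rule, X, max_decay=0.05)
        assert pruned.length <= rule.length
        # final error within the compounded decay bound of the start
        if rule.error > 0:
            assert pruned.error <= (1.05 ** rule.length) * rule.error + 1e-9
        assert pruned.length >= 1


def test_select_never_coselects_duplicate_condition_sets():
    X = toy_matrix(np.array([[0], [0], [5], [5]]), ["a", "a", "b", "b"])
    r1 = rule_metrics(Rule([Condition("M00", ">=", 3)]), X)
    r2 = rule_metrics(Rule([Condition("M00", ">=", 3)]), X)
    selected = select_rules([r1, r2], X)
    assert len(selected.rules) == 1


def test_select_perfect_rules_give_zero_training_error():
    X = toy_matrix(
        np.array([[5, 0], [5, 0], [0, 5], [0, 5], [0, 0], [0, 0]]),
        ["a", "a", "b", "b", "c", "c"],
    )
    cands = [
        rule_metrics(Rule([Condition("M00", ">=", 3)]), X),  # -> a
        rule_metrics(Rule([Condition("M01", ">=", 3)]), X),  # -> b
    ]
    rs = select_rules(cands, X)
    # rule-list + default ('a' by alphabetical tie) classifies all samples;
    # the 'a' rule is redundant with the default and may be skipped
    by_class = rs.by_class()
    assert len(by_class["b"]) == 1
    labels = np.asarray(X.labels)
    # simulate the rule list: first match wins, default = 'a'
    pred = []
    for i in range(X.n_samples):
        hit = None
        for r in rs.rules:
            if all(
                (X.counts[i, X.motif_names.index(c.motif)] <= c.threshold)
                if c.op == "<="
                else (X.counts[i, X.motif_names.index(c.motif)] >= c.threshold)
                for c in r.conditions
            ):
                hit = r.outcome
                break
        pred.append(hit or rs.provenance["default_class"])
    # only class 'c' samples fall to the default and the default is 'a';
    # selection stops once no candidate strictly improves
    assert (np.asarray(pred) == labels)[labels != "c"].all()


def test_filter_rules_boundaries():
    def mk(freq, err):
        r = Rule([Condition("M", ">=", 1)], outcome="a")
        r.frequency, r.error = freq, err
        return r

    rs = RuleSet(
        rules=[mk(0.079, 0.0), mk(0.08, 0.0), mk(0.5, 0.7), mk(0.5, 0.71)],
        class_names=["a"],
    )
    kept = filter_rules(rs, min_frequency=0.08, max_error=0.7)
    assert [(r.frequency, r.error) for r in kept.rules] == [(0.08, 0.0), (0.5, 0.7)]
    assert filter_rules(RuleSet(rules=[], class_names=["a"])).rules == []


def test_render_formats_conditions_and_missing_classes():
    r1 = Rule([Condition("NFE2", ">=", 3)], outcome="HCT-116")
    r2 = Rule(
        [Condition("MAF", "<=", 0), Condition("CDX2", ">=", 5)], outcome="HEK293"
    )
    rs = RuleSet(rules=[r1, r2], class_names=["HCT-116", "HEK293", "PANC-1"])
    text = render_rules(rs)
    lines = text.splitlines()
    assert "NFE2>=3 -> HCT-116" in lines
    assert "CDX2>=5 & MAF=0 -> HEK293" in lines  # alphabetical, '=0' display
    assert "No rule identified -> PANC-1" in lines


def test_mine_grammar_recovers_a_planted_single_split(rng):
    """End-to-end miniature: one informative motif, two classes."""
    n = 200
    X = rng.poisson(0.2, size=(n, 6))
    labels = ["pos" if i % 2 else "neg" for i in range(n)]
    for i, l in enumerate(labels):
        if l == "pos":
            X[i, 2] += 3
        else:
            X[i, 2] = 0
    M = toy_matrix(X, labels)
    model = train_forest(M, n_trees=100, seed=3)
    rs = mine_grammar(model, M)
    pos_rules = rs.by_class()["pos"]
    assert pos_rules, "expected at least one rule for the planted class"
    top = pos_rules[0]
    assert any(
        c.motif == "M02" and c.op == ">=" and abs(c.threshold - 3) <= 1
        for c in top.conditions
    )
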
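"""Motif-grammar rule mining from a trained forest.

Every root-to-leaf path of every tree is a candidate rule: a conjunction of
integer threshold conditions on motif counts.  Candidates are measured on
the training matrix (frequency = fraction of samples satisfying the
conditions; outcome = majority class among them; error = misclassified
fraction among them), pruned condition-by-condition under a relative
error-decay bound, reduced to a compact non-redundant ordered rule list by
greedy selection, and finally filtered on frequency and error.  The
surviving rules per class are the motif grammar.

Because count features are integers, real-valued split thresholds are
integerised on extraction: ``x <= 2.5`` becomes ``x <= 2`` and ``x > 2.5``
becomes ``x >= 3``; an upper bound of 0 is displayed as ``= 0``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .motif_scanner import MotifCountMatrix
from .rf_model import ForestModel

log = logging.getLogger(__name__)

#: maximum number of conditions kept per extracted path
MAX_RULE_CONDITIONS = 6
#: relative error-decay tolerance for dropping a condition during pruning
DEFAULT_MAX_DECAY = 0.05
DEFAULT_MIN_FREQUENCY = 0.08
DEFAULT_MAX_ERROR = 0.7

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "extract_rules",
    "integerize",
    "rule_metrics",
    "prune_rule",
    "select_rules",
    "filter_rules",
    "filter_ruleset",
    "render_rules",
    "mine_grammar",
]


@dataclass(frozen=True)
class Condition:
    """One integer threshold test on a motif count: ``motif <= t`` or ``motif >= t``."""

    motif: str
    op: str  # "<=" or ">="
    threshold: int

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">="):
            raise ValueError(f"op must be '<=' or '>=', got {self.op!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    def __str__(self) -> str:
        if self.op == "<=" and self.threshold == 0:
            return f"{self.motif}=0"
        return f"{self.motif}{self.op}{self.threshold}"


@dataclass
class Rule:
    """A conjunction of conditions with its predicted class and metrics."""

    conditions: list[Condition]
    outcome: str | None = None
    frequency: float = float("nan")
    error: float = float("nan")
    satisfiable: bool = True

    @property
    def length(self) -> int:
        return len(self.conditions)

    def key(self) -> tuple:
        """Canonical identity of the condition set (order-independent)."""
        return tuple(sorted((c.motif, c.op, c.threshold) for c in self.conditions))

    def condition_string(self) -> str:
        return " & ".join(
            str(c) for c in sorted(self.conditions, key=lambda c: (c.motif, c.op))
        )


@dataclass
class RuleSet:
    """Selected rules grouped by outcome class, with provenance."""

    rules: list[Rule]
    class_names: list[str]
    provenance: dict = field(default_factory=dict)

    def by_class(self) -> dict[str, list[Rule]]:
        out: dict[str, list[Rule]] = {c: [] for c in self.class_names}
        for r in self.rules:
            out.setdefault(r.outcome, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.class_names:
            for r in self.by_class().get(cls, []):
                rows.append(
                    {
                        "rule": r.condition_string(),
                        "prediction": cls,
                        "frequency": r.frequency,
                        "error": r.error,
                        "length": r.length,
                    }
                )
        return pd.DataFrame(
            rows, columns=["rule", "prediction", "frequency", "error", "length"]
        )

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def to_json(self, path: str | Path, meta: dict | None = None) -> None:
        obj = {
            "meta": meta or {},
            "class_names": self.class_names,
            "provenance": self.provenance,
            "rules": [
                {
                    "conditions": [
                        {"motif": c.motif, "op": c.op, "threshold": c.threshold}
                        for c in r.conditions
                    ],
                    "outcome": r.outcome,
                    "frequency": r.frequency,
                    "error": r.error,
                    "length": r.length,
                }
                for r in self.rules
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def integerize(op: str, threshold: float) -> tuple[str, int]:
    """Convert a real split test on an integer count into an integer condition.

    ``x <= t`` becomes ``(<=, floor(t))``; ``x > t`` becomes ``(>=, floor(t) + 1)``.
    """
    if op == "<=":
        return "<=", int(math.floor(threshold))
    if op == ">":
        return ">=", int(math.floor(threshold)) + 1
    raise ValueError(f"unknown split op {op!r}")


def _merge_conditions(conds: list[Condition]) -> tuple[list[Condition], bool]:
    """Merge multiple bounds on one motif to the tightest interval.

    Returns (merged conditions in first-appearance motif order, satisfiable).
    An interval with lower bound > upper bound is unsatisfiable.
    """
    upper: dict[str, int] = {}
    lower: dict[str, int] = {}
    order: list[str] = []
    for c in conds:
        if c.motif not in order:
            order.append(c.motif)
        if c.op == "<=":
            upper[c.motif] = min(upper.get(c.motif, c.threshold), c.threshold)
        else:
            lower[c.motif] = max(lower.get(c.motif, c.threshold), c.threshold)
    merged: list[Condition] = []
    ok = True
    for m in order:
        lo = lower.get(m)
        hi = upper.get(m)
        if lo is not None and hi is not None and lo > hi:
            ok = False
        if lo is not None:
            merged.append(Condition(m, ">=", lo))
        if hi is not None:
            merged.append(Condition(m, "<=", hi))
    return merged, ok


def extract_rules(
    model: ForestModel, max_conditions: int = MAX_RULE_CONDITIONS
) -> list[Rule]:
    """One candidate rule per leaf per tree, deduplicated by condition set.

    The conjunction of split tests along the root-to-leaf path is truncated
    at ``max_conditions`` conditions, integerised, and per-motif bounds are
    merged to the tightest interval.  Outcomes are not assigned here; they
    are re-derived from covered training samples by :func:`rule_metrics`.
    """
    seen: set[tuple] = set()
    rules: list[Rule] = []
    for tree in model.trees:
        stack: list[tuple[int, list[Condition]]] = [(0, [])]
        while stack:
            node, path = stack.pop()
            f = tree.feature[node]
            if f < 0:
                conds = path[:max_conditions]
                if not conds:
                    continue  # a stump-free tree root leaf carries no rule
                merged, ok = _merge_conditions(conds)
                rule = Rule(conditions=merged, satisfiable=ok)
                k = rule.key()
                if k not in seen:
                    seen.add(k)
                    rules.append(rule)
                continue
            name = model.feature_names[f]
            thr = float(tree.threshold[node])
            op_l, t_l = integerize("<=", thr)
            op_r, t_r = integerize(">", thr)
            # push right first so the left path is explored first (stable order)
            stack.append((int(tree.right[node]), path + [Condition(name, op_r, t_r)]))
            stack.append((int(tree.left[node]), path + [Condition(name, op_l, t_l)]))
    return rules


def _coverage(rule: Rule, X: MotifCountMatrix) -> np.ndarray:
    """Boolean mask of samples satisfying all conditions."""
    if not rule.satisfiable:
        return np.zeros(X.n_samples, dtype=bool)
    mask = np.ones(X.n_samples, dtype=bool)
    pos = {m: j for j, m in enumerate(X.motif_names)}
    for c in rule.conditions:
        col = X.counts[:, pos[c.motif]]
        mask &= (col <= c.threshold) if c.op == "<=" else (col >= c.threshold)
    return mask


def _metrics_from_mask(mask: np.ndarray, labels: np.ndarray) -> tuple[str | None, float, float]:
    n = mask.size
    covered = labels[mask]
    if covered.size == 0:
        return None, 0.0, 1.0
    classes, counts = np.unique(covered, return_counts=True)
    outcome = str(classes[np.argmax(counts)])  # np.unique sorts: tie -> alphabetical
    error = float(1.0 - counts.max() / covered.size)
    return outcome, covered.size / n, error


def rule_metrics(rule: Rule, X: MotifCountMatrix) -> Rule:
    """Attach outcome, frequency and error measured on the training matrix.

    The outcome is the majority class among covered samples (ties broken
    alphabetically); a rule covering no sample gets frequency 0, error 1
    and no outcome.
    """
    mask = _coverage(rule, X)
    outcome, freq, err = _metrics_from_mask(mask, np.asarray(X.labels))
    return replace(rule, outcome=outcome, frequency=freq, error=err)


def prune_rule(
    rule: Rule, X: MotifCountMatrix, max_decay: float = DEFAULT_MAX_DECAY
) -> Rule:
    """Drop conditions whose removal barely degrades the rule's error.

    Conditions are visited last-to-first; for each, the error of the rule
    without it (outcome re-derived from the covered samples) is compared to
    the current error, and the condition is permanently removed when the
    relative decay ``(E' - E) / max(E, 1e-6)`` does not exceed
    ``max_decay``.  A rule is never pruned below one condition.
    """
    labels = np.asarray(X.labels)
    current = rule if not math.isnan(rule.error) else rule_metrics(rule, X)
    conds = list(current.conditions)
    err = current.error
    i = len(conds) - 1
    while i >= 0 and len(conds) > 1:
        trial = Rule(conditions=conds[:i] + conds[i + 1:], satisfiable=True)
        mask = _coverage(trial, X)
        _, _, err_trial = _metrics_from_mask(mask, labels)
        if (err_trial - err) / max(err, 1e-6) <= max_decay:
            conds = trial.conditions
            err = err_trial
        i -= 1
    return rule_metrics(Rule(conditions=conds, satisfiable=True), X)


def _candidate_sort_key(r: Rule):
    return (r.error, r.length, -r.frequency, r.condition_string())


def select_rules(rules: list[Rule], X: MotifCountMatrix) -> RuleSet:
    """Greedy selection of a compact, non-redundant ordered rule list.

    Candidates are sorted by (error asc, length asc, frequency desc,
    condition string); a candidate is appended iff it strictly reduces the
    training misclassification of the rule-list classifier in which the
    first matching rule wins and unmatched samples get the global majority
    class.  Passes repeat until one adds nothing.  Two rules with the same
    condition set are never co-selected.
    """
    labels = np.asarray(X.labels)
    classes, counts = np.unique(labels, return_counts=True)
    default_class = str(classes[np.argmax(counts)])

    measured = [r if not math.isnan(r.frequency) else rule_metrics(r, X) for r in rules]
    candidates = sorted(
        (r for r in measured if r.outcome is not None), key=_candidate_sort_key
    )
    cover = {id(r): _coverage(r, X) for r in candidates}

    selected: list[Rule] = []
    selected_keys: set[tuple] = set()
    unmatched = np.ones(X.n_samples, dtype=bool)
    while True:
        added = False
        for r in candidates:
            if r.key() in selected_keys:
                continue
            reach = cover[id(r)] & unmatched
            if not reach.any():
                continue
            gained = int((labels[reach] == r.outcome).sum())
            lost = int((labels[reach] == default_class).sum())
            if gained > lost:
                selected.append(r)
                selected_keys.add(r.key())
                unmatched &= ~reach
                added = True
        if not added:
            break

    return RuleSet(
        rules=selected,
        class_names=sorted(set(X.labels)),
        provenance={"default_class": default_class, "n_candidates": len(candidates)},
    )


def filter_rules(
    ruleset: RuleSet,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    max_error: float = DEFAULT_MAX_ERROR,
) -> RuleSet:
    """Keep rules with frequency >= min_frequency and error <= max_error.

    Boundary values survive ("below 8%" and "above 0.7" are read strictly).
    Classes may end up with no rules at all.
    """
    kept = [
        r
        for r in ruleset.rules
        if r.frequency >= min_frequency and r.error <= max_error
    ]
    return RuleSet(
        rules=kept,
        class_names=list(ruleset.class_names),
        provenance={
            **ruleset.provenance,
            "min_frequency": min_frequency,
            "max_error": max_error,
        },
    )


filter_ruleset = filter_rules  # historical alias


def render_rules(ruleset: RuleSet) -> str:
    """Human-readable grammar table, one line per rule.

    Conditions are joined by " & " with motifs in alphabetical order; an
    upper bound of 0 renders as "MOTIF=0".  Classes without a surviving
    rule report "No rule identified".
    """
    lines = []
    grouped = ruleset.by_class()
    for cls in ruleset.class_names:
        rules = grouped.get(cls, [])
        if not rules:
            lines.append(f"No rule identified -> {cls}")
            continue
        for r in rules:
            lines.append(f"{r.condition_string()} -> {cls}")
    return "\n".join(lines)


def mine_grammar(
    model: ForestModel,
    X: MotifCountMatrix,
    max_conditions: int = MAX_RULE_CONDITIONS,
    max_decay: float = DEFAULT_MAX_DECAY,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    max_error: float = DEFAULT_MAX_ERROR,
) -> RuleSet:
    """Full rule-mining pass: extract, measure, prune, select, filter."""
    raw = extract_rules(model, max_conditions=max_conditions)
    log.info("extracted %d unique candidate rules", len(raw))
    measured = [rule_metrics(r, X) for r in raw]
    pruned = [prune_rule(r, X, max_decay=max_decay) for r in measured]
    # pruning can collapse different paths onto the same condition set
    unique: dict[tuple, Rule] = {}
    for r in pruned:
        unique.setdefault(r.key(), r)
    selected = select_rules(list(unique.values()), X)
    log.info("selected %d rules before filtering", len(selected.rules))
    final = filter_rules(selected, min_frequency=min_frequency, max_error=max_error)
    log.info("%d rules survive frequency/error filtering", len(final.rules))
    return final
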
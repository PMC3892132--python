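"""Shared fixtures: toy grammars, an enumeration oracle, template pieces."""

from __future__ import annotations

import math

import numpy as np
import pytest

from helixgram.grammar import Grammar, Rule
from helixgram.properties import (
    load_packaged_property,
    problem_based_scaling,
    terminal_rule_probs,
    uniform_composition,
)
from helixgram.synthetic import default_two_class_specs, plant_motif_dataset
from helixgram.templates import build_helix_pair_template


def enumerate_derivation_logprob(grammar: Grammar, target, mode: str = "sum") -> float:
    """Independent oracle: exhaustive leftmost-derivation enumeration.

    Expands sentential forms breadth-first, pruning on terminal-prefix
    mismatch and on minimum yield length (every symbol yields at least
    one terminal in epsilon-free grammars).  Returns the log of the sum
    (or max) of complete-derivation probabilities, -inf if none.
    """
    target = tuple(target)
    groups = grammar.rules_by_lhs()
    terminals = grammar.terminals
    probs: list[float] = []
    stack: list[tuple[tuple[str, ...], float]] = [((grammar.start,), 1.0)]
    while stack:
        form, p = stack.pop()
        i = 0
        while i < len(form) and form[i] in terminals:
            i += 1
        prefix = form[:i]
        if len(prefix) > len(target) or prefix != target[: len(prefix)]:
            continue
        if i == len(form):
            if len(form) == len(target):
                probs.append(p)
            continue
        if len(form) > len(target):  # every symbol yields >= 1 terminal
            continue
        sym = form[i]
        for rule in groups.get(sym, ()):
            if rule.prob == 0.0:
                continue
            stack.append((form[:i] + rule.rhs + form[i + 1 :], p * rule.prob))
    if not probs:
        return float("-inf")
    return math.log(math.fsum(probs) if mode == "sum" else max(probs))


def random_proper_grammar(rng: np.random.Generator, n_nt: int | None = None) -> Grammar:
    """A random proper, epsilon-free PCFG with acyclic unary rules."""
    n_nt = n_nt or int(rng.integers(2, 7))
    nts = [f"N{i}" for i in range(n_nt)]
    terminals = ["a", "b", "c"][: int(rng.integers(1, 4))]
    rules: list[Rule] = []
    for i, nt in enumerate(nts):
        n_rules = int(rng.integers(1, 4))
        weights = rng.random(n_rules) + 0.1
        weights /= weights.sum()
        for w in weights:
            length = int(rng.integers(1, 4))
            rhs = []
            for _ in range(length):
                if rng.random() < 0.5:
                    rhs.append(terminals[int(rng.integers(0, len(terminals)))])
                else:
                    rhs.append(nts[int(rng.integers(0, n_nt))])
            # avoid unary non-terminal cycles: unary NT targets must be downstream
            if length == 1 and rhs[0] in nts and nts.index(rhs[0]) <= i:
                rhs = [terminals[int(rng.integers(0, len(terminals)))]]
            rules.append(Rule(nt, tuple(rhs), float(w)))
        # guarantee the symbol can terminate
        rules.append(Rule(nt, (terminals[int(rng.integers(0, len(terminals)))],), 0.0))
    # renormalize after appending the zero-weight terminator
    by_lhs: dict[str, float] = {}
    for r in rules:
        by_lhs[r.lhs] = by_lhs.get(r.lhs, 0.0) + r.prob
    rules = [Rule(r.lhs, r.rhs, r.prob / by_lhs[r.lhs]) for r in rules]
    return Grammar(
        terminals=frozenset(terminals),
        nonterminals=frozenset(nts),
        start="N0",
        rules=rules,
    )


@pytest.fixture(scope="session")
def vdw_terminals():
    table = load_packaged_property("FAUJ880103")
    scaled = problem_based_scaling(table, uniform_composition())
    return terminal_rule_probs(scaled)


@pytest.fixture(scope="session")
def helix_template(vdw_terminals):
    return build_helix_pair_template(terminals=vdw_terminals)


@pytest.fixture(scope="session")
def two_class_dataset():
    """The default planted-motif fixture: noise 0.2, 100 per class, seed 42."""
    return plant_motif_dataset(default_two_class_specs(0.2), 100, seed=42)


@pytest.fixture()
def ambiguous_grammar():
    """S -> A A (0.6) | B (0.4); A -> a; B -> a a.  'a a' has two derivations."""
    return Grammar(
        terminals=frozenset("a"),
        nonterminals=frozenset({"S", "A", "B"}),
        start="S",
        rules=[
            Rule("S", ("A", "A"), 0.6),
            Rule("S", ("B",), 0.4),
            Rule("A", ("a",), 1.0),
            Rule("B", ("a", "a"), 1.0),
        ],
    )


@pytest.fixture()
def branching_grammar():
    """S -> A A (0.5) | A (0.5); A -> a.  P('a') = P('a a') = 0.5."""
    return Grammar(
        terminals=frozenset("a"),
        nonterminals=frozenset({"S", "A"}),
        start="S",
        rules=[
            Rule("S", ("A", "A"), 0.5),
            Rule("S", ("A",), 0.5),
            Rule("A", ("a",), 1.0),
        ],
    )
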
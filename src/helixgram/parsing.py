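"""Probabilistic parsing of strings under a PCFG.

Two scoring modes are provided:

* ``sum`` (:func:`inside_logprob`) -- the log of the total probability of
  all derivations of the string, the quantity the training objective
  averages (a cross-entropy estimate);
* ``max`` (:func:`viterbi_parse`) -- the log probability of the single
  most likely derivation together with its parse tree, the quantity used
  for scanning and classification.

The implementation is a memoized dotted-rule recursion over the original
grammar (no visible binarization), which supports arbitrary right-hand
side lengths and epsilon rules.  Probabilities are accumulated in the
linear domain and reported as natural logs, with ``-inf`` as the
unparseable sentinel.

Grammars that allow a derivation ``A =>+ A`` consuming no input (a
non-consuming cycle) have no finite sum of derivation probabilities per
cell; ``sum`` mode raises on re-entry, while ``max`` mode prunes the
cycle (a cyclic derivation is never strictly more probable).

:func:`sample` draws a string from the grammar's distribution by seeded
leftmost derivation, the generative counterpart of the inside sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .grammar import Grammar, GrammarError, Rule
from .sequences import HelixPairSequence

__all__ = [
    "ParseTree",
    "ParseResult",
    "ParseError",
    "inside_logprob",
    "viterbi_parse",
    "sample",
    "NEG_INF",
]

NEG_INF = float("-inf")


class ParseError(ValueError):
    """Raised for inputs outside the grammar's alphabet or cyclic sum-mode grammars."""


@dataclass
class ParseTree:
    """A derivation tree node: the rule applied and its ordered children.

    Children are :class:`ParseTree` nodes for non-terminal right-hand side
    symbols and bare terminal strings for terminal ones.  The node's
    ``logprob`` is the log probability of the whole subtree (sum of the
    logs of every rule used below and including this node).
    """

    rule: Rule
    children: list[Union["ParseTree", str]] = field(default_factory=list)
    logprob: float = 0.0

    def yield_string(self) -> tuple[str, ...]:
        """Left-to-right terminal yield of the subtree."""
        out: list[str] = []
        for child in self.children:
            if isinstance(child, ParseTree):
                out.extend(child.yield_string())
            else:
                out.append(child)
        return tuple(out)

    def rules_used(self) -> list[Rule]:
        rules = [self.rule]
        for child in self.children:
            if isinstance(child, ParseTree):
                rules.extend(child.rules_used())
        return rules

    def to_newick(self, with_probs: bool = False) -> str:
        """A Newick-like bracket rendering of the tree (deterministic)."""
        parts = []
        for child in self.children:
            if isinstance(child, ParseTree):
                parts.append(child.to_newick(with_probs))
            else:
                parts.append(child)
        label = self.rule.lhs
        if with_probs:
            label += f":{self.rule.prob:.6g}"
        inner = ",".join(parts)
        return f"({inner}){label}" if parts else f"(){label}"


@dataclass(frozen=True)
class ParseResult:
    """Outcome of scoring one sequence under one grammar."""

    logprob: float
    mode: str  # "sum" or "max"
    tree: ParseTree | None = None

    @property
    def parseable(self) -> bool:
        return self.logprob > NEG_INF


def _tokens(seq: Union[str, Sequence[str], HelixPairSequence]) -> tuple[str, ...]:
    if isinstance(seq, HelixPairSequence):
        return tuple(seq.encoded)
    if isinstance(seq, str):
        return tuple(seq)
    return tuple(seq)


class _Chart:
    """Memoized dotted-rule parser over the original grammar."""

    def __init__(self, grammar: Grammar, tokens: tuple[str, ...], mode: str):
        unknown = set(tokens) - set(grammar.terminals)
        if unknown:
            raise ParseError(f"symbols outside the grammar alphabet: {sorted(unknown)}")
        self.grammar = grammar
        self.tokens = tokens
        self.mode = mode
        self.groups = grammar.rules_by_lhs()
        self.rule_index = {id(r): i for i, r in enumerate(grammar.rules)}
        self.nt_memo: dict[tuple[str, int, int], float] = {}
        self.nt_stack: set[tuple[str, int, int]] = set()
        self.seq_memo: dict[tuple[int, int, int, int], float] = {}
        # counts cycle-prune events; results that depended on a pruned
        # re-entry are not memoized (they are valid only in that context)
        self.prunes = 0
        self.min_yield = self._min_yields()

    def _min_yields(self) -> dict[str, float]:
        """Minimum terminal yield per non-terminal (0 only via epsilon)."""
        my: dict[str, float] = {nt: float("inf") for nt in self.grammar.nonterminals}
        changed = True
        while changed:
            changed = False
            for rule in self.grammar.rules:
                total = 0.0
                for sym in rule.rhs:
                    total += 1.0 if sym in self.grammar.terminals else my[sym]
                if total < my[rule.lhs]:
                    my[rule.lhs] = total
                    changed = True
        return my

    def _sym_min(self, sym: str) -> float:
        return 1.0 if sym in self.grammar.terminals else self.min_yield[sym]

    # -- probabilities -----------------------------------------------------

    def nt_prob(self, sym: str, i: int, j: int) -> float:
        """Probability mass (sum or max over derivations) of sym => tokens[i:j]."""
        if j - i < self.min_yield[sym]:
            return 0.0
        key = (sym, i, j)
        if key in self.nt_memo:
            return self.nt_memo[key]
        if key in self.nt_stack:
            if self.mode == "sum":
                raise ParseError(
                    f"grammar allows a non-consuming cycle through {sym!r}; "
                    "the inside sum diverges (use max mode or remove the cycle)"
                )
            self.prunes += 1
            return 0.0  # max mode: a cyclic derivation never wins
        self.nt_stack.add(key)
        prunes_before = self.prunes
        total = 0.0
        for rule in self.groups.get(sym, ()):
            if rule.prob == 0.0:
                continue
            ridx = self.rule_index[id(rule)]
            inner = self.seq_prob(ridx, rule, 0, i, j)
            value = rule.prob * inner
            if self.mode == "sum":
                total += value
            elif value > total:
                total = value
        self.nt_stack.discard(key)
        if self.prunes == prunes_before:
            self.nt_memo[key] = total
        return total

    def seq_prob(self, ridx: int, rule: Rule, dot: int, i: int, j: int) -> float:
        """Mass of rhs[dot:] => tokens[i:j]."""
        if dot == len(rule.rhs):
            return 1.0 if i == j else 0.0
        key = (ridx, dot, i, j)
        if key in self.seq_memo:
            return self.seq_memo[key]
        prunes_before = self.prunes
        sym = rule.rhs[dot]
        total = 0.0
        if sym in self.grammar.terminals:
            if i < j and self.tokens[i] == sym:
                total = self.seq_prob(ridx, rule, dot + 1, i + 1, j)
        else:
            remaining_min = sum(self._sym_min(s) for s in rule.rhs[dot + 1 :])
            own_min = self.min_yield[sym]
            if math.isinf(own_min) or math.isinf(remaining_min):
                lo, hi = i, i - 1  # no completion possible; empty split range
            else:
                lo, hi = i + int(own_min), j - int(remaining_min)
            for k in range(lo, hi + 1):
                left = self.nt_prob(sym, i, k)
                if left == 0.0:
                    continue
                right = self.seq_prob(ridx, rule, dot + 1, k, j)
                value = left * right
                if self.mode == "sum":
                    total += value
                elif value > total:
                    total = value
        if self.prunes == prunes_before:
            self.seq_memo[key] = total
        return total

    # -- Viterbi tree reconstruction --------------------------------------

    def build_tree(self, sym: str, i: int, j: int) -> ParseTree:
        target = self.nt_prob(sym, i, j)
        for rule in self.groups.get(sym, ()):  # first rule in template order wins ties
            if rule.prob == 0.0:
                continue
            ridx = self.rule_index[id(rule)]
            inner = self.seq_prob(ridx, rule, 0, i, j)
            if inner > 0.0 and rule.prob * inner == target:
                children, logprob = self._build_children(ridx, rule, 0, i, j)
                return ParseTree(
                    rule=rule,
                    children=children,
                    logprob=math.log(rule.prob) + logprob,
                )
        raise ParseError(f"no derivation of span ({i}, {j}) from {sym!r}")

    def _build_children(
        self, ridx: int, rule: Rule, dot: int, i: int, j: int
    ) -> tuple[list[Union[ParseTree, str]], float]:
        if dot == len(rule.rhs):
            return [], 0.0
        sym = rule.rhs[dot]
        target = self.seq_prob(ridx, rule, dot, i, j)
        if sym in self.grammar.terminals:
            rest, logprob = self._build_children(ridx, rule, dot + 1, i + 1, j)
            return [sym, *rest], logprob
        for k in range(i, j + 1):
            left = self.nt_prob(sym, i, k)
            right = self.seq_prob(ridx, rule, dot + 1, k, j)
            if left > 0.0 and left * right == target:
                subtree = self.build_tree(sym, i, k)
                rest, logprob = self._build_children(ridx, rule, dot + 1, k, j)
                return [subtree, *rest], subtree.logprob + logprob
        raise ParseError("inconsistent Viterbi chart during tree reconstruction")


def inside_logprob(
    grammar: Grammar, seq: Union[str, Sequence[str], HelixPairSequence]
) -> ParseResult:
    """Natural log of the total probability of all derivations of ``seq``.

    Returns ``-inf`` if the string is outside the grammar's language.
    """
    tokens = _tokens(seq)
    chart = _Chart(grammar, tokens, mode="sum")
    p = chart.nt_prob(grammar.start, 0, len(tokens))
    return ParseResult(logprob=math.log(p) if p > 0.0 else NEG_INF, mode="sum")


def viterbi_parse(
    grammar: Grammar,
    seq: Union[str, Sequence[str], HelixPairSequence],
    with_tree: bool = True,
) -> ParseResult:
    """Log probability of the most likely derivation, plus its tree.

    Ties between derivations are broken deterministically: the first rule
    in template order, then the earliest split point.
    """
    tokens = _tokens(seq)
    chart = _Chart(grammar, tokens, mode="max")
    p = chart.nt_prob(grammar.start, 0, len(tokens))
    if p <= 0.0:
        return ParseResult(logprob=NEG_INF, mode="max")
    tree = chart.build_tree(grammar.start, 0, len(tokens)) if with_tree else None
    return ParseResult(logprob=math.log(p), mode="max", tree=tree)


def sample(
    grammar: Grammar,
    rng: Union[int, np.random.Generator],
    max_steps: int = 500,
) -> str:
    """Draw one terminal string by seeded leftmost derivation.

    ``max_steps`` caps the number of rule applications to guard against
    inconsistent grammars whose derivations fail to terminate.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    groups = grammar.rules_by_lhs()
    stack: list[str] = [grammar.start]
    out: list[str] = []
    steps = 0
    while stack:
        sym = stack.pop()
        if sym in grammar.terminals:
            out.append(sym)
            continue
        rules = groups.get(sym)
        if not rules:
            raise GrammarError(f"non-terminal {sym!r} has no rules")
        steps += 1
        if steps > max_steps:
            raise ParseError(
                f"derivation exceeded {max_steps} rule applications; "
                "possibly inconsistent grammar"
            )
        u = rng.random()
        acc = 0.0
        chosen = rules[-1]
        for rule in rules:
            acc += rule.prob
            if u < acc:
                chosen = rule
                break
        stack.extend(reversed(chosen.rhs))
    return "".join(out)
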
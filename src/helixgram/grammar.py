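"""Weighted context-free grammar data model.

A probabilistic context-free grammar (PCFG) is a CFG whose rules carry
probabilities.  The grammar is *proper* when, for every left-hand side,
the probabilities of its alternative rules sum to one.  This module
provides the grammar container together with properness validation,
per-LHS normalization, low-probability rule pruning and a plain-text
serialization format.

Symbols are plain strings; a :class:`Grammar` declares which strings are
terminals and which are non-terminals (the two sets are disjoint).  The
empty right-hand side (an epsilon rule) is written ``@`` in grammar files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "AA_ALPHABET",
    "BRACKET_SYMBOLS",
    "Symbol",
    "Rule",
    "Grammar",
    "PropernessReport",
    "GrammarError",
    "validate_properness",
    "normalize",
    "prune",
    "read_grammar",
    "write_grammar",
    "grammar_to_dict",
    "grammar_from_dict",
]

#: The 20 standard amino acids, in the order AAindex uses.
AA_ALPHABET: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Helix boundary markers: "[h1]{h2}".
BRACKET_SYMBOLS: tuple[str, ...] = ("[", "]", "{", "}")

#: Default tolerance for properness checks.
PROPERNESS_TOL = 1e-9

#: Token standing for the empty right-hand side in grammar files.
EPSILON_TOKEN = "@"


class GrammarError(ValueError):
    """Raised for structurally invalid grammars or malformed grammar files."""


@dataclass(frozen=True)
class Symbol:
    """A grammar symbol: a name plus its terminal/non-terminal status."""

    name: str
    is_terminal: bool

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class Rule:
    """A context-free production ``lhs -> rhs`` with probability ``prob``.

    ``rhs`` is an ordered tuple of symbol names; the empty tuple encodes an
    epsilon rule.  ``prob`` may be any non-negative weight before
    normalization; in a proper grammar each LHS group's probabilities sum
    to one (so every probability lies in [0, 1]).
    """

    lhs: str
    rhs: tuple[str, ...]
    prob: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rhs", tuple(self.rhs))
        if not self.prob >= 0.0:
            raise GrammarError(
                f"rule {self.lhs} -> {' '.join(self.rhs) or EPSILON_TOKEN}: "
                f"negative or invalid probability {self.prob!r}"
            )

    def format(self) -> str:
        rhs = " ".join(self.rhs) if self.rhs else EPSILON_TOKEN
        return f"{self.lhs} -> {rhs} # {self.prob!r}"


@dataclass
class Grammar:
    """A weighted CFG: terminal/non-terminal sets, start symbol and rules.

    ``frozen_lhs`` lists left-hand sides whose rule probabilities are fixed
    (terminal rules derived from an amino-acid property) and therefore not
    subject to inference.
    """

    terminals: frozenset[str]
    nonterminals: frozenset[str]
    start: str
    rules: list[Rule]
    frozen_lhs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.terminals = frozenset(self.terminals)
        self.nonterminals = frozenset(self.nonterminals)
        self.frozen_lhs = frozenset(self.frozen_lhs)
        overlap = self.terminals & self.nonterminals
        if overlap:
            raise GrammarError(f"symbols both terminal and non-terminal: {sorted(overlap)}")
        if self.start not in self.nonterminals:
            raise GrammarError(f"start symbol {self.start!r} is not a declared non-terminal")
        if not self.frozen_lhs <= self.nonterminals:
            raise GrammarError("frozen_lhs contains undeclared non-terminals")
        for rule in self.rules:
            if rule.lhs not in self.nonterminals:
                raise GrammarError(f"rule LHS {rule.lhs!r} is not a declared non-terminal")
            for sym in rule.rhs:
                if sym not in self.terminals and sym not in self.nonterminals:
                    raise GrammarError(
                        f"rule {rule.lhs} -> {' '.join(rule.rhs)}: unknown symbol {sym!r}"
                    )

    # -- structure helpers -------------------------------------------------

    def rules_by_lhs(self) -> dict[str, list[Rule]]:
        """Rules grouped by LHS, preserving file/template order within groups."""
        groups: dict[str, list[Rule]] = {}
        for rule in self.rules:
            groups.setdefault(rule.lhs, []).append(rule)
        return groups

    def symbol(self, name: str) -> Symbol:
        if name in self.terminals:
            return Symbol(name, True)
        if name in self.nonterminals:
            return Symbol(name, False)
        raise KeyError(name)

    @property
    def evolvable_lhs(self) -> list[str]:
        """Non-frozen LHS symbols in first-appearance order."""
        seen: list[str] = []
        for rule in self.rules:
            if rule.lhs not in self.frozen_lhs and rule.lhs not in seen:
                seen.append(rule.lhs)
        return seen

    def evolvable_rule_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.rules) if r.lhs not in self.frozen_lhs]

    def copy_with_probs(self, probs: Iterable[float]) -> "Grammar":
        """A new grammar with per-rule probabilities replaced positionally."""
        probs = list(probs)
        if len(probs) != len(self.rules):
            raise GrammarError(f"expected {len(self.rules)} probabilities, got {len(probs)}")
        rules = [replace(r, prob=float(p)) for r, p in zip(self.rules, probs)]
        return Grammar(self.terminals, self.nonterminals, self.start, rules, self.frozen_lhs)


@dataclass(frozen=True)
class PropernessReport:
    """Per-LHS probability sums and a global pass/fail at tolerance ``tol``."""

    lhs_sums: Mapping[str, float]
    tol: float
    is_proper: bool

    def failing_lhs(self) -> list[str]:
        return [lhs for lhs, s in self.lhs_sums.items() if abs(s - 1.0) > self.tol]


def validate_properness(grammar: Grammar, tol: float = PROPERNESS_TOL) -> PropernessReport:
    """Check that every LHS group's rule probabilities sum to one.

    Purely a reporting operation; it never raises on an improper grammar.
    """
    sums = {lhs: math.fsum(r.prob for r in group) for lhs, group in grammar.rules_by_lhs().items()}
    ok = all(abs(s - 1.0) <= tol for s in sums.values())
    return PropernessReport(lhs_sums=sums, tol=tol, is_proper=ok)


def normalize(grammar: Grammar) -> Grammar:
    """Divide each LHS group's weights by their sum, yielding a proper grammar.

    Raises :class:`GrammarError` if any group carries zero total weight,
    naming the offending LHS.
    """
    sums = {lhs: math.fsum(r.prob for r in group) for lhs, group in grammar.rules_by_lhs().items()}
    for lhs, total in sums.items():
        if total <= 0.0:
            raise GrammarError(f"cannot normalize: all rules of {lhs!r} have zero weight")
    # groups already summing to 1 within tolerance are left untouched,
    # which makes normalize exactly idempotent
    rules = [
        r if abs(sums[r.lhs] - 1.0) <= PROPERNESS_TOL else replace(r, prob=r.prob / sums[r.lhs])
        for r in grammar.rules
    ]
    return Grammar(grammar.terminals, grammar.nonterminals, grammar.start, rules, grammar.frozen_lhs)


def prune(grammar: Grammar, threshold: float = 0.05) -> Grammar:
    """Drop rules with probability below ``threshold`` and renormalize.

    If pruning would empty an LHS group entirely, the group's single
    highest-probability rule is kept instead (first by rule order on ties),
    so the output grammar always has at least one rule per LHS and is proper.
    """
    groups = grammar.rules_by_lhs()
    keep: set[int] = set()
    index_of = {id(r): i for i, r in enumerate(grammar.rules)}
    for group in groups.values():
        surviving = [r for r in group if r.prob >= threshold]
        if not surviving:
            surviving = [max(group, key=lambda r: r.prob)]
        keep.update(index_of[id(r)] for r in surviving)
    rules = [r for i, r in enumerate(grammar.rules) if i in keep]
    pruned = Grammar(grammar.terminals, grammar.nonterminals, grammar.start, rules, grammar.frozen_lhs)
    return normalize(pruned)


# -- serialization ---------------------------------------------------------


def write_grammar(grammar: Grammar, path) -> None:
    """Write the grammar in the one-rule-per-line text format.

    Header lines declare the start symbol, the terminal and non-terminal
    sets and the frozen LHS set; probabilities are written with ``repr`` so
    the write/read round trip is bit-exact.
    """
    lines = [
        "# helixgram grammar",
        f"start: {grammar.start}",
        "terminals: " + " ".join(sorted(grammar.terminals)),
        "nonterminals: " + " ".join(sorted(grammar.nonterminals)),
        "frozen: " + " ".join(sorted(grammar.frozen_lhs)),
    ]
    lines.extend(rule.format() for rule in grammar.rules)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_grammar(path) -> Grammar:
    """Parse a grammar file written by :func:`write_grammar`.

    Unknown symbols and malformed lines raise :class:`GrammarError` naming
    the line; an improper grammar is read as-is (a warning concern for the
    caller, not a fatal error).
    """
    headers: dict[str, str] = {}
    rules: list[Rule] = []
    with open(path) as fh:
        raw_lines = fh.readlines()
    terminals: frozenset[str] = frozenset()
    nonterminals: frozenset[str] = frozenset()
    for lineno, raw in enumerate(raw_lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        head, sep, tail = line.partition(":")
        if sep and head in {"start", "terminals", "nonterminals", "frozen"} and "->" not in line:
            headers[head] = tail.strip()
            if head == "terminals":
                terminals = frozenset(tail.split())
            elif head == "nonterminals":
                nonterminals = frozenset(tail.split())
            continue
        if "->" not in line:
            raise GrammarError(f"{path}:{lineno}: malformed line (no '->'): {line!r}")
        lhs_part, _, rest = line.partition("->")
        body, _, prob_part = rest.partition("#")
        lhs = lhs_part.strip()
        rhs_tokens = body.split()
        if rhs_tokens == [EPSILON_TOKEN]:
            rhs: tuple[str, ...] = ()
        else:
            rhs = tuple(rhs_tokens)
        if not prob_part.strip():
            raise GrammarError(f"{path}:{lineno}: missing probability: {line!r}")
        try:
            prob = float(prob_part.strip())
        except ValueError as exc:
            raise GrammarError(f"{path}:{lineno}: bad probability {prob_part.strip()!r}") from exc
        for sym in (lhs, *rhs):
            if sym not in terminals and sym not in nonterminals:
                raise GrammarError(f"{path}:{lineno}: undeclared symbol {sym!r}")
        rules.append(Rule(lhs, rhs, prob))
    if "start" not in headers:
        raise GrammarError(f"{path}: missing 'start:' header")
    return Grammar(
        terminals=terminals,
        nonterminals=nonterminals,
        start=headers["start"],
        rules=rules,
        frozen_lhs=frozenset(headers.get("frozen", "").split()),
    )


def grammar_to_dict(grammar: Grammar) -> dict:
    """Lossless structured export (JSON-compatible) of the grammar."""
    return {
        "start": grammar.start,
        "terminals": sorted(grammar.terminals),
        "nonterminals": sorted(grammar.nonterminals),
        "frozen_lhs": sorted(grammar.frozen_lhs),
        "rules": [{"lhs": r.lhs, "rhs": list(r.rhs), "prob": r.prob} for r in grammar.rules],
    }


def grammar_from_dict(data: Mapping) -> Grammar:
    return Grammar(
        terminals=frozenset(data["terminals"]),
        nonterminals=frozenset(data["nonterminals"]),
        start=data["start"],
        rules=[Rule(r["lhs"], tuple(r["rhs"]), float(r["prob"])) for r in data["rules"]],
        frozen_lhs=frozenset(data.get("frozen_lhs", ())),
    )
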
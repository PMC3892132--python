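"""Averaged a-priori parse trees and stem statistics.

Every parse tree of the helix-pair grammar has exactly one *stem*: the
chain of Interface/Outerface symbols from the start symbol down to
``Turn``.  Conditional on a stem path, each derivation step emits one or
two residues per helix whose property level is a random variable under
the grammar's rule probabilities.  Assigning numerical values to the
property levels (Low = 0, Medium = 1, High = 2) gives an expected level
per emitted position -- the averaged *a priori* parse tree -- which can
be read as the grammar's preferred property profile along the contact
site, independent of any particular sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .grammar import Grammar, GrammarError
from .parsing import ParseTree, viterbi_parse
from .sequences import HelixPairSequence
from .templates import stem_children

__all__ = [
    "PropertyLevelMap",
    "StemPath",
    "AvgTreeNode",
    "AvgTree",
    "expected_context_level",
    "average_a_priori_tree",
    "stem_statistics",
    "extract_stem",
    "render_tree",
]

#: Numerical property-level values.
DEFAULT_LEVELS: dict[str, float] = {"Low": 0.0, "Medium": 1.0, "High": 2.0}


@dataclass(frozen=True)
class PropertyLevelMap:
    """Level values for property non-terminals; ``Any`` gets the middle
    value (its uniform expectation) unless configured otherwise."""

    val: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    any_value: float = 1.0

    def level_of(self, sym: str) -> float | None:
        if sym in self.val:
            return float(self.val[sym])
        if sym == "Any":
            return self.any_value
        return None


@dataclass(frozen=True)
class StemPath:
    """An Interface/Outerface chain from the start symbol to Turn."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        for parent, child in zip(self.symbols, self.symbols[1:]):
            allowed = {c for _, c, _ in stem_children(parent)}
            if child not in allowed:
                raise GrammarError(
                    f"stem step {parent} -> {child} violates context compatibility "
                    f"(allowed children: {sorted(allowed)})"
                )


@dataclass(frozen=True)
class AvgTreeNode:
    """One emitted position of the averaged tree."""

    helix: int  # 1 or 2
    position: int  # 0-based coordinate within its helix's stem emissions
    expected: float
    rounded: int


@dataclass(frozen=True)
class AvgTree:
    """Expected property levels along a stem, ordered by sequence coordinate."""

    stem: StemPath
    nodes: tuple[AvgTreeNode, ...]

    def helix_nodes(self, helix: int) -> tuple[AvgTreeNode, ...]:
        return tuple(n for n in self.nodes if n.helix == helix)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _position_level(
    grammar: Grammar, sym: str, position: int, levels: PropertyLevelMap
) -> float:
    """Expected level of position ``position`` (1-based) emitted by a
    context symbol: a property non-terminal directly, or a Double symbol
    mixed over its own two-residue expansions."""
    direct = levels.level_of(sym)
    if direct is not None:
        if position != 1:
            raise GrammarError(f"{sym} emits one residue; position {position} invalid")
        return direct
    rules = grammar.rules_by_lhs().get(sym)
    if not rules:
        raise GrammarError(f"unknown context symbol {sym!r}")
    total = 0.0
    for rule in rules:
        if position > len(rule.rhs):
            raise GrammarError(f"{sym} rule has no position {position}")
        child = rule.rhs[position - 1]
        lv = levels.level_of(child)
        if lv is None:
            raise GrammarError(f"{sym} expands to non-level symbol {child!r}")
        total += rule.prob * lv
    return total


def _context_rules(grammar: Grammar, parent: str, child: str | None):
    """Parent's stem-shaped rules (left ctx, stem child, right ctx),
    optionally restricted to a given child, with renormalized weights."""
    rules = [r for r in grammar.rules_by_lhs().get(parent, []) if len(r.rhs) == 3]
    if child is not None:
        rules = [r for r in rules if r.rhs[1] == child]
    if not rules:
        raise GrammarError(f"no context rules for {parent!r}" + (f" with child {child!r}" if child else ""))
    total = math.fsum(r.prob for r in rules)
    if total <= 0:
        raise GrammarError(f"context rules of {parent!r} carry zero mass")
    return [(r, r.prob / total) for r in rules]


def expected_context_level(
    grammar: Grammar,
    parent_symbol: str,
    side: str,
    position: int = 1,
    child: str | None = None,
    levels: PropertyLevelMap | None = None,
) -> float:
    """Expected property level of one context position emitted by a stem symbol.

    Mixes over the parent's rule alternatives (renormalized, optionally
    conditioned on the stem child) and, for two-residue Double contexts,
    over the Double symbols' own expansions.
    """
    levels = levels or PropertyLevelMap()
    if side not in ("left", "right"):
        raise GrammarError("side must be 'left' or 'right'")
    total = 0.0
    for rule, w in _context_rules(grammar, parent_symbol, child):
        ctx = rule.rhs[0] if side == "left" else rule.rhs[2]
        total += w * _position_level(grammar, ctx, position, levels)
    return total


def _context_size(grammar: Grammar, sym: str, levels: PropertyLevelMap) -> int:
    if levels.level_of(sym) is not None:
        return 1
    rules = grammar.rules_by_lhs().get(sym)
    if not rules:
        raise GrammarError(f"unknown context symbol {sym!r}")
    return len(rules[0].rhs)


def average_a_priori_tree(
    grammar: Grammar,
    stem: StemPath | Sequence[str],
    levels: PropertyLevelMap | None = None,
) -> AvgTree:
    """Expected property level at every position emitted along a stem path.

    Helix-1 positions are emitted outermost-first (N to C); helix-2
    contexts nest the other way, so their sequence order is the reverse
    of the stem order.  Rounding of expected levels is to the nearest
    integer with ties up.
    """
    if not isinstance(stem, StemPath):
        stem = StemPath(tuple(stem))
    levels = levels or PropertyLevelMap()
    h1: list[float] = []
    h2_rev: list[float] = []
    for t, parent in enumerate(stem.symbols):
        child = stem.symbols[t + 1] if t + 1 < len(stem.symbols) else None
        try:
            rules = _context_rules(grammar, parent, child)
        except GrammarError:
            if child is None:
                break  # parent exits via Turn only; no context emitted
            raise
        left_sym = rules[0][0].rhs[0]
        right_sym = rules[0][0].rhs[2]
        for pos in range(1, _context_size(grammar, left_sym, levels) + 1):
            h1.append(
                math.fsum(
                    w * _position_level(grammar, r.rhs[0], pos, levels) for r, w in rules
                )
            )
        right_levels = [
            math.fsum(w * _position_level(grammar, r.rhs[2], pos, levels) for r, w in rules)
            for pos in range(1, _context_size(grammar, right_sym, levels) + 1)
        ]
        h2_rev.append(right_levels)
    h2: list[float] = [lv for step in reversed(h2_rev) for lv in step]
    nodes = [
        AvgTreeNode(1, i, e, _round_half_up(e)) for i, e in enumerate(h1)
    ] + [AvgTreeNode(2, i, e, _round_half_up(e)) for i, e in enumerate(h2)]
    return AvgTree(stem=stem, nodes=tuple(nodes))


def extract_stem(tree: ParseTree, stem_prefixes: tuple[str, ...] = ("Interface", "Outerface")) -> StemPath:
    """The Interface/Outerface chain of one parse tree, start to Turn."""
    chain: list[str] = []

    def descend(node: ParseTree) -> None:
        for child in node.children:
            if isinstance(child, ParseTree):
                name = child.rule.lhs
                if name.partition("_")[0] in stem_prefixes:
                    chain.append(name)
                    descend(child)
                    return
                descend(child)

    descend(tree)
    return StemPath(tuple(chain))


def stem_statistics(
    grammar: Grammar, sequences: Sequence[HelixPairSequence]
) -> tuple[dict[tuple[str, ...], float], list[str]]:
    """Stem-path frequencies among Viterbi parses of a sequence set.

    Returns (frequencies over parseable sequences, ids of unparseable
    sequences).  Frequencies sum to one when any sequence parses.
    """
    tally: dict[tuple[str, ...], int] = {}
    unparseable: list[str] = []
    n_ok = 0
    for seq in sequences:
        result = viterbi_parse(grammar, seq)
        if not result.parseable or result.tree is None:
            unparseable.append(seq.id)
            continue
        stem = extract_stem(result.tree).symbols
        tally[stem] = tally.get(stem, 0) + 1
        n_ok += 1
    freqs = {stem: c / n_ok for stem, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))}
    return freqs, unparseable


def render_tree(tree: AvgTree | ParseTree, rounded: bool = False) -> str:
    """Deterministic text rendering with a Newick-like summary line.

    For an :class:`AvgTree` the branch lengths are the expected (or
    rounded) property levels.
    """
    if isinstance(tree, ParseTree):
        lines = []

        def walk(node: ParseTree, depth: int) -> None:
            lines.append("  " * depth + node.rule.lhs)
            for child in node.children:
                if isinstance(child, ParseTree):
                    walk(child, depth + 1)
                else:
                    lines.append("  " * (depth + 1) + child)

        walk(tree, 0)
        lines.append(tree.to_newick())
        return "\n".join(lines) + "\n"

    lines = ["stem: " + (" -> ".join(tree.stem.symbols) if tree.stem.symbols else "(root only)")]
    for helix in (1, 2):
        nodes = tree.helix_nodes(helix)
        lines.append(f"helix {helix}:")
        for node in nodes:
            length = node.rounded if rounded else node.expected
            lines.append(f"  pos {node.position}: {length:g}")
    newick_parts = [
        ",".join(f"p{n.position}:{(n.rounded if rounded else n.expected):g}" for n in tree.helix_nodes(h))
        for h in (1, 2)
    ]
    lines.append(f"(({newick_parts[0]})helix1,({newick_parts[1]})helix2)stem;")
    return "\n".join(lines) + "\n"
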
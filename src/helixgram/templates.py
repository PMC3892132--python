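"""Helix-pair grammar templates.

The helix-pair template is a PCFG skeleton over bracketed strings
``[h1]{h2}`` whose core is a *stem* of alternating ``Interface`` /
``Outerface`` non-terminals.  Each stem symbol carries a two-letter
subscript (``S`` single, ``D`` double) recording how many residues its
parent emitted around it on the helix-1 (left) and helix-2 (right) side.
A parent whose subscript on a side is ``S`` must emit a double context on
that side next, while after ``D`` both single and double are allowed, so
consecutive emissions on one helix always span 3 or 4 residues -- one
full turn of an alpha helix (mean periodicity 3.6).

Concrete contexts are property non-terminals (``Low``/``Medium``/``High``,
single residue) or ``Double_X`` symbols (two residues); ``Turn`` closes
the stem across the ``]`` ``{`` boundary, and ``Whatever`` absorbs
unconstrained residues at the four helix ends.

Terminal rules (property non-terminal -> amino acid) are frozen; all
other rule groups are initialized uniform and subject to inference.

Two ablation variants are provided: ``no_dependency`` removes the
helix-2 context from every stem rule and generates helix 2 by an
independent chain, and ``unconstrained`` is a right-linear grammar with
no periodicity structure at all.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

from .grammar import BRACKET_SYMBOLS, Grammar, GrammarError, Rule
from .properties import TerminalRuleSet

__all__ = [
    "TemplateConfig",
    "STEM_SYMBOLS",
    "build_helix_pair_template",
    "build_variant",
    "build_template",
    "stem_children",
]

#: The eight stem non-terminals, in template order.
STEM_SYMBOLS: tuple[str, ...] = tuple(
    f"{family}_{a}{b}"
    for family in ("Interface", "Outerface")
    for a in "DS"
    for b in "DS"
)

#: Context sizes allowed after a given subscript on the same helix side,
#: keeping each complete helix turn 3 or 4 residues long.
_NEXT_SIZE = {"S": ("D",), "D": ("S", "D")}

_PNT = ("Low", "Medium", "High")

VARIANTS = ("helix_pair", "no_dependency", "unconstrained")


@dataclass(frozen=True)
class TemplateConfig:
    """Structural choices for the helix-pair template.

    ``n_double_symbols`` controls how many distinct two-residue context
    symbols the grammar may specialize during inference (3 in the default
    model).
    """

    n_double_symbols: int = 3
    variant: str = "helix_pair"
    stem_symbols: tuple[str, ...] = field(default=STEM_SYMBOLS)

    def __post_init__(self) -> None:
        if self.n_double_symbols < 1:
            raise GrammarError("n_double_symbols must be >= 1")
        if self.variant not in VARIANTS:
            raise GrammarError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def double_symbols(self) -> tuple[str, ...]:
        letters = string.ascii_uppercase
        return tuple(f"Double_{letters[i]}" for i in range(self.n_double_symbols))


def _other_family(family: str) -> str:
    return "Outerface" if family == "Interface" else "Interface"


def stem_children(symbol: str) -> list[tuple[str, str, str]]:
    """Context-compatible (left_size, child, right_size) triples for a stem symbol.

    E.g. ``Outerface_SS`` admits only ``Interface_DD`` as child: after a
    single context on each side, only double contexts keep the turn length
    in {3, 4}.
    """
    family, _, sub = symbol.partition("_")
    left, right = sub[0], sub[1]
    child_family = _other_family(family)
    out = []
    for c in _NEXT_SIZE[left]:
        for d in _NEXT_SIZE[right]:
            out.append((c, f"{child_family}_{c}{d}", d))
    return out


def _terminal_rules(terminals: TerminalRuleSet) -> list[Rule]:
    rules = []
    alphabet = terminals.alphabet()
    for level in _PNT:
        row = terminals.row(level)
        for aa in alphabet:
            rules.append(Rule(level, (aa,), row[aa]))
    for aa in alphabet:
        rules.append(Rule("Any", (aa,), terminals.any_probs[aa]))
    return rules


def _check_terminals(terminals: TerminalRuleSet) -> None:
    import math

    alphabet = terminals.alphabet()
    for level in _PNT:
        row = terminals.row(level)
        if abs(math.fsum(row.get(aa, 0.0) for aa in alphabet) - 1.0) > 1e-9:
            raise GrammarError(f"terminal rule row {level} is not proper")


def _context_symbols(size: str, doubles: tuple[str, ...]) -> tuple[str, ...]:
    return _PNT if size == "S" else doubles


def build_helix_pair_template(
    cfg: TemplateConfig | None = None,
    terminals: TerminalRuleSet | None = None,
) -> Grammar:
    """Build the full helix-pair grammar with uniform evolvable groups.

    The returned grammar is proper; its frozen LHS set contains the
    property non-terminals (terminal rules), and every other group is
    initialized uniform.
    """
    cfg = cfg or TemplateConfig()
    if terminals is None:
        raise GrammarError("a terminal rule set is required")
    _check_terminals(terminals)
    if cfg.variant != "helix_pair":
        return build_variant(cfg, terminals)

    doubles = cfg.double_symbols
    rules: list[Rule] = _terminal_rules(terminals)

    # two-residue contexts: every ordered pair of property levels
    for dsym in doubles:
        pairs = [(p, q) for p in _PNT for q in _PNT]
        for p, q in pairs:
            rules.append(Rule(dsym, (p, q), 1.0 / len(pairs)))

    # start wraps the stem with the helix-1 opening and helix-2 closing bracket
    for root in cfg.stem_symbols:
        rules.append(Rule("Start", ("[", "Whatever", root, "Whatever", "}"), 1.0 / len(cfg.stem_symbols)))

    # stem: emit left (helix 1) and right (helix 2) contexts around the child
    for sym in cfg.stem_symbols:
        options: list[tuple[str, str, str]] = []
        for c, child, d in stem_children(sym):
            for left in _context_symbols(c, doubles):
                for right in _context_symbols(d, doubles):
                    options.append((left, child, right))
        n = len(options) + 1  # + the Turn exit
        for left, child, right in options:
            rules.append(Rule(sym, (left, child, right), 1.0 / n))
        rules.append(Rule(sym, ("Turn",), 1.0 / n))

    rules.append(Rule("Turn", ("Whatever", "]", "{", "Whatever"), 1.0))
    rules.append(Rule("Whatever", ("Any", "Whatever"), 0.5))
    rules.append(Rule("Whatever", (), 0.5))

    nonterminals = (
        set(_PNT)
        | set(doubles)
        | set(cfg.stem_symbols)
        | {"Turn", "Whatever", "Any", "Start"}
    )
    return Grammar(
        terminals=frozenset(terminals.alphabet()) | frozenset(BRACKET_SYMBOLS),
        nonterminals=frozenset(nonterminals),
        start="Start",
        rules=rules,
        frozen_lhs=frozenset(("Low", "Medium", "High", "Any")),
    )


def build_variant(cfg: TemplateConfig, terminals: TerminalRuleSet) -> Grammar:
    """Build an ablation variant (``no_dependency`` or ``unconstrained``)."""
    _check_terminals(terminals)
    if cfg.variant == "no_dependency":
        return _build_no_dependency(cfg, terminals)
    if cfg.variant == "unconstrained":
        return _build_unconstrained(cfg, terminals)
    return build_helix_pair_template(cfg, terminals)


def _build_no_dependency(cfg: TemplateConfig, terminals: TerminalRuleSet) -> Grammar:
    """Helix periodicity without inter-helix dependency.

    Stem rules keep only their helix-1 context; helix 2 is generated by an
    independent single-subscript chain hanging off ``Turn`` and terminated
    by an epsilon rule.
    """
    doubles = cfg.double_symbols
    h1_syms = tuple(f"{fam}_{a}" for fam in ("Interface", "Outerface") for a in "DS")
    h2_syms = tuple(f"H2{fam}_{a}" for fam in ("Interface", "Outerface") for a in "DS")
    rules: list[Rule] = _terminal_rules(terminals)

    for dsym in doubles:
        pairs = [(p, q) for p in _PNT for q in _PNT]
        for p, q in pairs:
            rules.append(Rule(dsym, (p, q), 1.0 / len(pairs)))

    for root in h1_syms:
        rules.append(Rule("Start", ("[", "Whatever", root, "Whatever", "}"), 1.0 / len(h1_syms)))

    def chain_rules(syms: tuple[str, ...], terminator: tuple[str, ...]) -> None:
        for sym in syms:
            fam, _, a = sym.partition("_")
            fam = fam.removeprefix("H2")
            prefix = "H2" if sym.startswith("H2") else ""
            child_family = prefix + _other_family(fam)
            options: list[tuple[str, str]] = []
            for c in _NEXT_SIZE[a]:
                for ctx in _context_symbols(c, doubles):
                    options.append((ctx, f"{child_family}_{c}"))
            n = len(options) + 1
            for ctx, child in options:
                rules.append(Rule(sym, (ctx, child), 1.0 / n))
            rules.append(Rule(sym, terminator, 1.0 / n))

    chain_rules(h1_syms, ("Turn",))
    for root in h2_syms:
        rules.append(Rule("Turn", ("Whatever", "]", "{", "Whatever", root), 1.0 / len(h2_syms)))
    chain_rules(h2_syms, ())  # helix-2 chain ends with an epsilon rule

    rules.append(Rule("Whatever", ("Any", "Whatever"), 0.5))
    rules.append(Rule("Whatever", (), 0.5))

    nonterminals = (
        set(_PNT)
        | set(doubles)
        | set(h1_syms)
        | set(h2_syms)
        | {"Turn", "Whatever", "Any", "Start"}
    )
    return Grammar(
        terminals=frozenset(terminals.alphabet()) | frozenset(BRACKET_SYMBOLS),
        nonterminals=frozenset(nonterminals),
        start="Start",
        rules=rules,
        frozen_lhs=frozenset(("Low", "Medium", "High", "Any")),
    )


def _build_unconstrained(cfg: TemplateConfig, terminals: TerminalRuleSet) -> Grammar:
    """Right-linear grammar: one symbol from {Low, Medium, High, Any, Turn}
    appended per derivation step, no periodicity or pairing structure."""
    rules: list[Rule] = _terminal_rules(terminals)
    rules.append(Rule("Start", ("[", "Chain", "}"), 1.0))
    appendable = ("Low", "Medium", "High", "Any", "Turn")
    n = len(appendable) + 1
    for sym in appendable:
        rules.append(Rule("Chain", (sym, "Chain"), 1.0 / n))
    rules.append(Rule("Chain", (), 1.0 / n))
    rules.append(Rule("Turn", ("]", "{"), 1.0))

    nonterminals = set(_PNT) | {"Any", "Chain", "Turn", "Start"}
    return Grammar(
        terminals=frozenset(terminals.alphabet()) | frozenset(BRACKET_SYMBOLS),
        nonterminals=frozenset(nonterminals),
        start="Start",
        rules=rules,
        frozen_lhs=frozenset(("Low", "Medium", "High", "Any", "Turn", "Start")),
    )


def build_template(
    terminals: TerminalRuleSet,
    variant: str = "helix_pair",
    n_double_symbols: int = 3,
) -> Grammar:
    """Convenience wrapper: build any variant from a terminal rule set."""
    cfg = TemplateConfig(n_double_symbols=n_double_symbols, variant=variant)
    return build_helix_pair_template(cfg, terminals)
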
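"""Compiled batch scoring of many sequences under many rule assignments.

Grammar-rule inference evaluates the same grammar *structure* thousands
of times with different rule probabilities (one candidate per individual
in the population) over the same training sequences.  This module
compiles a grammar once into a binarized, epsilon-eliminated form whose
transformed rule probabilities are monomials in the original rule
probabilities, and then runs a single CYK-style inside (or max) pass
whose chart cells are arrays over ``sequences x candidates``.

The compilation is invisible in the reported probabilities: for any
proper probability assignment the scores equal those of the reference
parser in :mod:`helixgram.parsing` (asserted in the test suite).

Restrictions (met by every grammar this package builds):

* epsilon rules are allowed only on symbols that are nullable *directly*
  (no symbol may derive the empty string through a chain of other
  nullable symbols);
* unary non-terminal rules must be acyclic;
* the start symbol must not be nullable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .grammar import Grammar, GrammarError
from .sequences import HelixPairSequence

__all__ = ["CompiledGrammar", "batch_logprobs"]

NEG_INF = float("-inf")


def _tokens(seq: Union[str, Sequence[str], HelixPairSequence]) -> tuple[str, ...]:
    if isinstance(seq, HelixPairSequence):
        return tuple(seq.encoded)
    if isinstance(seq, str):
        return tuple(seq)
    return tuple(seq)


@dataclass(frozen=True)
class _Binary:
    parent: int
    left: int
    right: int
    mono: tuple[int, ...]


@dataclass(frozen=True)
class _Unary:
    parent: int
    child: int
    mono: tuple[int, ...]


class CompiledGrammar:
    """A grammar compiled for vectorized inside/max scoring.

    Transformed rules carry *monomials*: tuples of original rule indices
    whose probability product is the transformed rule's probability.
    Binarization intermediates and preterminals carry the empty monomial
    (probability one).
    """

    def __init__(self, grammar: Grammar):
        self.grammar = grammar
        self.n_rules = len(grammar.rules)
        self._sym_index: dict[str, int] = {}
        self._binaries: list[_Binary] = []
        self._unaries: list[_Unary] = []
        # symbol index -> {terminal char -> list of monomials (summed)}
        self._term_emissions: dict[int, dict[str, list[tuple[int, ...]]]] = {}
        self._suffix_cache: dict[tuple[str, ...], int] = {}
        self._compile()
        self._plan_cache: dict[tuple[tuple[str, ...], ...], _Plan] = {}

    # -- compilation -------------------------------------------------------

    def _sym(self, name: str) -> int:
        if name not in self._sym_index:
            self._sym_index[name] = len(self._sym_index)
        return self._sym_index[name]

    def _nullables(self) -> dict[str, int]:
        """Directly nullable non-terminals -> their epsilon rule index."""
        g = self.grammar
        direct: dict[str, int] = {}
        for i, rule in enumerate(g.rules):
            if not rule.rhs:
                if rule.lhs in direct:
                    raise GrammarError(f"{rule.lhs!r} has more than one epsilon rule")
                direct[rule.lhs] = i
        # reject indirect nullability: a non-epsilon rule whose whole RHS is nullable
        for rule in g.rules:
            if rule.rhs and all(s in direct for s in rule.rhs):
                raise GrammarError(
                    f"rule {rule.lhs} -> {' '.join(rule.rhs)} makes {rule.lhs!r} "
                    "indirectly nullable; compiled scoring supports only direct epsilon rules"
                )
        if g.start in direct:
            raise GrammarError("nullable start symbol is not supported")
        return direct

    def _add_term(self, sym_idx: int, char: str, mono: tuple[int, ...]) -> None:
        emissions = self._term_emissions.setdefault(sym_idx, {})
        emissions.setdefault(char, []).append(mono)

    def _preterminal(self, char: str) -> int:
        name = f"<t:{char}>"
        fresh = name not in self._sym_index
        idx = self._sym(name)
        if fresh:
            self._add_term(idx, char, ())
        return idx

    def _emit_chain(self, parent: int, rhs: list[int], names: tuple[str, ...], mono: tuple[int, ...]) -> None:
        """Binarize parent -> rhs (len >= 2), attaching ``mono`` to the top rule."""
        if len(rhs) == 2:
            self._binaries.append(_Binary(parent, rhs[0], rhs[1], mono))
            return
        suffix_names = names[1:]
        if suffix_names in self._suffix_cache:
            mid = self._suffix_cache[suffix_names]
        else:
            mid = self._sym("<chain:" + " ".join(suffix_names) + ">")
            self._suffix_cache[suffix_names] = mid
            self._emit_chain(mid, rhs[1:], suffix_names, ())
        self._binaries.append(_Binary(parent, rhs[0], mid, mono))

    def _compile(self) -> None:
        g = self.grammar
        for nt in sorted(g.nonterminals):
            self._sym(nt)
        nullable = self._nullables()

        for ridx, rule in enumerate(g.rules):
            if not rule.rhs:
                continue  # null mass is applied at the use sites
            # epsilon-elimination: keep/drop each nullable occurrence
            null_positions = [p for p, s in enumerate(rule.rhs) if s in nullable]
            for mask in range(1 << len(null_positions)):
                dropped = {
                    null_positions[b] for b in range(len(null_positions)) if mask >> b & 1
                }
                body = [s for p, s in enumerate(rule.rhs) if p not in dropped]
                if not body:
                    continue
                mono = (ridx,) + tuple(nullable[rule.rhs[p]] for p in sorted(dropped))
                self._emit_variant(rule.lhs, body, mono)

        self._check_unary_acyclic()
        self.n_symbols = len(self._sym_index)
        self.start_idx = self._sym_index[g.start]

    def _emit_variant(self, lhs: str, body: list[str], mono: tuple[int, ...]) -> None:
        g = self.grammar
        parent = self._sym(lhs)
        if len(body) == 1:
            sym = body[0]
            if sym in g.terminals:
                self._add_term(parent, sym, mono)
            else:
                self._unaries.append(_Unary(parent, self._sym(sym), mono))
            return
        idxs = []
        names = []
        for sym in body:
            if sym in g.terminals:
                idxs.append(self._preterminal(sym))
                names.append(f"<t:{sym}>")
            else:
                idxs.append(self._sym(sym))
                names.append(sym)
        self._emit_chain(parent, idxs, tuple(names), mono)

    def _check_unary_acyclic(self) -> None:
        edges: dict[int, set[int]] = {}
        for u in self._unaries:
            edges.setdefault(u.parent, set()).add(u.child)
        order: list[int] = []
        state: dict[int, int] = {}

        def visit(node: int) -> None:
            if state.get(node) == 1:
                raise GrammarError("unary rule cycle; compiled scoring requires acyclic unaries")
            if state.get(node) == 2:
                return
            state[node] = 1
            for child in edges.get(node, ()):
                visit(child)
            state[node] = 2
            order.append(node)

        for node in list(edges):
            visit(node)
        pos = {node: i for i, node in enumerate(order)}
        # children first: sort unaries so every child is finalized before its parent
        self._unaries.sort(key=lambda u: pos.get(u.parent, 0))

    # -- plans (per bracket/character layout) -------------------------------

    def _plan_for(self, patterns: tuple[frozenset, ...]) -> "_Plan":
        key = tuple(tuple(sorted(p)) for p in patterns)
        if key in self._plan_cache:
            return self._plan_cache[key]
        plan = _Plan(self, patterns)
        self._plan_cache[key] = plan
        return plan

    # -- scoring ------------------------------------------------------------

    def logprobs(
        self,
        sequences: Sequence[Union[str, Sequence[str], HelixPairSequence]],
        rule_probs: np.ndarray | None = None,
        mode: str = "sum",
    ) -> np.ndarray:
        """Log probabilities for same-length sequences under K rule assignments.

        ``rule_probs`` is ``(n_rules,)`` or ``(n_rules, K)``; ``None`` uses
        the grammar's own probabilities.  Returns ``(S,)`` or ``(S, K)``
        natural-log scores with ``-inf`` for unparseable sequences.
        """
        token_rows = [_tokens(s) for s in sequences]
        if not token_rows:
            return np.zeros((0,))
        length = len(token_rows[0])
        if any(len(t) != length for t in token_rows):
            raise GrammarError("batch scoring requires equal-length sequences")
        squeeze = False
        if rule_probs is None:
            rule_probs = np.array([r.prob for r in self.grammar.rules])
        rule_probs = np.asarray(rule_probs, dtype=float)
        if rule_probs.ndim == 1:
            rule_probs = rule_probs[:, None]
            squeeze = True
        if rule_probs.shape[0] != self.n_rules:
            raise GrammarError(
                f"rule_probs has {rule_probs.shape[0]} rows, grammar has {self.n_rules} rules"
            )
        patterns = tuple(
            frozenset(row[i] for row in token_rows) for i in range(length)
        )
        plan = self._plan_for(patterns)
        out = plan.run(token_rows, rule_probs, mode)
        return out[:, 0] if squeeze else out


class _Plan:
    """Feasibility-pruned chart schedule for one position-character layout."""

    def __init__(self, cg: CompiledGrammar, patterns: tuple[frozenset, ...]):
        self.cg = cg
        self.n = len(patterns)
        n, n_sym = self.n, cg.n_symbols
        feasible = [[set() for _ in range(n + 1)] for _ in range(n + 1)]
        # leaves
        self.leaf_syms: list[list[int]] = [[] for _ in range(n)]
        for i, chars in enumerate(patterns):
            for sym, emissions in cg._term_emissions.items():
                if chars & set(emissions):
                    feasible[i][i + 1].add(sym)
                    self.leaf_syms[i].append(sym)
        # unaries at leaf level
        self.leaf_unaries: list[list[_Unary]] = [[] for _ in range(n)]
        for i in range(n):
            for u in cg._unaries:
                if u.child in feasible[i][i + 1]:
                    feasible[i][i + 1].add(u.parent)
                    self.leaf_unaries[i].append(u)
        # larger spans, increasing length
        self.steps: dict[tuple[int, int], tuple[list[tuple[int, _Binary]], list[_Unary]]] = {}
        for span_len in range(2, n + 1):
            for i in range(0, n - span_len + 1):
                j = i + span_len
                bins: list[tuple[int, _Binary]] = []
                for k in range(i + 1, j):
                    left_ok = feasible[i][k]
                    right_ok = feasible[k][j]
                    if not left_ok or not right_ok:
                        continue
                    for b in cg._binaries:
                        if b.left in left_ok and b.right in right_ok:
                            bins.append((k, b))
                            feasible[i][j].add(b.parent)
                unas: list[_Unary] = []
                for u in cg._unaries:
                    if u.child in feasible[i][j]:
                        feasible[i][j].add(u.parent)
                        unas.append(u)
                if bins:
                    self.steps[(i, j)] = (bins, unas)
        self.start_feasible = cg.start_idx in feasible[0][n]

    def run(self, token_rows, rule_probs: np.ndarray, mode: str) -> np.ndarray:
        cg = self.cg
        S = len(token_rows)
        K = rule_probs.shape[1]
        n = self.n
        if not self.start_feasible:
            return np.full((S, K), NEG_INF)

        mono_val_cache: dict[tuple[int, ...], np.ndarray] = {}

        def mono_val(mono: tuple[int, ...]) -> np.ndarray:
            if mono not in mono_val_cache:
                if mono:
                    v = rule_probs[mono[0]].copy()
                    for idx in mono[1:]:
                        v = v * rule_probs[idx]
                else:
                    v = np.ones(K)
                mono_val_cache[mono] = v
            return mono_val_cache[mono]

        combine_is_sum = mode == "sum"
        chart: dict[tuple[int, int], dict[int, np.ndarray]] = {}

        # leaves
        for i in range(n):
            cell: dict[int, np.ndarray] = {}
            for sym in self.leaf_syms[i]:
                emissions = cg._term_emissions[sym]
                vals = np.zeros((S, K))
                for s, row in enumerate(token_rows):
                    monos = emissions.get(row[i])
                    if monos:
                        if combine_is_sum:
                            for m in monos:
                                vals[s] += mono_val(m)
                        else:
                            for m in monos:
                                np.maximum(vals[s], mono_val(m), out=vals[s])
                cell[sym] = vals
            for u in self.leaf_unaries[i]:
                child_vals = cell.get(u.child)
                if child_vals is None:
                    continue
                add = mono_val(u.mono)[None, :] * child_vals
                if u.parent in cell:
                    if combine_is_sum:
                        cell[u.parent] = cell[u.parent] + add
                    else:
                        cell[u.parent] = np.maximum(cell[u.parent], add)
                else:
                    cell[u.parent] = add
            chart[(i, i + 1)] = cell

        # larger spans
        for span_len in range(2, n + 1):
            for i in range(0, n - span_len + 1):
                j = i + span_len
                step = self.steps.get((i, j))
                if step is None:
                    continue
                bins, unas = step
                cell = {}
                for k, b in bins:
                    left = chart[(i, k)].get(b.left)
                    if left is None:
                        continue
                    right = chart[(k, j)].get(b.right)
                    if right is None:
                        continue
                    contrib = mono_val(b.mono)[None, :] * left * right
                    if b.parent in cell:
                        if combine_is_sum:
                            cell[b.parent] += contrib
                        else:
                            np.maximum(cell[b.parent], contrib, out=cell[b.parent])
                    else:
                        cell[b.parent] = contrib
                for u in unas:
                    child_vals = cell.get(u.child)
                    if child_vals is None:
                        continue
                    add = mono_val(u.mono)[None, :] * child_vals
                    if u.parent in cell:
                        if combine_is_sum:
                            cell[u.parent] = cell[u.parent] + add
                        else:
                            cell[u.parent] = np.maximum(cell[u.parent], add)
                    else:
                        cell[u.parent] = add
                chart[(i, j)] = cell

        top = chart.get((0, n), {}).get(cg.start_idx)
        if top is None:
            return np.full((S, K), NEG_INF)
        with np.errstate(divide="ignore"):
            return np.where(top > 0.0, np.log(np.where(top > 0.0, top, 1.0)), NEG_INF)


def batch_logprobs(
    grammar: Grammar | CompiledGrammar,
    sequences: Sequence[Union[str, Sequence[str], HelixPairSequence]],
    rule_probs: np.ndarray | None = None,
    mode: str = "sum",
) -> np.ndarray:
    """Score sequences of arbitrary lengths, grouping equal-length batches.

    Returns ``(S,)`` or ``(S, K)`` depending on ``rule_probs``.
    """
    cg = grammar if isinstance(grammar, CompiledGrammar) else CompiledGrammar(grammar)
    token_rows = [_tokens(s) for s in sequences]
    groups: dict[int, list[int]] = {}
    for idx, row in enumerate(token_rows):
        groups.setdefault(len(row), []).append(idx)
    squeeze = rule_probs is None or np.asarray(rule_probs).ndim == 1
    K = 1 if squeeze else np.asarray(rule_probs).shape[1]
    out = np.zeros((len(token_rows), K))
    for indices in groups.values():
        sub = [token_rows[i] for i in indices]
        scores = cg.logprobs(sub, rule_probs, mode=mode)
        if scores.ndim == 1:
            scores = scores[:, None]
        out[indices] = scores
    return out[:, 0] if squeeze else out
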
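"""Inside/Viterbi parsing against exhaustive derivation enumeration."""

import math

import numpy as np
import pytest
from scipy import stats

from helixgram.grammar import Grammar, Rule
from helixgram.parsing import (
    NEG_INF,
    ParseError,
    inside_logprob,
    sample,
    viterbi_parse,
)

from conftest import enumerate_derivation_logprob, random_proper_grammar


class TestInside:
    def test_branching_grammar_halves_mass(self, branching_grammar):
        assert inside_logprob(branching_grammar, "aa").logprob == pytest.approx(math.log(0.5))
        assert inside_logprob(branching_grammar, "a").logprob == pytest.approx(math.log(0.5))

    def test_ambiguous_derivations_sum_to_one(self, ambiguous_grammar):
        assert inside_logprob(ambiguous_grammar, "aa").logprob == pytest.approx(0.0, abs=1e-12)

    def test_unemittable_symbol_gives_sentinel(self, branching_grammar):
        assert inside_logprob(branching_grammar, "").logprob == NEG_INF

    def test_symbol_outside_alphabet_rejected(self, branching_grammar):
        with pytest.raises(ParseError, match="outside"):
            inside_logprob(branching_grammar, "az")


class TestViterbi:
    def test_ambiguous_grammar_picks_max_derivation(self, ambiguous_grammar):
        res = viterbi_parse(ambiguous_grammar, "aa")
        assert res.logprob == pytest.approx(math.log(0.6))
        assert res.tree.rule.rhs == ("A", "A")
        assert res.tree.yield_string() == ("a", "a")
        assert res.tree.logprob == pytest.approx(res.logprob)

    def test_unambiguous_equals_inside(self):
        g = Grammar(
            terminals=frozenset("ab"),
            nonterminals=frozenset({"S"}),
            start="S",
            rules=[Rule("S", ("a", "b"), 0.7), Rule("S", ("a",), 0.3)],
        )
        assert viterbi_parse(g, "ab").logprob == pytest.approx(inside_logprob(g, "ab").logprob)

    def test_template_parses_any_bracketed_string(self, helix_template):
        res = viterbi_parse(helix_template, "[GAGA]{LILI}")
        assert res.parseable
        assert "".join(res.tree.yield_string()) == "[GAGA]{LILI}"

    def test_max_never_exceeds_sum(self, ambiguous_grammar, branching_grammar, helix_template):
        cases = [
            (ambiguous_grammar, "aa"),
            (branching_grammar, "aa"),
            (helix_template, "[GAG]{LIL}"),
        ]
        for g, s in cases:
            assert viterbi_parse(g, s, with_tree=False).logprob <= (
                inside_logprob(g, s).logprob + 1e-9
            )

    def test_tie_broken_by_rule_order(self):
        g = Grammar(
            terminals=frozenset("a"),
            nonterminals=frozenset({"S", "A", "B"}),
            start="S",
            rules=[
                Rule("S", ("A",), 0.5),
                Rule("S", ("B",), 0.5),
                Rule("A", ("a",), 1.0),
                Rule("B", ("a",), 1.0),
            ],
        )
        assert viterbi_parse(g, "a").tree.rule.rhs == ("A",)


class TestOracleEquivalence:
    def test_random_grammars_match_enumeration(self):
        """Inside and Viterbi equal exhaustive derivation enumeration."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(40):
            g = random_proper_grammar(rng)
            for _ in range(4):
                length = int(rng.integers(1, 7))
                s = "".join(
                    sorted(g.terminals)[int(rng.integers(0, len(g.terminals)))]
                    for _ in range(length)
                )
                expect_sum = enumerate_derivation_logprob(g, s, "sum")
                expect_max = enumerate_derivation_logprob(g, s, "max")
                got_sum = inside_logprob(g, s).logprob
                got_max = viterbi_parse(g, s, with_tree=False).logprob
                if math.isinf(expect_sum):
                    assert math.isinf(got_sum) and math.isinf(got_max)
                else:
                    assert got_sum == pytest.approx(expect_sum, abs=1e-9)
                    assert got_max == pytest.approx(expect_max, abs=1e-9)
                checked += 1
        assert checked >= 150

    def test_consistency_mass_bounded_by_one(self, branching_grammar, ambiguous_grammar):
        """Sum of string probabilities up to length 8 never exceeds 1 and
        reaches 1 for grammars without mass leakage to longer strings."""
        for g, expect_total in [(branching_grammar, 1.0), (ambiguous_grammar, 1.0)]:
            total = 0.0
            for n in range(0, 9):
                for i in range(len(g.terminals) ** n):
                    # single-terminal alphabets here: only one string per length
                    s = "a" * n
                    lp = inside_logprob(g, s).logprob
                    if lp > NEG_INF:
                        total += math.exp(lp)
                    break
            assert total <= 1.0 + 1e-9
            assert total == pytest.approx(expect_total, abs=1e-9)


class TestCyclicGrammars:
    def test_non_consuming_cycle_raises_in_sum_mode(self):
        g = Grammar(
            terminals=frozenset("a"),
            nonterminals=frozenset({"S"}),
            start="S",
            rules=[Rule("S", ("S",), 0.5), Rule("S", ("a",), 0.5)],
        )
        with pytest.raises(ParseError, match="cycle"):
            inside_logprob(g, "a")

    def test_cycle_pruned_in_max_mode(self):
        g = Grammar(
            terminals=frozenset("a"),
            nonterminals=frozenset({"S"}),
            start="S",
            rules=[Rule("S", ("S",), 0.5), Rule("S", ("a",), 0.5)],
        )
        assert viterbi_parse(g, "a", with_tree=False).logprob == pytest.approx(math.log(0.5))


class TestSampling:
    def test_deterministic_grammar_always_same_string(self):
        g = Grammar(
            terminals=frozenset("a"), nonterminals=frozenset({"S"}), start="S",
            rules=[Rule("S", ("a",), 1.0)],
        )
        assert {sample(g, seed) for seed in range(5)} == {"a"}

    def test_seeded_sampling_reproducible(self, helix_template):
        assert sample(helix_template, 7) == sample(helix_template, 7)

    def test_depth_cap_guards_nonterminating_derivations(self):
        g = Grammar(
            terminals=frozenset("a"), nonterminals=frozenset({"S"}), start="S",
            rules=[Rule("S", ("S", "S"), 0.9), Rule("S", ("a",), 0.1)],
        )
        with pytest.raises(ParseError, match="inconsistent"):
            for seed in range(50):
                sample(g, seed, max_steps=200)

    def test_empirical_frequencies_match_inside_probabilities(self, branching_grammar):
        """Chi-square agreement between 10,000 seeded samples and the
        inside probabilities of the sampled strings."""
        rng = np.random.default_rng(99)
        counts = {}
        n = 10_000
        for _ in range(n):
            s = sample(branching_grammar, rng)
            counts[s] = counts.get(s, 0) + 1
        assert set(counts) == {"a", "aa"}
        assert counts["a"] / n == pytest.approx(0.5, abs=0.02)
        expected = [
            n * math.exp(inside_logprob(branching_grammar, s).logprob) for s in sorted(counts)
        ]
        observed = [counts[s] for s in sorted(counts)]
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01


class TestMonotoneDegradation:
    def test_halving_the_used_start_rule_degrades_the_derivation(self, helix_template):
        """Halving the probability of a rule used exactly once in a tree
        (and renormalizing its group) lowers that derivation's log
        probability: the tree used only that rule at the changed LHS."""
        s = "[GAGAG]{LILIL}"
        base = viterbi_parse(helix_template, s)
        target = next(r for r in base.tree.rules_used() if r.lhs == "Start")
        group_sum = sum(
            (r.prob / 2 if r is target else r.prob)
            for r in helix_template.rules
            if r.lhs == "Start"
        )
        new_rules = [
            Rule(r.lhs, r.rhs, ((r.prob / 2 if r is target else r.prob) / group_sum))
            if r.lhs == "Start"
            else r
            for r in helix_template.rules
        ]
        worse = Grammar(
            helix_template.terminals, helix_template.nonterminals,
            helix_template.start, new_rules, helix_template.frozen_lhs,
        )
        # same derivation tree under the modified grammar
        probs = {(r.lhs, r.rhs): r.prob for r in worse.rules}
        new_tree_logprob = sum(
            math.log(probs[(r.lhs, r.rhs)]) for r in base.tree.rules_used()
        )
        assert new_tree_logprob < base.tree.logprob
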
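"""Averaged a-priori parse trees and stem statistics."""

import pytest

from helixgram.grammar import Grammar, GrammarError, Rule
from helixgram.treeview import (
    AvgTree,
    StemPath,
    average_a_priori_tree,
    expected_context_level,
    extract_stem,
    render_tree,
    stem_statistics,
)
from helixgram.parsing import viterbi_parse
from helixgram.sequences import HelixPairSequence


@pytest.fixture()
def worked_example_grammar():
    """The stem-rule fragment with its two-residue context marginals:
    Outerface_DD expands to (Double, Interface_DS, property level) with
    probabilities 0.5 / 0.3 / 0.2; Double_A/B have position marginals
    {Low .6, Medium .4} and {Low .1, Medium .9}; Double_C {Medium 1.0}
    and {Medium .4, High .6}."""
    rules = [
        Rule("Outerface_DD", ("Double_A", "Interface_DS", "Low"), 0.5),
        Rule("Outerface_DD", ("Double_B", "Interface_DS", "Medium"), 0.3),
        Rule("Outerface_DD", ("Double_C", "Interface_DS", "Medium"), 0.2),
    ]
    for d in ("Double_A", "Double_B"):
        rules += [
            Rule(d, ("Low", "Low"), 0.06),
            Rule(d, ("Low", "Medium"), 0.54),
            Rule(d, ("Medium", "Low"), 0.04),
            Rule(d, ("Medium", "Medium"), 0.36),
        ]
    rules += [
        Rule("Double_C", ("Medium", "Medium"), 0.4),
        Rule("Double_C", ("Medium", "High"), 0.6),
    ]
    rules += [
        Rule("Interface_DS", ("Turn",), 1.0),
        Rule("Turn", ("]", "{"), 1.0),
        Rule("Low", ("G",), 1.0),
        Rule("Medium", ("A",), 1.0),
        Rule("High", ("L",), 1.0),
    ]
    return Grammar(
        terminals=frozenset("GAL]{"),
        nonterminals=frozenset(
            {"Outerface_DD", "Interface_DS", "Double_A", "Double_B", "Double_C",
             "Low", "Medium", "High", "Turn"}
        ),
        start="Outerface_DD",
        rules=rules,
    )


class TestExpectedContextLevel:
    def test_right_single_context(self, worked_example_grammar):
        # 0 x 0.5 + 1 x (0.3 + 0.2) = 0.5
        assert expected_context_level(worked_example_grammar, "Outerface_DD", "right") == 0.5

    def test_left_double_first_position(self, worked_example_grammar):
        # (0.5+0.3) x (0 x 0.6 + 1 x 0.4) + 0.2 x (1 x 1.0) = 0.52
        got = expected_context_level(worked_example_grammar, "Outerface_DD", "left", 1)
        assert got == pytest.approx(0.52, abs=1e-12)

    def test_left_double_second_position(self, worked_example_grammar):
        # (0.5+0.3) x (0 x 0.1 + 1 x 0.9) + 0.2 x (1 x 0.4 + 2 x 0.6) = 1.04
        got = expected_context_level(worked_example_grammar, "Outerface_DD", "left", 2)
        assert got == pytest.approx(1.04, abs=1e-12)

    def test_deterministic_high_rule_gives_two(self):
        g = Grammar(
            terminals=frozenset("L]{"),
            nonterminals=frozenset({"Outerface_DD", "Interface_DS", "High", "Turn"}),
            start="Outerface_DD",
            rules=[
                Rule("Outerface_DD", ("High", "Interface_DS", "High"), 1.0),
                Rule("Interface_DS", ("Turn",), 1.0),
                Rule("Turn", ("]", "{"), 1.0),
                Rule("High", ("L",), 1.0),
            ],
        )
        assert expected_context_level(g, "Outerface_DD", "left") == 2.0

    def test_unknown_parent_rejected(self, worked_example_grammar):
        with pytest.raises(GrammarError):
            expected_context_level(worked_example_grammar, "Nonsense", "left")


class TestAverageTree:
    def test_worked_example_tree_and_rounding(self, worked_example_grammar):
        tree = average_a_priori_tree(worked_example_grammar, ("Outerface_DD", "Interface_DS"))
        h1 = tree.helix_nodes(1)
        h2 = tree.helix_nodes(2)
        assert [n.expected for n in h1] == pytest.approx([0.52, 1.04], abs=1e-12)
        assert [n.expected for n in h2] == [0.5]
        # rounding to nearest integer, ties up: 0.52 -> 1, 1.04 -> 1, 0.5 -> 1
        assert [n.rounded for n in tree.nodes] == [1, 1, 1]

    def test_levels_bounded_and_rounded_in_range(self, worked_example_grammar):
        tree = average_a_priori_tree(worked_example_grammar, ("Outerface_DD", "Interface_DS"))
        for n in tree.nodes:
            assert 0.0 <= n.expected <= 2.0
            assert n.rounded in (0, 1, 2)

    def test_matches_enumeration_over_context_assignments(self, worked_example_grammar):
        """Brute-force expectation: enumerate every (rule, Double expansion)
        combination weighted by probability."""
        g = worked_example_grammar
        groups = g.rules_by_lhs()
        val = {"Low": 0.0, "Medium": 1.0, "High": 2.0}
        exp = [0.0, 0.0, 0.0]  # h1 pos1, h1 pos2, h2 pos1
        for stem_rule in groups["Outerface_DD"]:
            for dbl_rule in groups[stem_rule.rhs[0]]:
                w = stem_rule.prob * dbl_rule.prob
                exp[0] += w * val[dbl_rule.rhs[0]]
                exp[1] += w * val[dbl_rule.rhs[1]]
            exp[2] += stem_rule.prob * val[stem_rule.rhs[2]]
        tree = average_a_priori_tree(g, ("Outerface_DD", "Interface_DS"))
        got = [n.expected for n in tree.helix_nodes(1)] + [
            n.expected for n in tree.helix_nodes(2)
        ]
        assert got == pytest.approx(exp, abs=1e-12)

    def test_linearity_in_rule_probabilities(self, worked_example_grammar):
        """Mixing two grammars' stem-rule groups mixes expectations."""
        g1 = worked_example_grammar
        alt_rules = []
        for r in g1.rules:
            if r.lhs == "Outerface_DD":
                probs = {"Double_A": 0.1, "Double_B": 0.2, "Double_C": 0.7}
                alt_rules.append(Rule(r.lhs, r.rhs, probs[r.rhs[0]]))
            else:
                alt_rules.append(r)
        g2 = Grammar(g1.terminals, g1.nonterminals, g1.start, alt_rules)
        lam = 0.3
        mixed_rules = [
            Rule(a.lhs, a.rhs, lam * a.prob + (1 - lam) * b.prob)
            for a, b in zip(g1.rules, g2.rules)
        ]
        gm = Grammar(g1.terminals, g1.nonterminals, g1.start, mixed_rules)
        e1 = expected_context_level(g1, "Outerface_DD", "left", 2)
        e2 = expected_context_level(g2, "Outerface_DD", "left", 2)
        em = expected_context_level(gm, "Outerface_DD", "left", 2)
        assert em == pytest.approx(lam * e1 + (1 - lam) * e2, abs=1e-12)

    def test_invalid_stem_rejected(self):
        with pytest.raises(GrammarError, match="compatibility"):
            StemPath(("Outerface_SS", "Interface_SS"))


class TestStemStatistics:
    def test_frequencies_sum_to_one_and_dominant_stem_first(self, helix_template, two_class_dataset):
        seqs = two_class_dataset[:10]
        freqs, bad = stem_statistics(helix_template, seqs)
        assert not bad
        assert sum(freqs.values()) == pytest.approx(1.0)
        counts = list(freqs.values())
        assert counts == sorted(counts, reverse=True)

    def test_single_sequence_single_stem(self, helix_template):
        freqs, bad = stem_statistics(
            helix_template, [HelixPairSequence("s", "GAGAG", "LILIL")]
        )
        assert not bad and list(freqs.values()) == [1.0]

    def test_extracted_stem_is_valid_path(self, helix_template):
        res = viterbi_parse(helix_template, "[GAGAG]{LILIL}")
        stem = extract_stem(res.tree)
        assert stem.symbols  # non-empty and passes StemPath validation


class TestRendering:
    def test_same_input_renders_identical_bytes(self, worked_example_grammar):
        tree = average_a_priori_tree(worked_example_grammar, ("Outerface_DD", "Interface_DS"))
        assert render_tree(tree) == render_tree(tree)
        assert "helix 1" in render_tree(tree)

    def test_empty_stem_renders_root_only(self):
        tree = AvgTree(stem=StemPath(()), nodes=())
        out = render_tree(tree)
        assert "(root only)" in out

    def test_parse_tree_rendering(self, helix_template):
        res = viterbi_parse(helix_template, "[GA]{LI}")
        out = render_tree(res.tree)
        assert out.startswith("Start")
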
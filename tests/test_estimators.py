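"""Estimator API: sklearn conventions, fitting, workflows and CLI smoke."""

import json

import numpy as np
import pytest
from click.testing import CliRunner
from sklearn.base import clone

from helixgram.cli import main as cli_main
from helixgram.estimators import (
    AveragePropertyClassifier,
    GrammarClassifier,
    MultiGrammarClassifier,
)
from helixgram.grammar import validate_properness
from helixgram.sequences import HelixPairSequence
from helixgram.synthetic import default_two_class_specs, plant_motif_dataset
from helixgram.workflows import RunConfig, run_experiment

TINY = dict(n_grammars=1, population_size=8, max_generations=3)


@pytest.fixture(scope="module")
def tiny_dataset():
    return plant_motif_dataset(default_two_class_specs(0.1), 8, seed=5)


class TestGrammarClassifier:
    def test_sklearn_param_interface(self):
        clf = GrammarClassifier(population_size=30)
        params = clf.get_params()
        assert params["population_size"] == 30
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_fit_and_score(self, tiny_dataset):
        pos = [s for s in tiny_dataset if s.label == "c1"]
        clf = GrammarClassifier(random_state=1, **TINY).fit(pos)
        assert len(clf.grammars_) == 1
        assert validate_properness(clf.grammars_[0]).is_proper
        scores = clf.score_samples(tiny_dataset)
        assert scores.shape == (len(tiny_dataset),)
        assert np.all(np.isfinite(scores))
        assert np.array_equal(clf.decision_function(tiny_dataset), scores)

    def test_accepts_bracketed_strings(self, tiny_dataset):
        pos = [s.encoded for s in tiny_dataset if s.label == "c1"]
        clf = GrammarClassifier(random_state=1, **TINY).fit(pos)
        assert np.isfinite(clf.score_samples(["[GAGAGAGAGA]{LILILILILI}"])[0])

    def test_unfitted_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            GrammarClassifier().score_samples(["[GA]{LI}"])

    def test_same_random_state_reproducible(self, tiny_dataset):
        pos = [s for s in tiny_dataset if s.label == "c1"]
        s1 = GrammarClassifier(random_state=3, **TINY).fit(pos).score_samples(tiny_dataset)
        s2 = GrammarClassifier(random_state=3, **TINY).fit(pos).score_samples(tiny_dataset)
        assert np.array_equal(s1, s2)


class TestMultiGrammarClassifier:
    def test_fit_predict_and_multiscore_identity(self, tiny_dataset):
        y = [s.label for s in tiny_dataset]
        clf = MultiGrammarClassifier(
            n_grammars=1, population_size=8, max_generations=3, random_state=2
        ).fit(tiny_dataset, y)
        assert set(clf.classes_) == {"c1", "c2"}
        dec = clf.decision_function(tiny_dataset)
        assert dec.shape == (len(tiny_dataset), 2)
        # multiscores sum to zero across classes for every sequence
        assert np.allclose(dec.sum(axis=1), 0.0, atol=1e-9)
        preds = clf.predict(tiny_dataset)
        assert set(preds) <= {"c1", "c2"}


class TestAveragePropertyClassifier:
    def test_separable_toy_problem(self):
        pos = [HelixPairSequence(f"p{i}", "WWWWW", "FFFFF") for i in range(4)]
        neg = [HelixPairSequence(f"n{i}", "GGGGG", "GGGGG") for i in range(4)]
        X = pos + neg
        y = ["big"] * 4 + ["small"] * 4
        clf = AveragePropertyClassifier(pos_label="big").fit(X, y)
        assert clf.direction_ == "higher"
        assert list(clf.predict(X)) == y


class TestWorkflow:
    def test_pipeline_emits_declared_files_and_is_deterministic(self, tmp_path):
        cfg = RunConfig(
            out_dir=str(tmp_path / "run1"),
            n_per_class=6,
            seeds=(0,),
            population_size=8,
            max_generations=2,
            cv_scheme="none",
        )
        manifest = run_experiment(cfg)
        out = tmp_path / "run1"
        for name in ("dataset.tsv", "scores.tsv", "auc.tsv", "manifest.json"):
            assert (out / name).exists()
        assert {"simulate", "train", "classify", "tree"} <= set(manifest["stages"])
        saved = json.loads((out / "manifest.json").read_text())
        assert saved["config"]["data_seed"] == 42
        assert any(r["class"] == "c1" for r in manifest["auc"])
        # rerun with identical seeds: byte-identical score table
        cfg2 = RunConfig(**{**cfg.__dict__, "out_dir": str(tmp_path / "run2")})
        run_experiment(cfg2)
        assert (out / "scores.tsv").read_bytes() == (tmp_path / "run2" / "scores.tsv").read_bytes()


class TestCLI:
    def test_simulate_make_train_scan_tree_roundtrip(self, tmp_path):
        runner = CliRunner()
        pairs = tmp_path / "pairs.tsv"
        r = runner.invoke(cli_main, ["simulate", "--n", "6", "--seed", "1", "--out", str(pairs)])
        assert r.exit_code == 0, r.output
        grammar = tmp_path / "template.txt"
        r = runner.invoke(cli_main, ["make-grammar", "--seqs", str(pairs), "--out", str(grammar)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["check-grammar", "--grammar", str(grammar)])
        assert r.exit_code == 0 and "proper" in r.output
        trained = tmp_path / "trained.txt"
        r = runner.invoke(
            cli_main,
            ["train", "--grammar", str(grammar), "--pos", str(pairs), "--seed", "0",
             "--population", "8", "--generations", "2", "--out", str(trained)],
        )
        assert r.exit_code == 0, r.output
        scores = tmp_path / "scores.tsv"
        r = runner.invoke(
            cli_main, ["scan", "--grammar", str(trained), "--seqs", str(pairs), "--out", str(scores)]
        )
        assert r.exit_code == 0, r.output
        assert scores.read_text().count("\n") == 13  # header + 12 pairs
        tree_out = tmp_path / "tree.txt"
        r = runner.invoke(
            cli_main,
            ["tree", "--grammar", str(trained), "--stem", "auto", "--seqs", str(pairs),
             "--out", str(tree_out)],
        )
        assert r.exit_code == 0, r.output
        assert "helix 1" in tree_out.read_text()

    def test_classify_command_multiscore(self, tmp_path):
        runner = CliRunner()
        pairs = tmp_path / "pairs.tsv"
        runner.invoke(cli_main, ["simulate", "--n", "4", "--seed", "2", "--out", str(pairs)])
        g = tmp_path / "g.txt"
        runner.invoke(cli_main, ["make-grammar", "--seqs", str(pairs), "--out", str(g)])
        out = tmp_path / "cls.tsv"
        r = runner.invoke(
            cli_main,
            ["classify", "--grammars", f"c1:{g}", "--grammars", f"c2:{g}",
             "--seqs", str(pairs), "--mode", "multi", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        text = out.read_text()
        assert "multiscore_c1" in text
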
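"""Scikit-learn style estimators wrapping the grammar machinery.

``GrammarClassifier`` is a one-class scorer in the spirit of
``OneClassSVM``: fitted on positive examples of a single contact-site
class, it scores new helix pairs by grammar log-probability.
``MultiGrammarClassifier`` trains one grammar ensemble per class and
combines them through multiscores for k-way classification.
``AveragePropertyClassifier`` is the deliberately weak baseline that
scores a pair by its mean raw property value only.

All estimators accept ``X`` as a sequence of bracketed strings
``[h1]{h2}`` or :class:`~helixgram.sequences.HelixPairSequence` objects,
follow the fit/predict/get_params conventions and expose fitted state in
trailing-underscore attributes, so they compose with sklearn model
selection utilities that do not require rectangular numeric input.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import classify as _classify
from .fastparse import CompiledGrammar
from .ga import GAConfig, TrainingSet, evolve
from .grammar import Grammar
from .properties import (
    PropertyTable,
    estimate_composition,
    load_packaged_property,
    problem_based_scaling,
    terminal_rule_probs,
)
from .sequences import HelixPairSequence
from .templates import TemplateConfig, build_helix_pair_template

__all__ = ["GrammarClassifier", "MultiGrammarClassifier", "AveragePropertyClassifier"]


def as_pairs(X: Sequence[Union[str, HelixPairSequence]]) -> list[HelixPairSequence]:
    """Normalize input to a list of helix-pair sequences."""
    out = []
    for i, x in enumerate(X):
        if isinstance(x, HelixPairSequence):
            out.append(x)
        else:
            out.append(HelixPairSequence.from_encoded(str(x), id=f"x{i}"))
    return out


def _resolve_property(prop: Union[str, PropertyTable]) -> PropertyTable:
    if isinstance(prop, PropertyTable):
        return prop
    return load_packaged_property(prop)


def _derived_seed(random_state: int, k: int) -> int:
    return (int(random_state) * 1_000_003 + 7919 * k + 1) % (2**31)


class GrammarClassifier(BaseEstimator):
    """One-class helix-pair scorer backed by trained PCFGs.

    Parameters
    ----------
    property_table : accession string or PropertyTable
        Amino-acid property behind the Low/Medium/High terminal rules.
    variant : {"helix_pair", "no_dependency", "unconstrained"}
        Grammar template variant.
    n_grammars : int
        Independently seeded inference runs whose scores are averaged
        (the combined classifier).
    population_size, max_generations, stop_window, phenotype_exponent,
    distortion_halfwidth : GA budget and operators; defaults are the
        reduced desk-scale budget.
    scan_mode : {"max", "sum"}
        Viterbi (default) or total-probability scoring.
    """

    def __init__(
        self,
        property_table: Union[str, PropertyTable] = "FAUJ880103",
        variant: str = "helix_pair",
        n_grammars: int = 3,
        n_double_symbols: int = 3,
        population_size: int = 60,
        max_generations: int = 150,
        stop_window: int = 100,
        phenotype_exponent: float = 3.0,
        distortion_halfwidth: float = 0.05,
        any_mode: str = "uniform",
        scan_mode: str = "max",
        random_state: int = 0,
    ):
        self.property_table = property_table
        self.variant = variant
        self.n_grammars = n_grammars
        self.n_double_symbols = n_double_symbols
        self.population_size = population_size
        self.max_generations = max_generations
        self.stop_window = stop_window
        self.phenotype_exponent = phenotype_exponent
        self.distortion_halfwidth = distortion_halfwidth
        self.any_mode = any_mode
        self.scan_mode = scan_mode
        self.random_state = random_state

    # -- template construction --------------------------------------------

    def _build_template(self, pairs: list[HelixPairSequence]) -> Grammar:
        table = _resolve_property(self.property_table)
        comp = estimate_composition(pairs)
        scaled = problem_based_scaling(table, comp)
        terminals = terminal_rule_probs(scaled, any_mode=self.any_mode, comp=comp)
        cfg = TemplateConfig(n_double_symbols=self.n_double_symbols, variant=self.variant)
        return build_helix_pair_template(cfg, terminals)

    def fit(self, X, y=None):
        """Infer rule probabilities on positive examples only."""
        pairs = as_pairs(X)
        if not pairs:
            raise ValueError("cannot fit on an empty sequence set")
        self.template_ = self._build_template(pairs)
        train = TrainingSet(tuple(pairs))
        self.grammars_ = []
        self.histories_ = []
        for k in range(self.n_grammars):
            cfg = GAConfig(
                population_size=self.population_size,
                max_generations=self.max_generations,
                stop_window=self.stop_window,
                phenotype_exponent=self.phenotype_exponent,
                distortion_halfwidth=self.distortion_halfwidth,
                rng_seed=_derived_seed(self.random_state, k),
            )
            grammar, history = evolve(self.template_, train, cfg)
            self.grammars_.append(grammar)
            self.histories_.append(history)
        self.compiled_ = [CompiledGrammar(g) for g in self.grammars_]
        return self

    def score_samples(self, X) -> np.ndarray:
        """Combined (mean over grammars) log-probability scores."""
        if not hasattr(self, "compiled_"):
            raise AttributeError("GrammarClassifier is not fitted")
        pairs = as_pairs(X)
        return _classify.combined_scores(self.compiled_, pairs, mode=self.scan_mode)

    def decision_function(self, X) -> np.ndarray:
        return self.score_samples(X)


class MultiGrammarClassifier(BaseEstimator, ClassifierMixin):
    """k-way classifier combining per-class grammar ensembles by multiscore.

    One :class:`GrammarClassifier` is fitted per class on that class's
    sequences; a sequence's multiscore for class q is q's combined score
    minus the mean of the other classes' scores.
    """

    def __init__(
        self,
        property_table: Union[str, PropertyTable] = "FAUJ880103",
        variant: str = "helix_pair",
        n_grammars: int = 3,
        population_size: int = 60,
        max_generations: int = 150,
        scan_mode: str = "max",
        random_state: int = 0,
    ):
        self.property_table = property_table
        self.variant = variant
        self.n_grammars = n_grammars
        self.population_size = population_size
        self.max_generations = max_generations
        self.scan_mode = scan_mode
        self.random_state = random_state

    def fit(self, X, y):
        pairs = as_pairs(X)
        y = np.asarray(y)
        if len(pairs) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.estimators_ = {}
        for ci, cls in enumerate(self.classes_):
            sub = [p for p, lab in zip(pairs, y) if lab == cls]
            est = GrammarClassifier(
                property_table=self.property_table,
                variant=self.variant,
                n_grammars=self.n_grammars,
                population_size=self.population_size,
                max_generations=self.max_generations,
                scan_mode=self.scan_mode,
                random_state=_derived_seed(self.random_state, ci),
            )
            self.estimators_[cls] = est.fit(sub)
        return self

    def class_scores(self, X) -> dict:
        """Per-class combined log-probability score vectors."""
        pairs = as_pairs(X)
        return {cls: est.score_samples(pairs) for cls, est in self.estimators_.items()}

    def decision_function(self, X) -> np.ndarray:
        """Multiscore matrix (n_samples, n_classes); NaN rows are flagged
        sequences with a non-finite score in some class."""
        scores = self.class_scores(X)
        table, _flagged = _classify.multiscore_table(scores)
        return np.column_stack([table[cls] for cls in self.classes_])

    def predict(self, X) -> np.ndarray:
        scores = self.class_scores(X)
        table, flagged = _classify.multiscore_table(scores)
        mat = np.column_stack([table[cls] for cls in self.classes_])
        raw = np.column_stack([scores[cls] for cls in self.classes_])
        out = np.empty(mat.shape[0], dtype=self.classes_.dtype)
        for i in range(mat.shape[0]):
            row = mat[i] if i not in flagged else raw[i]
            out[i] = self.classes_[int(np.argmax(row))]
        return out


class AveragePropertyClassifier(BaseEstimator, ClassifierMixin):
    """Baseline: classify by the mean raw property value of the pair.

    Training establishes only the preferred direction (higher or lower
    property level in the positive class) and a decision threshold.
    """

    def __init__(self, property_table: Union[str, PropertyTable] = "FAUJ880103", pos_label=None):
        self.property_table = property_table
        self.pos_label = pos_label

    def fit(self, X, y):
        pairs = as_pairs(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("AveragePropertyClassifier is binary")
        pos_label = self.pos_label if self.pos_label is not None else self.classes_[1]
        self.pos_label_ = pos_label
        table = _resolve_property(self.property_table)
        self.table_ = table
        pos = [p for p, lab in zip(pairs, y) if lab == pos_label]
        neg = [p for p, lab in zip(pairs, y) if lab != pos_label]
        self.direction_ = _classify.fit_avg_property_direction(table, pos, neg)
        ps = np.array([_classify.avg_property_score(table, p, self.direction_) for p in pos])
        ns = np.array([_classify.avg_property_score(table, p, self.direction_) for p in neg])
        self.threshold_ = float((ps.mean() + ns.mean()) / 2.0)
        return self

    def decision_function(self, X) -> np.ndarray:
        pairs = as_pairs(X)
        return np.array(
            [_classify.avg_property_score(self.table_, p, self.direction_) for p in pairs]
        )

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        neg_label = self.classes_[self.classes_ != self.pos_label_][0]
        return np.where(s >= self.threshold_, self.pos_label_, neg_label)
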
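"""Turning grammar log-probabilities into class decisions.

Scanning uses the Viterbi (max) score by default: the log probability of
the single most likely derivation.  Scores of several grammars trained
for the same class may be averaged into a *combined* classifier, and
grammars trained for different classes combine into a *multiscore*:
the class's own score minus the mean score of the other classes, so that
positive and negative evidence both contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .fastparse import CompiledGrammar, batch_logprobs
from .grammar import Grammar
from .properties import PropertyTable
from .sequences import HelixPairSequence

__all__ = [
    "ClassScore",
    "grammar_scores",
    "combined_score",
    "combined_scores",
    "multiscore",
    "multiscore_table",
    "avg_property_score",
    "fit_avg_property_direction",
]


@dataclass(frozen=True)
class ClassScore:
    """Per-class log scores and multiscores for one sequence."""

    seq_id: str
    class_scores: Mapping[str, float]
    multiscores: Mapping[str, float]


def grammar_scores(
    grammar: Grammar | CompiledGrammar,
    seqs: Sequence[HelixPairSequence],
    mode: str = "max",
) -> np.ndarray:
    """Log-probability scores of many sequences under one grammar."""
    return batch_logprobs(grammar, seqs, mode=mode)


def combined_score(
    grammars: Sequence[Grammar | CompiledGrammar],
    seq: HelixPairSequence,
    mode: str = "max",
) -> float:
    """Mean log-probability over several grammars trained for one class."""
    if not grammars:
        raise ValueError("combined_score requires at least one grammar")
    return float(np.mean([grammar_scores(g, [seq], mode=mode)[0] for g in grammars]))


def combined_scores(
    grammars: Sequence[Grammar | CompiledGrammar],
    seqs: Sequence[HelixPairSequence],
    mode: str = "max",
) -> np.ndarray:
    """Vectorized :func:`combined_score` over a sequence set."""
    if not grammars:
        raise ValueError("combined_scores requires at least one grammar")
    stacked = np.stack([grammar_scores(g, seqs, mode=mode) for g in grammars])
    return stacked.mean(axis=0)


def multiscore(scores: Mapping[str, float], q: str) -> float:
    """Class score minus the mean of the other classes' scores.

    With four classes this is ``score_q - (1/3) * sum_{p != q} score_p``;
    the definition extends to any k >= 2 classes.  All scores must be
    finite -- a sequence with an unparseable class is flagged upstream,
    not scored.
    """
    if q not in scores:
        raise KeyError(f"class {q!r} missing from scores {sorted(scores)}")
    if len(scores) < 2:
        raise ValueError("multiscore requires at least 2 class scores")
    if any(not math.isfinite(v) for v in scores.values()):
        raise ValueError("multiscore requires finite scores for every class")
    others = [v for p, v in scores.items() if p != q]
    return scores[q] - sum(others) / len(others)


def multiscore_table(
    class_scores: Mapping[str, np.ndarray],
    seq_ids: Sequence[str] | None = None,
) -> tuple[dict[str, np.ndarray], list[int]]:
    """Multiscores for every class over a score matrix.

    ``class_scores`` maps class -> per-sequence score vector.  Returns the
    per-class multiscore vectors and the indices of flagged sequences
    (those with a non-finite score in any class), whose multiscores are
    set to NaN.
    """
    classes = list(class_scores)
    if len(classes) < 2:
        raise ValueError("multiscore requires at least 2 classes")
    mat = np.stack([np.asarray(class_scores[c], dtype=float) for c in classes])
    finite = np.all(np.isfinite(mat), axis=0)
    flagged = [int(i) for i in np.nonzero(~finite)[0]]
    k = len(classes)
    total = mat.sum(axis=0)
    out: dict[str, np.ndarray] = {}
    for ci, c in enumerate(classes):
        with np.errstate(invalid="ignore"):
            ms = mat[ci] - (total - mat[ci]) / (k - 1)
        ms[~finite] = np.nan
        out[c] = ms
    return out, flagged


def avg_property_score(
    table: PropertyTable,
    seq: Union[HelixPairSequence, str],
    direction: str = "higher",
) -> float:
    """Baseline score: mean raw property value over the pair's residues.

    ``direction='lower'`` negates the mean so that larger scores always
    mean "more like the positive class" once the direction has been
    fitted on training data.
    """
    residues = seq.residues if isinstance(seq, HelixPairSequence) else seq.replace(
        "[", ""
    ).replace("]", "").replace("{", "").replace("}", "")
    if not residues:
        raise ValueError("cannot score an empty residue string")
    mean = float(np.mean([table.pval[aa] for aa in residues]))
    if direction == "higher":
        return mean
    if direction == "lower":
        return -mean
    raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")


def fit_avg_property_direction(
    table: PropertyTable,
    pos: Sequence[HelixPairSequence],
    neg: Sequence[HelixPairSequence],
) -> str:
    """Choose the sign convention with the larger training AUC."""
    from .evaluate import roc_auc

    aucs = {}
    for direction in ("higher", "lower"):
        p = [avg_property_score(table, s, direction) for s in pos]
        n = [avg_property_score(table, s, direction) for s in neg]
        aucs[direction] = roc_auc(p, n).auc
    return max(aucs, key=lambda d: (aucs[d], d == "higher"))
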
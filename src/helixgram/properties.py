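"""Amino-acid property tables and frozen terminal-rule probabilities.

The grammars in this package do not condition on 20 residue identities
directly.  Instead a quantitative amino-acid property (e.g. normalized
van der Waals volume) is turned into three *property non-terminals* --
``Low``, ``Medium``, ``High`` -- whose terminal-rule probabilities encode
a fuzzy membership of each residue in the low/medium/high level of the
property.  The conversion first centres the property at the composition-
weighted mean of the training corpus (*problem-based scaling*), so that
the residue-composition bias of transmembrane helices is absorbed before
levels are assigned.

Two AAindex entries used throughout ship as packaged fixtures:
``FAUJ880103`` (normalized van der Waals volume) and ``BIOV880101``
(information value for accessibility).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

from .grammar import AA_ALPHABET
from .sequences import HelixPairSequence

__all__ = [
    "PropertyTable",
    "CompositionProfile",
    "ScaledProperty",
    "TerminalRuleSet",
    "PropertyError",
    "estimate_composition",
    "problem_based_scaling",
    "terminal_rule_probs",
    "read_aaindex",
    "load_packaged_property",
    "uniform_composition",
]

LEVELS = ("Low", "Medium", "High")

_CENTERING_TOL = 1e-9


class PropertyError(ValueError):
    """Raised for degenerate properties or malformed AAindex input."""


@dataclass(frozen=True)
class PropertyTable:
    """A named amino-acid property: symbol -> raw value.

    AAindex entries carry exactly the 20 standard amino acids; reduced
    alphabets are permitted for toy models and tests.
    """

    name: str
    pval: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.pval) < 2:
            raise PropertyError(f"property {self.name!r}: need at least 2 symbols")

    @property
    def alphabet(self) -> tuple[str, ...]:
        return tuple(self.pval)


@dataclass(frozen=True)
class CompositionProfile:
    """Relative amino-acid frequencies of the problem of interest."""

    prop: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.prop.values()):
            raise PropertyError("composition frequencies must be non-negative")
        total = math.fsum(self.prop.values())
        if abs(total - 1.0) > _CENTERING_TOL:
            raise PropertyError(f"composition frequencies sum to {total}, expected 1")


@dataclass(frozen=True)
class ScaledProperty:
    """Problem-scaled property values.

    ``pval_prime`` is the property centred at the composition-weighted
    mean; ``pvalL_pp`` and ``pvalH_pp`` are the centred values divided by
    the (negative) minimum and the (positive) maximum respectively, so
    residues below the mean get a positive low-level affinity and residues
    above it a positive high-level affinity.
    """

    name: str
    pval_prime: Mapping[str, float]
    pvalL_pp: Mapping[str, float]
    pvalH_pp: Mapping[str, float]


@dataclass(frozen=True)
class TerminalRuleSet:
    """Proper terminal-rule probabilities for Low/Medium/High plus Any."""

    probs: Mapping[tuple[str, str], float]  # (level, symbol) -> probability
    any_probs: Mapping[str, float]
    property_name: str = ""

    def row(self, level: str) -> dict[str, float]:
        return {aa: p for (lvl, aa), p in self.probs.items() if lvl == level}

    def alphabet(self) -> tuple[str, ...]:
        return tuple(self.any_probs)


def uniform_composition(alphabet: Iterable[str] = AA_ALPHABET) -> CompositionProfile:
    alphabet = tuple(alphabet)
    return CompositionProfile({a: 1.0 / len(alphabet) for a in alphabet})


def estimate_composition(sequences: Iterable[HelixPairSequence]) -> CompositionProfile:
    """Relative residue frequencies of a corpus, bracket symbols ignored.

    In training, the composition is estimated from the combined positive
    and negative learning sets.
    """
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for aa in seq.residues:
            counts[aa] = counts.get(aa, 0) + 1
            total += 1
    if total == 0:
        raise PropertyError("cannot estimate composition from an empty sequence set")
    return CompositionProfile({aa: c / total for aa, c in sorted(counts.items())})


def problem_based_scaling(table: PropertyTable, comp: CompositionProfile) -> ScaledProperty:
    """Centre a property at the composition-weighted mean and scale to [-1, 1].

    Residues absent from the composition profile get frequency zero.  A
    property that is constant after centring carries no signal and raises
    :class:`PropertyError`.
    """
    alphabet = table.alphabet
    weighted_mean = math.fsum(table.pval[a] * comp.prop.get(a, 0.0) for a in alphabet)
    pval_prime = {a: table.pval[a] - weighted_mean for a in alphabet}
    lo = min(pval_prime.values())
    hi = max(pval_prime.values())
    if max(abs(lo), abs(hi)) <= _CENTERING_TOL:
        raise PropertyError(f"property {table.name!r} has no signal (constant after centring)")
    if lo >= 0 or hi <= 0:
        raise PropertyError(
            f"property {table.name!r}: no residue on one side of the weighted mean"
        )
    pvalL_pp = {a: v / lo for a, v in pval_prime.items()}
    pvalH_pp = {a: v / hi for a, v in pval_prime.items()}
    return ScaledProperty(table.name, pval_prime, pvalL_pp, pvalH_pp)


def terminal_rule_probs(
    scaled: ScaledProperty,
    any_mode: str = "uniform",
    comp: CompositionProfile | None = None,
) -> TerminalRuleSet:
    """Proper Low/Medium/High terminal-rule probabilities from a scaled property.

    ``Low`` puts mass on residues below the weighted mean (proportional to
    their scaled distance), ``High`` on residues above it.  The ``Medium``
    row is the per-residue remainder ``1 - Low - High`` renormalized to sum
    to one, so all three rows are proper.  ``Any`` is uniform over the
    alphabet by default, or composition-weighted with ``any_mode='composition'``.
    """
    alphabet = tuple(scaled.pval_prime)
    low_num = {a: scaled.pvalL_pp[a] if scaled.pval_prime[a] < 0 else 0.0 for a in alphabet}
    high_num = {a: scaled.pvalH_pp[a] if scaled.pval_prime[a] > 0 else 0.0 for a in alphabet}
    low_den = math.fsum(low_num.values())
    high_den = math.fsum(high_num.values())
    if low_den <= 0:
        raise PropertyError("no residue below the weighted mean; Low row undefined")
    if high_den <= 0:
        raise PropertyError("no residue above the weighted mean; High row undefined")
    low = {a: v / low_den for a, v in low_num.items()}
    high = {a: v / high_den for a, v in high_num.items()}
    med_raw = {a: 1.0 - (low[a] + high[a]) for a in alphabet}
    med_den = math.fsum(med_raw.values())
    if med_den <= 0:
        raise PropertyError("Medium row has no mass after subtracting Low and High")
    med = {a: v / med_den for a, v in med_raw.items()}

    probs: dict[tuple[str, str], float] = {}
    for a in alphabet:
        probs[("Low", a)] = low[a]
        probs[("Medium", a)] = med[a]
        probs[("High", a)] = high[a]
    if any_mode == "uniform":
        any_probs = {a: 1.0 / len(alphabet) for a in alphabet}
    elif any_mode == "composition":
        if comp is None:
            raise PropertyError("any_mode='composition' requires a composition profile")
        any_probs = {a: comp.prop.get(a, 0.0) for a in alphabet}
    else:
        raise PropertyError(f"unknown any_mode {any_mode!r}")
    return TerminalRuleSet(probs=probs, any_probs=any_probs, property_name=scaled.name)


# -- AAindex flat-file reader ---------------------------------------------

#: Column order of the AAindex 2x10 value grid.
_AAINDEX_ORDER = tuple("ARNDCQEGHI") + tuple("LKMFPSTWYV")


def read_aaindex(path) -> list[PropertyTable]:
    """Read an AAindex1 flat file into one :class:`PropertyTable` per entry.

    Only the ``H`` (accession), ``D`` (description) and ``I`` (value grid)
    records are used.  Entries with ``NA`` values or a wrong value count
    are rejected.
    """
    with open(path) as fh:
        text = fh.read()
    tables: list[PropertyTable] = []
    for block in text.split("//"):
        block = block.strip()
        if not block:
            continue
        accession = None
        values: list[str] = []
        in_i = False
        for line in block.splitlines():
            if line.startswith("H "):
                accession = line[2:].strip()
                in_i = False
            elif line.startswith("I "):
                in_i = True
            elif in_i and line.startswith(" "):
                values.extend(line.split())
            elif in_i:
                in_i = False
        if accession is None:
            raise PropertyError(f"{path}: AAindex entry without an H record")
        if not values:
            raise PropertyError(f"{path}: entry {accession}: missing I record")
        if len(values) != 20:
            raise PropertyError(
                f"{path}: entry {accession}: expected 20 values, found {len(values)}"
            )
        if any(v == "NA" for v in values):
            raise PropertyError(f"{path}: entry {accession}: NA values are not supported")
        pval = {aa: float(v) for aa, v in zip(_AAINDEX_ORDER, values)}
        tables.append(PropertyTable(name=accession, pval=pval))
    return tables


def load_packaged_property(accession: str) -> PropertyTable:
    """Load one of the packaged AAindex fixtures by accession.

    Available: ``FAUJ880103`` (normalized van der Waals volume) and
    ``BIOV880101`` (information value for accessibility).
    """
    ref = resources.files("helixgram.data").joinpath("aaindex_fixtures.txt")
    with resources.as_file(ref) as path:
        tables = read_aaindex(path)
    for table in tables:
        if table.name == accession:
            return table
    raise PropertyError(
        f"accession {accession!r} not packaged; available: {[t.name for t in tables]}"
    )
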
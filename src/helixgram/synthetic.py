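"""Labeled helix-pair datasets with planted contact-site motifs.

Real transmembrane helix-pair datasets are derived from 3D structures;
this module instead emulates their sequence-level statistical structure:
classes of 10+10-residue helix pairs whose *interface* positions (spaced
by the 3/4-residue alternation that preserves the mean helix periodicity
of 3.6) are drawn from class-specific residue pools, with the remaining
*outerface* positions drawn from a shared background pool and a
controllable off-pool substitution noise.

The default two-class setup mirrors the two best-characterized packing
motifs: a class with small residues (G, A, S -- the GxxxG/heptad
flavour) at the interface of both helices, and a class with small
residues on helix 1 approached by large residues (L, I, F) on helix 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .grammar import AA_ALPHABET, Grammar
from .parsing import ParseError, sample
from .sequences import HelixPairSequence, read_pairs, write_pairs

__all__ = [
    "MotifSpec",
    "default_two_class_specs",
    "plant_motif_dataset",
    "reverse_helix2",
    "sample_from_grammar",
    "interface_positions",
    "HelixPairSequence",
    "read_pairs",
    "write_pairs",
]

_SHAPE_RE = re.compile(r"^\[[A-Z]+\]\{[A-Z]+\}$")

#: Hydrophobic background typical of transmembrane helices.
DEFAULT_OUTERFACE_POOL = "LIVMAFT"


@dataclass(frozen=True)
class MotifSpec:
    """Planted-motif description for one contact-site class.

    ``interface_pool`` is either one residue string (both helices) or a
    pair of strings (helix 1, helix 2).  ``noise`` is the per-position
    probability of replacing the drawn residue by a uniform one from the
    full 20-letter alphabet.  ``periods`` is the interface spacing
    pattern, alternating 3- and 4-residue steps by default (helix
    periodicity 3.6).
    """

    interface_pool: Union[str, tuple[str, str]]
    outerface_pool: str = DEFAULT_OUTERFACE_POOL
    noise: float = 0.0
    orientation: str = "antiparallel"
    periods: tuple[int, ...] = (3, 4)

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        if self.orientation not in ("antiparallel", "parallel"):
            raise ValueError("orientation must be 'antiparallel' or 'parallel'")
        pools = self.pools
        if not pools[0] or not pools[1] or not self.outerface_pool:
            raise ValueError("residue pools must be non-empty")
        if not set(self.periods) <= {3, 4}:
            raise ValueError("interface periods must be 3 or 4")

    @property
    def pools(self) -> tuple[str, str]:
        if isinstance(self.interface_pool, str):
            return (self.interface_pool, self.interface_pool)
        return self.interface_pool


def interface_positions(helix_len: int, periods: tuple[int, ...] = (3, 4)) -> list[int]:
    """Interface positions from the N-terminus under the period alternation.

    E.g. for a 10-residue helix with periods (3, 4): positions 0, 3, 7.
    """
    pos = [0]
    i = 0
    while True:
        nxt = pos[-1] + periods[i % len(periods)]
        if nxt >= helix_len:
            break
        pos.append(nxt)
        i += 1
    return pos


def default_two_class_specs(noise: float = 0.2) -> dict[str, MotifSpec]:
    """The two-class fixture: small/small vs small/large interfaces."""
    return {
        "c1": MotifSpec(interface_pool="GAS", noise=noise),
        "c2": MotifSpec(interface_pool=("GAS", "LIF"), noise=noise),
    }


def _plant_helix(
    rng: np.random.Generator,
    helix_len: int,
    iface_positions: Sequence[int],
    iface_pool: str,
    outer_pool: str,
    noise: float,
) -> str:
    iface = set(iface_positions)
    residues = []
    for i in range(helix_len):
        pool = iface_pool if i in iface else outer_pool
        aa = pool[rng.integers(0, len(pool))]
        if noise > 0.0 and rng.random() < noise:
            aa = AA_ALPHABET[rng.integers(0, len(AA_ALPHABET))]
        residues.append(aa)
    return "".join(residues)


def plant_motif_dataset(
    spec_by_class: Mapping[str, MotifSpec],
    n_per_class: int,
    seed: int,
    helix_len: int = 10,
) -> list[HelixPairSequence]:
    """Generate a labeled dataset of helix pairs with planted motifs.

    For the antiparallel orientation, helix-2 interface positions mirror
    helix 1's (position ``i`` of helix 1 packs against ``L-1-i`` of helix
    2); for the parallel orientation the motif phases align N-to-N.
    """
    if len(spec_by_class) < 2:
        raise ValueError("need at least 2 classes")
    if not 8 <= helix_len <= 14:
        raise ValueError("helix_len must be within 8..14")
    rng = np.random.default_rng(seed)
    dataset: list[HelixPairSequence] = []
    for label in sorted(spec_by_class):
        spec = spec_by_class[label]
        pool1, pool2 = spec.pools
        pos1 = interface_positions(helix_len, spec.periods)
        if spec.orientation == "antiparallel":
            pos2 = sorted(helix_len - 1 - p for p in pos1)
        else:
            pos2 = list(pos1)
        for i in range(n_per_class):
            h1 = _plant_helix(rng, helix_len, pos1, pool1, spec.outerface_pool, spec.noise)
            h2 = _plant_helix(rng, helix_len, pos2, pool2, spec.outerface_pool, spec.noise)
            dataset.append(
                HelixPairSequence(id=f"{label}_{i:04d}", helix1=h1, helix2=h2, label=label)
            )
    return dataset


def reverse_helix2(dataset: Sequence[HelixPairSequence]) -> list[HelixPairSequence]:
    """Copies with helix 2 reversed C-to-N.

    For parallel helix pairs, reversing one helix maps their crossing
    dependencies onto the nested form the grammar expresses; score a pair
    in both orders and keep the better one.
    """
    return [
        HelixPairSequence(id=s.id, helix1=s.helix1, helix2=s.helix2[::-1], label=s.label)
        for s in dataset
    ]


def sample_from_grammar(
    grammar: Grammar, n: int, seed: int, max_attempts_factor: int = 100
) -> list[HelixPairSequence]:
    """Draw helix-pair sequences from a grammar, rejecting malformed shapes.

    Samples are drawn by seeded leftmost derivation; strings that do not
    match the bracketed ``[h1]{h2}`` shape (with non-empty helices) are
    rejected and resampled, up to ``100 * n`` attempts.
    """
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    out: list[HelixPairSequence] = []
    attempts = 0
    cap = max_attempts_factor * n
    while len(out) < n:
        if attempts >= cap:
            raise ParseError(
                f"exceeded {cap} sampling attempts; grammar rarely emits bracketed pairs"
            )
        attempts += 1
        try:
            text = sample(grammar, rng)
        except ParseError:
            continue
        if _SHAPE_RE.match(text):
            try:
                out.append(HelixPairSequence.from_encoded(text, id=f"sample_{len(out):04d}"))
            except ValueError:
                continue
    return out
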
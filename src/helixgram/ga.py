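"""Genetic-algorithm inference of grammar rule probabilities.

The training objective is the arithmetic mean, over a positive training
set, of the log of the total derivation probability of each sequence --
an estimator (up to sign and a constant) of the cross-entropy between
the sample and the grammar distribution.  Maximizing it is therefore
cross-entropy minimization, and because every candidate grammar is
proper (hence consistent when optimal), no negative training set is
required.

One individual is a chromosome of real genes in [0, 1], one per
evolvable rule (terminal rules are frozen).  Genes map to probabilities
through a nonlinear power map followed by per-LHS normalization, which
sharpens contrasts and speeds convergence.  The loop is a steady-state
GA: tournament selection of two competitors on fitness scores derated by
a triangular sharing function (niching), offspring by gene-wise parent
averaging with a uniform random distortion, occasional one-point
mutation, and replacement of the worst half of the population.  The
sharing cutoff starts at 10.0 and doubles adaptively when improvement
slows, shifting search from exploration to local refinement; the run
stops when the record-best objective improves by less than a factor of
1.001 over 100 generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fastparse import CompiledGrammar
from .grammar import Grammar, GrammarError
from .sequences import HelixPairSequence

__all__ = [
    "GAConfig",
    "TrainingSet",
    "FitnessRecord",
    "EvolutionHistory",
    "objective",
    "genotype_to_phenotype",
    "shared_fitness",
    "evolve",
]

#: Log-probability floor for unparseable training sequences.
UNPARSEABLE_FLOOR = -1e6

_RAW_FITNESS_EPS = 1e-9


@dataclass(frozen=True)
class GAConfig:
    """Inference hyperparameters (defaults are the full-scale settings)."""

    population_size: int = 200
    p_crossover: float = 0.9
    p_mutation: float = 0.01
    overlap_fraction: float = 0.5
    tournament_size: int = 2
    sharing_cutoff_init: float = 10.0
    distortion_halfwidth: float = 0.05
    phenotype_exponent: float = 3.0
    stop_ratio: float = 1.001
    stop_window: int = 100
    max_generations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_crossover", "p_mutation", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.stop_window < 1:
            raise ValueError("stop_window must be >= 1")
        if self.sharing_cutoff_init <= 0:
            raise ValueError("sharing cutoff must be positive")


@dataclass(frozen=True)
class TrainingSet:
    """Positive examples for one contact-site class.

    Sequences may be :class:`HelixPairSequence` objects or plain strings
    over the grammar's terminal alphabet (toy grammars).
    """

    sequences: tuple[HelixPairSequence | str, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if not self.sequences:
            raise ValueError("training set must be non-empty")


@dataclass(frozen=True)
class FitnessRecord:
    """One individual's evaluation in one generation."""

    objective: float
    shared_fitness: float
    generation: int


@dataclass
class EvolutionHistory:
    """Per-generation best/mean objective plus the running record best."""

    generations: list[int] = field(default_factory=list)
    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)
    record_best: list[float] = field(default_factory=list)
    sharing_cutoff: list[float] = field(default_factory=list)

    def append(self, gen: int, best: float, mean: float, record: float, cutoff: float) -> None:
        self.generations.append(gen)
        self.best.append(best)
        self.mean.append(mean)
        self.record_best.append(record)
        self.sharing_cutoff.append(cutoff)


class _GeneMap:
    """Mapping between a flat gene vector and evolvable rule groups."""

    def __init__(self, template: Grammar):
        self.template = template
        self.base_probs = np.array([r.prob for r in template.rules])
        groups = template.rules_by_lhs()
        rule_pos = {id(r): i for i, r in enumerate(template.rules)}
        self.groups: list[np.ndarray] = []
        for lhs in template.evolvable_lhs:
            self.groups.append(np.array([rule_pos[id(r)] for r in groups[lhs]]))
        self.gene_rule_indices = np.concatenate(self.groups) if self.groups else np.array([], dtype=int)
        self.n_genes = int(self.gene_rule_indices.size)
        # slices of the gene vector per group
        self.group_slices: list[slice] = []
        off = 0
        for g in self.groups:
            self.group_slices.append(slice(off, off + g.size))
            off += g.size

    def phenotype_matrix(self, genes: np.ndarray, exponent: float) -> np.ndarray:
        """(K, n_genes) genes -> (n_rules, K) proper probability matrix."""
        genes = np.atleast_2d(genes)
        K = genes.shape[0]
        probs = np.repeat(self.base_probs[:, None], K, axis=1)
        weights = genes**exponent
        for rule_idx, sl in zip(self.groups, self.group_slices):
            w = weights[:, sl].T  # (group_size, K)
            sums = w.sum(axis=0)
            zero = sums <= 0.0
            if np.any(zero):  # degenerate all-zero group: fall back to uniform
                w[:, zero] = 1.0
                sums = w.sum(axis=0)
            probs[rule_idx, :] = w / sums
        return probs


def objective(
    grammar: Grammar | CompiledGrammar,
    train: TrainingSet | Sequence[HelixPairSequence],
) -> float:
    """Mean inside log-probability of the positive training set.

    Unparseable sequences contribute the floor ``-1e6`` instead of
    ``-inf`` so the objective stays finite.
    """
    seqs = train.sequences if isinstance(train, TrainingSet) else tuple(train)
    if not seqs:
        raise ValueError("training set must be non-empty")
    cg = grammar if isinstance(grammar, CompiledGrammar) else CompiledGrammar(grammar)
    from .fastparse import batch_logprobs

    scores = batch_logprobs(cg, seqs, mode="sum")
    return float(np.mean(np.maximum(scores, UNPARSEABLE_FLOOR)))


def genotype_to_phenotype(
    chrom: np.ndarray, template: Grammar, exponent: float = 3.0
) -> Grammar:
    """Map a gene vector to a proper grammar.

    Gene i is raised to ``exponent`` and the powered weights of each
    evolvable LHS group are normalized; frozen (terminal) groups keep the
    template's probabilities.
    """
    gm = _GeneMap(template)
    chrom = np.asarray(chrom, dtype=float)
    if chrom.shape != (gm.n_genes,):
        raise GrammarError(
            f"chromosome has {chrom.size} genes; template has {gm.n_genes} evolvable rules"
        )
    probs = gm.phenotype_matrix(chrom[None, :], exponent)[:, 0]
    return template.copy_with_probs(probs)


def shared_fitness(
    objectives: np.ndarray,
    distances: np.ndarray,
    cutoff: float,
    eps: float = _RAW_FITNESS_EPS,
) -> np.ndarray:
    """Derate raw fitness by triangular-sharing niche counts.

    Raw fitness is the objective shifted to be positive
    (``obj - min(obj) + eps``) so that dividing by the niche count
    ``sum_j max(0, 1 - d_ij / cutoff)`` is meaningful for negative
    log-probability objectives.
    """
    if cutoff <= 0:
        raise ValueError("sharing cutoff must be positive")
    objectives = np.asarray(objectives, dtype=float)
    sh = np.maximum(0.0, 1.0 - distances / cutoff)
    niche = sh.sum(axis=1)  # includes self (distance 0 -> sh = 1)
    raw = objectives - objectives.min() + eps
    return raw / niche


def _pairwise_distances(phenotypes: np.ndarray) -> np.ndarray:
    """Euclidean distances between phenotype probability vectors (columns)."""
    X = phenotypes.T  # (K, n_rules)
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.sqrt(np.maximum(d2, 0.0))


def evolve(
    template: Grammar,
    train: TrainingSet | Sequence[HelixPairSequence],
    cfg: GAConfig | None = None,
) -> tuple[Grammar, EvolutionHistory]:
    """Infer evolvable rule probabilities on a positive training set.

    Returns the best-ever phenotype grammar (the record best, which is
    monotone non-decreasing across generations even though the population
    itself has no elitism) and the per-generation history.
    """
    cfg = cfg or GAConfig()
    if not isinstance(train, TrainingSet):
        train = TrainingSet(tuple(train))
    gm = _GeneMap(template)
    if gm.n_genes == 0:
        raise GrammarError("template has no evolvable rules")
    compiled = CompiledGrammar(template)
    rng = np.random.default_rng(cfg.rng_seed)

    # group training sequences by token length for batched scoring
    from .fastparse import _tokens

    seq_groups: dict[int, list] = {}
    for seq in train.sequences:
        seq_groups.setdefault(len(_tokens(seq)), []).append(seq)
    n_train = len(train.sequences)

    def evaluate(genes: np.ndarray) -> np.ndarray:
        probs = gm.phenotype_matrix(genes, cfg.phenotype_exponent)
        total = np.zeros(genes.shape[0])
        for seqs in seq_groups.values():
            scores = compiled.logprobs(seqs, probs, mode="sum")  # (S, K)
            total += np.maximum(scores, UNPARSEABLE_FLOOR).sum(axis=0)
        return total / n_train

    P = cfg.population_size
    genes = rng.random((P, gm.n_genes))
    objs = evaluate(genes)

    record_idx = int(np.argmax(objs))
    record_obj = float(objs[record_idx])
    record_genes = genes[record_idx].copy()
    record_trace = [record_obj]

    history = EvolutionHistory()
    cutoff = cfg.sharing_cutoff_init
    history.append(0, float(objs.max()), float(objs.mean()), record_obj, cutoff)

    n_off = max(1, int(round(P * cfg.overlap_fraction)))
    half_window = max(1, cfg.stop_window // 2)
    last_double = 0

    def improvement_ratio(lag: int) -> float:
        if len(record_trace) <= lag:
            return float("inf")
        past = abs(record_trace[-1 - lag])
        now = abs(record_trace[-1])
        if now == 0.0:
            return float("inf")
        return past / now

    for gen in range(1, cfg.max_generations + 1):
        phen = gm.phenotype_matrix(genes, cfg.phenotype_exponent)
        dist = _pairwise_distances(phen)
        shared = shared_fitness(objs, dist, cutoff)

        offspring = np.empty((n_off, gm.n_genes))
        for o in range(n_off):
            parents = []
            for _ in range(2):
                cands = rng.integers(0, P, size=cfg.tournament_size)
                parents.append(cands[int(np.argmax(shared[cands]))])
            p1, p2 = parents
            if rng.random() < cfg.p_crossover:
                child = (genes[p1] + genes[p2]) / 2.0
                child += rng.uniform(
                    -cfg.distortion_halfwidth, cfg.distortion_halfwidth, gm.n_genes
                )
                np.clip(child, 0.0, 1.0, out=child)
            else:
                child = genes[p1].copy()
            if rng.random() < cfg.p_mutation:
                child[rng.integers(0, gm.n_genes)] = rng.random()
            offspring[o] = child

        off_objs = evaluate(offspring)

        worst = np.argsort(objs)[:n_off]  # steady-state: replace the worst half
        genes[worst] = offspring
        objs[worst] = off_objs

        gen_best = int(np.argmax(objs))
        if objs[gen_best] > record_obj:
            record_obj = float(objs[gen_best])
            record_genes = genes[gen_best].copy()
        record_trace.append(record_obj)

        # double the sharing cutoff when improvement over the half window slows
        if gen - last_double >= half_window and improvement_ratio(half_window) < cfg.stop_ratio:
            cutoff *= 2.0
            last_double = gen

        history.append(gen, float(objs.max()), float(objs.mean()), record_obj, cutoff)

        if gen >= cfg.stop_window and improvement_ratio(cfg.stop_window) < cfg.stop_ratio:
            break

    best = template.copy_with_probs(
        gm.phenotype_matrix(record_genes[None, :], cfg.phenotype_exponent)[:, 0]
    )
    return best, history
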
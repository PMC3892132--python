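# Methods

## The model

A helix-helix contact site is represented as a bracketed string
`[h1]{h2}` over the 20-letter amino-acid alphabet, where `h1` and `h2`
are two transmembrane helix fragments (10 residues each by default) in
contact.  The model is a probabilistic context-free grammar (PCFG)
`G = <Σ, N, P, S>` whose rule probabilities define a distribution
`P(x | G)` over such strings.  A grammar is *proper* when every
left-hand side's rule probabilities sum to one (enforced everywhere at
tolerance 1e-9) and *consistent* when its total mass over finite
strings is one; proper grammars at the cross-entropy optimum are
consistent, which is why training needs no negative examples.

### Property terminals

Rather than conditioning on 20 residue identities, terminal rules map
three *property non-terminals* — `Low`, `Medium`, `High` — to amino
acids with probabilities derived from a quantitative AAindex property
(packaged: `FAUJ880103`, normalized van der Waals volume, and
`BIOV880101`, accessibility information value).  *Problem-based
scaling* first centres the property at the composition-weighted mean of
the training corpus, then divides by the extreme negative (positive)
centred value, so `Low` puts mass on residues below the corpus mean in
proportion to their distance from it and `High` on residues above it.
The `Medium` row is the per-residue remainder `1 − Low − High`; taken
literally that row sums to ~18 over 20 residues, which would violate
properness, so it is renormalized to sum to one.  Likewise the `Low`
and `High` denominators run over the sign-restricted residues only
(summing the scaled values over all residues can cancel to zero by
antisymmetry).  Both choices keep the rows well-defined and proper; the
terminal rows are invariant under positive affine rescaling of the raw
property, which the tests assert.  `Any → a` is uniform (1/20) by
default, switchable to composition-weighted.

### The helix-pair template

The grammar skeleton has 18 non-terminals.  Its core is a *stem* of
alternating `Interface`/`Outerface` symbols carrying two-letter `S`/`D`
subscripts that record how many residues (one or two) the parent rule
emitted around the symbol on the helix-1 (left) and helix-2 (right)
side.  Context compatibility — after `S` only a double context, after
`D` either — keeps each complete helix turn 3 or 4 residues long,
matching the mean α-helical periodicity of 3.6.  Concrete one-residue
contexts are property non-terminals; two-residue contexts are `Double_X`
symbols (three by default, each with the nine ordered property-level
pairs as expansions).  `Turn` closes the stem across the `]` `{`
boundary; `Whatever → Any Whatever | ε` absorbs unconstrained residues
at the four helix ends (it appears after `[`, before `}`, and on both
sides inside `Turn`), so every bracketed string with non-empty helices
is parseable by the uniform-initialized template.  `Start` chooses the
stem root among the eight stem symbols as an ordinary evolvable 8-way
group.  The full rule list is not fixed by any single published table;
the stem family here is generated from the subscript semantics and the
periodicity constraint, giving 208 evolvable rules (170 stem + 27
Double + 8 Start + 1 Turn + 2 Whatever), consistent with the ~200-rule
scale the inference scheme is designed for.  `Outerface_P`, an
otherwise-unused symbol name appearing in one published symbol listing,
is instantiated as `Outerface_DD`, the only subscript otherwise missing
from the family.

Two ablation variants isolate what the full grammar contributes:
`no_dependency` drops the helix-2 context from every stem rule and
generates helix 2 with an independent single-subscript chain terminated
by an ε rule (periodicity without inter-helix dependency), and
`unconstrained` is a right-linear grammar appending one symbol from
{Low, Medium, High, Any, Turn} per step (no structure at all).

## Parsing

Two scoring modes: `sum` — the inside probability, i.e. the total mass
of all derivations, used by the training objective — and `max` — the
Viterbi derivation and its tree, used for scanning and classification.
The reference implementation is a memoized dotted-rule recursion over
the original grammar (arbitrary right-hand side lengths, ε rules); all
arithmetic is in the linear domain with natural-log output and `-inf`
as the unparseable sentinel (rule products over these short strings
stay far above double-precision underflow).  Viterbi ties are broken
deterministically: first rule in template order, then earliest split
point.  Grammars permitting a non-consuming cycle (`A ⇒+ A` over the
same span) have a divergent inside sum; `sum` mode raises on such
grammars while `max` mode prunes the cycle, which is exact because a
cyclic derivation can never be strictly more probable than its acyclic
core.  None of the grammars this package builds contain such cycles.

Training evaluates the same grammar structure under thousands of
candidate probability assignments, so a second, compiled engine
binarizes and ε-eliminates the grammar once — every transformed rule's
probability is a *monomial* (product) of original rule probabilities —
and runs one CYK pass whose chart cells are arrays over
`sequences × candidates`, with a feasibility-pruned schedule computed
per position-character layout.  Compiled restrictions: symbols may be
nullable only via a direct ε rule, unary non-terminal rules must be
acyclic, and the start symbol must not be nullable; every template
variant satisfies these.  The compilation is contract-invisible: tests
assert equality with the reference parser to 1e-9 on toy, random and
template grammars, and both are checked against an independent
leftmost-derivation enumeration oracle.

## Inference

The objective is the arithmetic mean of inside log-probabilities over
the positive training set — an estimator of (minus) the cross-entropy
between sample and model, proportional to the log-likelihood.
Unparseable sequences (impossible for the template, a guard for custom
grammars) contribute a floor of −1e6 rather than −∞.

One individual is a chromosome of genes in [0, 1], one per evolvable
rule.  Genes map to probabilities by a power nonlinearity (`gene^3`,
exponent configurable) followed by per-LHS normalization; terminal
groups stay frozen.  The loop is a steady-state GA with:

* population 200 (full scale) or 60 (reduced desk-scale default in the
  estimators), random uniform initialization;
* tournament selection with 2 competitors on *shared* fitness: raw
  fitness is the objective shifted positive (`obj − min + ε`), divided
  by the niche count `Σ_j max(0, 1 − d_ij / cutoff)` with Euclidean
  distance between phenotype probability vectors and triangular kernel;
  the cutoff starts at 10.0 and doubles adaptively (at most once per
  half stopping window) when the record best improves by less than the
  stopping ratio over half a window;
* crossover with probability 0.9: gene-wise parent averaging plus a
  uniform distortion in ±0.05, clamped to [0, 1]; otherwise the first
  parent is copied;
* one-point mutation with probability 0.01 per offspring (one random
  gene resampled uniformly);
* replacement of the worst 50% of the population (by raw objective)
  each generation — no elitism in the population, but the best-ever
  phenotype (the *record best*) is kept outside it and returned;
* stop when `|best(t−100)| / |best(t)| < 1.001` (under 0.1% relative
  improvement over 100 generations) or at the generation cap.

Reconstructed details (the published description leaves them open): the
similarity measure is Euclidean distance over phenotype probability
vectors; the phenotype nonlinearity is a power map with exponent 3; the
distortion half-width is 0.05; the adaptive-doubling trigger is the
half-window ratio test; the sharing sign handling uses the shifted-
positive raw fitness above.  All are configurable `GAConfig` fields.
Fixed seeds give bit-identical histories.

After training, rules below probability 0.05 are pruned and the
grammar renormalized for interpretation; a group that would be emptied
keeps its single highest-probability rule.

## Classification and evaluation

Scanning uses Viterbi scores (sum mode behind a flag).  Scores of
several same-class grammars are averaged into a *combined* classifier.
The *multiscore* of class q is q's score minus the mean of the other
classes' scores; with four classes this is the `−1/3 Σ` form, and the
implementation generalizes to k ≥ 2 (the two-class fixture uses k = 2).
Multiscores sum to zero over classes for every sequence and are
invariant to additive shifts; sequences with a non-finite component are
flagged, not scored.  The average-property baseline scores a pair by
its mean raw property value with the sign direction fitted by training
AUC.

AUC is the rank probability that a positive outscores a negative with
ties counted one half (delegated to scikit-learn's ROC utilities).
LOOCV trains on all but one positive and scores it against all
negatives; the per-sample AUC then equals the specificity at the
positive's own score, an identity the tests assert exactly.  k-fold CV
(k = 4) partitions positives into contiguous blocks by identifier sort
order, trains `combine = 3` differently-seeded grammars per fold and
reports single, combined and best-single AUCs against the full negative
set.  Vertical averaging samples each ROC step curve at a fixed FP-rate
grid (band 0.1; grid sampling, not within-band interpolation) and
attaches normal-approximation half-widths `1.96·sqrt(p(1−p)/n)`;
precision/recall/F1/accuracy are reported at the realized operating
point at or below each requested FP rate.

## Averaged a-priori parse trees

With levels valued Low = 0, Medium = 1, High = 2 (`Any` contributes 1,
its uniform expectation, configurable), the expected property level of
each position emitted along a stem path is a mixture over the parent's
rule alternatives — conditioned on the chosen stem child and
renormalized — and, for `Double` contexts, over the Double symbol's own
expansions.  The tree is conditional on a stem path (typically the most
common stem among Viterbi parses of a training set), not marginal over
stems.  Expected levels are linear in rule probabilities and bounded in
[0, 2]; rendering rounds to the nearest integer with ties up.

## Synthetic data

Real datasets of this kind are derived from 3D structures (contact
detection, RMSD assignment to class centroids, redundancy reduction);
the generator emulates only their sequence-level statistics.  Interface
positions follow the 3/4 alternation from the N-terminus (0, 3, 7 on a
10-residue helix); helix-2 positions mirror helix 1's in the default
antiparallel orientation (N-to-N aligned for parallel).  Interface
residues are drawn uniformly from class pools — small `{G, A, S}` on
both helices for the class-1-like motif, small on helix 1 and large
`{L, I, F}` on helix 2 for the class-2-like motif — outerface residues
from a hydrophobic transmembrane background `{L, I, V, M, A, F, T}`,
and each position is replaced by a uniform residue with probability
`noise`.  The default study condition is noise 0.2, 100 pairs per
class, data seed 42, helix length 10+10 (configurable 8-14).

What passing tests do and do not show: the generator plants clean,
phase-aligned periodic motifs with independent positions; real helix
pairs have correlated positions, variable lengths and phases, weak
intra-class homology and continuous conformation space, so held-out
AUCs on synthetic classes (~0.95+ at these settings) are an upper bound
of regime, not a forecast of performance on structure-derived data.

## Problem sizes and numerical choices

The reduced inference budget used by the estimator defaults and the
reproduction script — population 60, 150 generations, 3 seeds combined,
50 training pairs per class — was chosen as the smallest setting at
which the planted two-class problem is learned reliably; the full-scale
configuration (population 200, stop-ratio termination) remains the
`GAConfig` default.  Properness tolerance is 1e-9 everywhere; parser
cross-checks are asserted at 1e-9 in natural-log space; probabilities
are compared in the linear domain only where exactness is wanted
(worked-example levels to 1e-12).  Ties: Viterbi by rule order then
earliest split; pruning keeps the first-ordered max rule; rounding of
expected levels is half-up.

## Known limitations

* Context-free rules link residues at opposing sequence positions, so
  antiparallel pairs map naturally onto nested dependencies; for
  parallel pairs the crossing dependencies would need (mildly)
  context-sensitive rules, which are out of scope — the grammar still
  scores parallel classes but its trees are not directly interpretable
  there.  Sequence reversal of one helix is available as a data option.
* The inside sum requires cycle-free grammars (see Parsing); the
  compiled engine additionally requires directly-nullable ε symbols and
  acyclic unaries.
* GA convergence to the global optimum is not guaranteed; several
  seeded runs are combined by score averaging, and the record best of
  each run is reported.
* The AAindex reader supports the single-property `I` record of the
  AAindex1 dialect, not the mutation/contact matrices of AAindex2/3.
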
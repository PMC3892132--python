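# helixgram

Grammar-based classification of transmembrane helix-helix contact
sites.

Pairs of interacting transmembrane helices pack in a handful of
recurring configurations — the GxxxG motif, heptad (knobs-into-holes)
repeats — that leave a weak, *paired* signature in the two sequences:
small or large residues recur every 3-4 positions (one helix turn) on
the faces the helices present to each other.  Linear motifs and
profiles cannot couple positions across two sequences; a probabilistic
context-free grammar (PCFG) can, because nested rules emit one or two
residues of *each* helix per derivation step.  `helixgram` is for
structural bioinformaticians who want to train, apply and inspect such
grammar classifiers on helix-pair fragments without any structural
input.

## The model in brief

A helix pair is a bracketed string `[h1]{h2}` (10+10 residues by
default).  The grammar `G = <Σ, N, P, S>` has 18 non-terminals; its
stem alternates `Interface`/`Outerface` symbols whose `S`/`D`
subscripts keep every helix turn 3-4 residues long.  Terminal rules
encode an amino-acid property as fuzzy levels: after *problem-based
scaling* (centring property values `pval` at the composition-weighted
mean), `Pr(Low → a) ∝ pval″_L(a)` over residues below the mean and
`Pr(High → a) ∝ pval″_H(a)` above it.  With the packaged van der Waals
volume table, `Low` concentrates on G, A, S, C and `High` on W, Y, R, F
— exactly the small-vs-large contrast of the packing motifs.

Rule probabilities are inferred per contact-site class by a
steady-state genetic algorithm (tournament of 2 on triangular-sharing
fitness, averaging crossover with distortion, 50% replacement)
maximizing the mean inside log-probability of the positive training set
— a cross-entropy estimate, so no negative set is needed.  Trained
grammars score sequences by their Viterbi parse, combine by score
averaging, and fuse across classes by the *multiscore*
`multiscore_q(w) = log Pr_q(w) − (1/(k−1)) Σ_{p≠q} log Pr_p(w)`.
Evaluation is ROC/AUC with leave-one-out and k-fold cross-validation;
the *averaged a-priori parse tree* reads the learned property profile
(Low = 0, Medium = 1, High = 2) directly off the grammar.

## Worked example

Train a three-run combined classifier for the small-interface class of
the synthetic two-class benchmark, and test it on held-out pairs:

```python
from helixgram import GrammarClassifier
from helixgram.evaluate import roc_auc
from helixgram.synthetic import default_two_class_specs, plant_motif_dataset

dataset = plant_motif_dataset(default_two_class_specs(noise=0.2), 100, seed=42)
c1 = [s for s in dataset if s.label == "c1"]   # small/small interfaces
c2 = [s for s in dataset if s.label == "c2"]   # small/large interfaces

clf = GrammarClassifier(property_table="FAUJ880103", n_grammars=3,
                        population_size=60, max_generations=150,
                        random_state=42).fit(c1[:50])

pos = clf.score_samples(c1[50:])
neg = clf.score_samples(c2[50:])
print(f"held-out mean log-probability: class 1 {pos.mean():.2f}, class 2 {neg.mean():.2f}")
print(f"held-out AUC (class 1 vs class 2): {roc_auc(pos, neg).auc:.3f}")
```

Output:

```
held-out mean log-probability: class 1 -64.82, class 2 -70.69
held-out AUC (class 1 vs class 2): 0.982
```

The scores are natural-log Viterbi probabilities averaged over the
three inference runs: class-1 pairs are about 6 nats more probable
under the class-1 grammar than class-2 pairs, which translates into an
AUC of 0.98 — the probability that a random class-1 pair outscores a
random class-2 pair.

The same pipeline is available from the shell:

```sh
helixgram simulate --n 100 --noise 0.2 --seed 42 --out pairs.tsv
helixgram make-grammar --property FAUJ880103 --seqs pairs.tsv --out template.txt
helixgram train --grammar template.txt --pos pairs_c1.tsv --seed 0 --out trained.txt
helixgram scan --grammar trained.txt --seqs pairs.tsv --out scores.tsv
helixgram tree --grammar trained.txt --stem auto --seqs pairs_c1.tsv --out tree.txt
helixgram run --out results/   # full simulate-train-classify-report pipeline
```

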
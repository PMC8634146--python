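# discrimlex

Linear discriminative learning (LDL) for inflectional morphology.

`discrimlex` models the mental lexicon as two linear mappings between word
*forms* and word *meanings* — no stems, exponents, or inflectional classes.
It is aimed at psycholinguists and computational morphologists who want to
study comprehension, production, frequency effects, and wug-style
generalization in paradigm-based systems such as German noun declension,
where pervasive paradigm-cell homophony and semi-productivity make the
mapping problem interesting.

## The model

A word form is a binary vector over sublexical n-gram cues (phone, letter,
or syllable n-grams, padded with `#`); stacking them gives the cue matrix
**C**. A word's meaning is a real vector: the sum of its lexeme vector and
the vectors of its inflectional functions (number, case or semantic role,
definiteness), plus small Gaussian noise; stacking gives the semantic matrix
**S**. Comprehension and production are the multivariate multiple
regressions

    S = C·F        (comprehension)
    C = S·G        (production)

solved either in closed form (the minimum-norm least-squares *end-state of
learning*) or incrementally with the Widrow–Hoff rule,

    W(t+1) = W(t) + cᵀ(o − c·W(t))·η,

which updates after every word token and therefore learns frequent words
better — the end-state is frequency-blind, the incremental path is not.

A word is *understood* if the gold meaning best correlated (Pearson r) with
ŝ = c·F is the right one; for homophones a lenient criterion accepts any
meaning the surface form can carry. A word is *produced* by assembling cues
whose predicted support ĉ = s·G clears a threshold θ into paths through the
directed graph of overlapping n-grams, then picking the path whose
re-projected meaning best correlates with the target (*synthesis by
analysis*); production counts as correct only on exact string match. A
tolerance t admits up to t weakly supported cues per path, which is what
lets near-miss held-out forms through.

Everything runs on synthetic data: the built-in generator emulates
German-like noun paradigms (five plural classes with realistic type
frequencies, umlaut, the nominative/dative/accusative-singular and
nominative/genitive/accusative-plural homophone template, Zipfian token
frequencies, articles, semantic-role expansion) — or on any paradigm
lexicon you supply as delimited text with columns
`form lemma case number gender frequency`.

## Worked example

```python
from discrimlex import (ExperimentConfig, GeneratorSpec, generate_toy_lexicon,
                        run_experiment)
from discrimlex.workbench import format_report

lex, _ = generate_toy_lexicon(GeneratorSpec(n_lemmas=40, seed=3))
report = run_experiment(lex, ExperimentConfig(seed=3))
print(format_report(report))
```

prints

```
config 15ca5926cef8edfc  (320 entries, 271 cues)
        train   val_all val_lenient     val_strict      val_newform
comprehension   1.000   0.906   1.000   0.000   0.250
production      0.988   0.219   0.250   0.250   0.000
```

Reading the numbers: the end-state model is an excellent *memory* — training
comprehension is perfect and training production nearly so. On held-out data
it recognizes 90.6% overall, but almost all of that is carried by homophones
(`val_lenient` = 1.0: these surface forms were seen in training under other
paradigm cells); genuinely new forms are understood only 25% of the time and
produced never — the semi-productivity the model is supposed to show.
`val_strict` is near zero because an isolated homophone gives the model (or
a listener) no way to tell which paradigm cell was meant.

The same pipeline is available from the shell:

```sh
discrimlex simulate lexicon --n-lemmas 40 --seed 3 --out lex.tsv
discrimlex run --lexicon lex.tsv --seed 3 --out report.json
discrimlex wug --lexicon lex.tsv --seed 3          # nonce plural candidates
discrimlex lexicon split --lexicon lex.tsv --mode no-novel-cues --cue triphone --seed 3
```

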